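"""Deterministic child-stream derivation from a root seed.

Child generators are keyed by stable string/int tuples (e.g. compound id,
replica, window) so that enlarging an ensemble never perturbs the streams
of existing members.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "stable_hash"]


def stable_hash(key: object) -> int:
    """CRC32 of the string form of *key*; stable across processes and runs."""
    return zlib.crc32(str(key).encode("utf-8"))


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator for the stream identified by ``(seed, *keys)``.

    The root seed plus hashed keys form the entropy of a SeedSequence, so
    streams for distinct key tuples are statistically independent and a
    given tuple always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(stable_hash(k) for k in keys)
    return np.random.default_rng(entropy)
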