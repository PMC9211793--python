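"""Perturbation-network accounting for alchemical transformations.

A perturbation network has compounds as nodes and calculated
transformations (edges) carrying ΔΔG_calc ± SE and the experimental ΔΔG.
Exact thermodynamics makes ΔΔG a state function: the signed sum around any
closed cycle is zero, so nonzero cycle sums (hysteresis) diagnose error —
though a small cycle sum can hide large compensating per-leg errors, which
is why cycle reports also flag individual leg discrepancies.

Discrepancy accounting uses the mean signed error, MSE = ⟨ΔΔG_calc −
ΔΔG_exp⟩: negative means the calculation systematically overestimates the
binding improvement.  When a set of edges shares a common chemical change
(here, growing an alkyl group into a hydrophobic subpocket), a constant
offset derived from a reference pair can be applied to the whole set; the
MSE shifts by exactly the offset while correlation statistics are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TransformationEdge",
    "PerturbationNetwork",
    "CycleReport",
    "OffsetResult",
    "compose_path",
    "cycle_closure",
    "mean_signed_error",
    "directional_agreement",
    "directional_agreement_report",
    "apply_common_change_offset",
    "enumerate_hub_triangles",
]

SIGN_TIE_TOL = 1e-12


@dataclass(frozen=True)
class TransformationEdge:
    """Directed alchemical transformation ref → target with calc and exp ΔΔG."""

    ref_id: str
    target_id: str
    ddG_calc: float
    se_calc: float = 0.0
    ddG_exp: float = float("nan")
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ref_id == self.target_id:
            raise ValueError(f"self-edge not allowed: {self.ref_id!r}")
        if self.se_calc < 0:
            raise ValueError("se_calc must be non-negative")
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def edge_id(self) -> str:
        return f"{self.ref_id}~{self.target_id}"

    def reversed(self) -> "TransformationEdge":
        """The same transformation traversed backwards (ΔΔGs negated)."""
        return replace(
            self,
            ref_id=self.target_id,
            target_id=self.ref_id,
            ddG_calc=-self.ddG_calc,
            ddG_exp=-self.ddG_exp,
        )


class PerturbationNetwork:
    """Compound nodes plus transformation edges; parallel edges allowed."""

    def __init__(self, edges: Iterable[TransformationEdge]):
        self.edges: list[TransformationEdge] = list(edges)
        self.graph = nx.MultiDiGraph()
        for e in self.edges:
            self.graph.add_edge(e.ref_id, e.target_id, edge=e)

    @property
    def compounds(self) -> set[str]:
        return set(self.graph.nodes)

    def find_edge(self, a: str, b: str) -> tuple[TransformationEdge, int]:
        """Edge connecting a→b in either stored orientation.

        Returns (edge, direction) with direction +1 if stored as a→b and −1
        if stored as b→a (traversed backwards, ΔΔG negated by the caller).
        """
        if self.graph.has_edge(a, b):
            data = self.graph.get_edge_data(a, b)
            return data[next(iter(data))]["edge"], +1
        if self.graph.has_edge(b, a):
            data = self.graph.get_edge_data(b, a)
            return data[next(iter(data))]["edge"], -1
        raise KeyError(f"no edge between {a!r} and {b!r} in either orientation")


@dataclass(frozen=True)
class CycleReport:
    """Hysteresis accounting around one closed cycle."""

    nodes: tuple[str, ...]
    calc_sum: float
    discrepancy_sum: float
    leg_discrepancies: tuple[float, ...]
    flagged_legs: tuple[int, ...]
    flag_threshold: float

    def __post_init__(self) -> None:
        if self.nodes[0] != self.nodes[-1]:
            raise ValueError("cycle node sequence must close (first node = last node)")


def compose_path(
    network: PerturbationNetwork,
    nodes: Sequence[str],
) -> tuple[float, float]:
    """Signed ΔΔG and quadrature SE along a chain of nodes.

    Each consecutive pair must be connected by an edge in either
    orientation; traversing an edge against its stored direction negates
    its ΔΔG.  A missing link raises an error naming the gap.
    """
    if len(nodes) < 2:
        raise ValueError("a path needs at least two nodes")
    total = 0.0
    var = 0.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        try:
            edge, direction = network.find_edge(a, b)
        except KeyError as exc:
            raise ValueError(f"broken chain: no edge linking {a!r} to {b!r}") from exc
        total += direction * edge.ddG_calc
        var += edge.se_calc**2
    return total, float(np.sqrt(var))


def cycle_closure(
    network: PerturbationNetwork,
    nodes: Sequence[str],
    flag_threshold: float = 0.5,
) -> CycleReport:
    """Hysteresis and per-leg discrepancies around a closed node cycle.

    A hysteresis (calc sum) of zero is necessary but not sufficient for
    convergence: legs whose |calc − exp| exceeds ``flag_threshold``
    (kcal/mol) are flagged even when the cycle sum is small, since per-leg
    errors can cancel around the loop.
    """
    nodes = list(nodes)
    if nodes[0] != nodes[-1]:
        nodes = nodes + [nodes[0]]
    calc_sum = 0.0
    discrepancies: list[float] = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        try:
            edge, direction = network.find_edge(a, b)
        except KeyError as exc:
            raise ValueError(f"cycle is missing an edge between {a!r} and {b!r}") from exc
        calc_sum += direction * edge.ddG_calc
        discrepancies.append(direction * (edge.ddG_calc - edge.ddG_exp))
    flagged = tuple(
        i for i, d in enumerate(discrepancies) if np.isfinite(d) and abs(d) > flag_threshold
    )
    finite = [d for d in discrepancies if np.isfinite(d)]
    return CycleReport(
        nodes=tuple(nodes),
        calc_sum=calc_sum,
        discrepancy_sum=float(np.sum(finite)) if finite else float("nan"),
        leg_discrepancies=tuple(discrepancies),
        flagged_legs=flagged,
        flag_threshold=flag_threshold,
    )


def _require_exp(edges: Sequence[TransformationEdge]) -> None:
    if not edges:
        raise ValueError("edge subset is empty")
    for e in edges:
        if not np.isfinite(e.ddG_exp):
            raise ValueError(f"edge {e.edge_id} has no experimental value")


def mean_signed_error(edges: Sequence[TransformationEdge]) -> float:
    """Mean of (ΔΔG_calc − ΔΔG_exp) over the subset, kcal/mol.

    Negative values mean the calculations are systematically more negative
    than experiment, i.e. the predicted binding improvement is
    overestimated.
    """
    _require_exp(edges)
    return float(np.mean([e.ddG_calc - e.ddG_exp for e in edges]))


def directional_agreement_report(
    edges: Sequence[TransformationEdge],
) -> tuple[float, int, int]:
    """(fraction agreeing in sign, edges used, edges excluded as sign ties).

    An edge whose calculated or experimental ΔΔG is within 1e−12 of zero
    has no meaningful direction and is excluded from the denominator.
    """
    _require_exp(edges)
    used = 0
    agree = 0
    for e in edges:
        if abs(e.ddG_calc) < SIGN_TIE_TOL or abs(e.ddG_exp) < SIGN_TIE_TOL:
            continue
        used += 1
        if np.sign(e.ddG_calc) == np.sign(e.ddG_exp):
            agree += 1
    if used == 0:
        raise ValueError("all edges are sign ties; directional agreement undefined")
    return agree / used, used, len(edges) - used


def directional_agreement(edges: Sequence[TransformationEdge]) -> float:
    """Fraction of edges whose calculated ΔΔG has the experimental sign."""
    fraction, _, _ = directional_agreement_report(edges)
    return fraction


@dataclass(frozen=True)
class OffsetResult:
    """A common-change offset applied to an edge subset."""

    edges: tuple[TransformationEdge, ...]
    offset: float
    mode: str  # "supplied" or "fitted"
    mse_before: float
    mse_after: float


def apply_common_change_offset(
    edges: Sequence[TransformationEdge],
    offset: float | None = None,
    fit: bool = False,
) -> OffsetResult:
    """Shift every calculated ΔΔG in the subset by a constant offset.

    The offset is either supplied (e.g. the discrepancy of a reference pair
    that isolates the shared chemical change) or fitted as −MSE of the
    subset, which zeroes the post-correction MSE.  MSE after equals MSE
    before plus the offset — an exact identity that is asserted.  Pearson
    correlation of (calc, exp) is unaffected by any constant shift.
    """
    _require_exp(edges)
    if fit == (offset is not None):
        raise ValueError("supply exactly one of: an explicit offset, or fit=True")
    mse_before = mean_signed_error(edges)
    if fit:
        applied = -mse_before
        mode = "fitted"
    else:
        if not np.isfinite(offset):
            raise ValueError("offset must be finite")
        applied = float(offset)
        mode = "supplied"
    corrected = tuple(replace(e, ddG_calc=e.ddG_calc + applied) for e in edges)
    mse_after = mean_signed_error(corrected)
    assert abs(mse_after - (mse_before + applied)) < 1e-9
    return OffsetResult(
        edges=corrected, offset=applied, mode=mode, mse_before=mse_before, mse_after=mse_after
    )


def enumerate_hub_triangles(
    network: PerturbationNetwork,
    hubs: tuple[str, str],
) -> list[tuple[str, str, str, str]]:
    """Closed triangles hub1 → hub2 → X → hub1 through both hub compounds.

    X ranges over compounds connected (in either orientation) to both hubs;
    full cycle enumeration is exponential and deliberately not attempted.
    """
    h1, h2 = hubs
    und = network.graph.to_undirected(as_view=True)
    if not und.has_edge(h1, h2):
        return []
    shared = (set(und.neighbors(h1)) & set(und.neighbors(h2))) - {h1, h2}
    return [(h1, h2, x, h1) for x in sorted(shared)]
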