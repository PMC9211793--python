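"""Synthetic study generator with planted ground truth.

Molecular-dynamics energies for the ROS1 congeneric series were never
released, so every input the analysis consumes is generated here with known
truth: per-frame MMPBSA component tables for 25-replica end-point
ensembles, per-window ∂U/∂λ samples for 5-replica thermodynamic
integration, and a compound table mimicking the published series structure
(seven modification subgroups, pIC50 between 5.03 and 8.37, censored
compounds at the 5.00 floor, two hub compounds L30 and L2).

The planted values are constructed to be *quadrature-consistent*: each TI
leg's mean ∂U/∂λ profile is a smooth quadratic shifted so that its
trapezoidal integral over the requested λ schedule equals the planted leg
ΔG exactly.  Noiseless data therefore recover the planted ΔΔG to floating
precision regardless of quadrature error, and all noise enters as
replica-level offsets plus per-sample jitter, matching how independent
ensemble simulations scatter.

All generators are pure functions of their spec: one root seed, child
streams derived per (compound/edge, leg, window, replica), so enlarging an
ensemble never perturbs existing members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .esmacs import ENERGY_COMPONENTS

__all__ = [
    "DEFAULT_LAMBDA_SCHEDULE",
    "DEFAULT_SUBGROUP_SIZES",
    "TISeriesSpec",
    "EsmacsSeriesSpec",
    "CompoundSeriesSpec",
    "gen_ti_dataset",
    "gen_esmacs_dataset",
    "gen_compound_series",
    "edges_from_truth",
    "two_hub_pairs",
    "plant_affinities",
    "noise_sd_for_pearson",
]

#: 13-point schedule, densified near the endpoints where ⟨∂U/∂λ⟩ varies fastest.
DEFAULT_LAMBDA_SCHEDULE = (
    0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0,
)

#: Neutral-compound counts per modification subgroup in the emulated series.
DEFAULT_SUBGROUP_SIZES: dict[str, int] = {
    "0": 1, "1": 36, "2": 7, "3": 25, "4": 26, "14": 31, "34": 14,
}

_SUBGROUP_CATEGORIES: dict[str, tuple[int, ...]] = {
    "0": (), "1": (1,), "2": (2,), "3": (3,), "4": (4,), "14": (1, 4), "34": (3, 4),
}

_CENSORED_PIC50 = 5.00


# --------------------------------------------------------------------------
# thermodynamic integration inputs


@dataclass(frozen=True)
class TISeriesSpec:
    """Layout of a synthetic TI study: edges with planted ΔΔG plus noise levels."""

    edges: tuple[tuple[str, str, float], ...]  # (ref_id, target_id, true ΔΔG kcal/mol)
    lambda_schedule: tuple[float, ...] = DEFAULT_LAMBDA_SCHEDULE
    n_replicas: int = 5
    n_samples_per_window: int = 400
    within_replica_sd: float = 0.3
    between_replica_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((str(a), str(b), float(g)) for a, b, g in self.edges))
        object.__setattr__(self, "lambda_schedule", tuple(float(v) for v in self.lambda_schedule))
        lams = np.asarray(self.lambda_schedule)
        if lams.size < 2 or np.any(np.diff(lams) <= 0):
            raise ValueError("lambda schedule must be strictly increasing")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise ValueError("lambda schedule must start at 0 and end at 1")
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if self.n_samples_per_window < 1:
            raise ValueError("need at least 1 sample per window")
        if self.within_replica_sd < 0 or self.between_replica_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _leg_profile(
    rng: np.random.Generator, lams: np.ndarray, target_dg: float
) -> np.ndarray:
    """Quadratic ⟨∂U/∂λ⟩ profile whose trapezoidal integral equals target_dg.

    The shift trick works because the trapezoid weights over [0, 1] sum to
    one, so adding a constant moves the integral by exactly that constant.
    """
    a, b, c = rng.normal(0.0, 4.0, size=3)
    profile = a + b * lams + c * lams**2
    integral = float(np.trapezoid(profile, lams))
    return profile + (target_dg - integral)


def gen_ti_dataset(spec: TISeriesSpec) -> pd.DataFrame:
    """∂U/∂λ tables for both legs of every edge (long format).

    Columns: edge_id, leg, lambda, replica, frame, dudl.  For each edge the
    bound- and free-leg profiles are built so their trapezoidal integrals
    differ by exactly the planted ΔΔG (bound − free convention); replica
    offsets (SD = between_replica_sd) and per-sample jitter (SD =
    within_replica_sd) are added on top.
    """
    lams = np.asarray(spec.lambda_schedule)
    n_win, n_rep, n_smp = lams.size, spec.n_replicas, spec.n_samples_per_window

    edge_ids, legs_col, lam_col, rep_col, frame_col, dudl_col = [], [], [], [], [], []
    for ref, target, ddg in spec.edges:
        edge_id = f"{ref}~{target}"
        free_dg = float(child_rng(spec.seed, "ti-legbase", edge_id).normal(0.0, 3.0))
        leg_targets = {"free": free_dg, "bound": free_dg + ddg}
        for leg, target_dg in leg_targets.items():
            prof_rng = child_rng(spec.seed, "ti-profile", edge_id, leg)
            profile = _leg_profile(prof_rng, lams, target_dg)
            for w, lam in enumerate(lams):
                for rep in range(n_rep):
                    rng = child_rng(spec.seed, "ti-rep", edge_id, leg, w, rep)
                    offset = rng.normal(0.0, spec.between_replica_sd)
                    noise = rng.normal(0.0, spec.within_replica_sd, size=n_smp)
                    samples = profile[w] + offset + noise
                    edge_ids.append(np.full(n_smp, edge_id, dtype=object))
                    legs_col.append(np.full(n_smp, leg, dtype=object))
                    lam_col.append(np.full(n_smp, lam))
                    rep_col.append(np.full(n_smp, rep))
                    frame_col.append(np.arange(n_smp))
                    dudl_col.append(samples)

    return pd.DataFrame(
        {
            "edge_id": np.concatenate(edge_ids),
            "leg": np.concatenate(legs_col),
            "lambda": np.concatenate(lam_col),
            "replica": np.concatenate(rep_col).astype(int),
            "frame": np.concatenate(frame_col).astype(int),
            "dudl": np.concatenate(dudl_col),
        }
    )


# --------------------------------------------------------------------------
# end-point (ESMACS) inputs

#: Baseline component means, chosen at protein/ligand magnitudes so the
#: internal-energy cancellation in 1traj is exercised against large numbers.
_RECEPTOR_BASE = {
    "E_vdw": -820.0, "E_ele": -6450.0, "E_internal": 4875.0, "G_PB": -2600.0, "G_SA": 96.0,
}
_LIGAND_BASE = {
    "E_vdw": -6.0, "E_ele": -14.0, "E_internal": 38.0, "G_PB": -18.0, "G_SA": 4.5,
}
#: How the planted interaction free energy is split across components.  No
#: internal term: interaction internal energy is identically zero, which is
#: what makes the 1traj ΔE_internal cancellation exact.
_INTERACTION_SPLIT = {
    "E_vdw": 0.45, "E_ele": 0.25, "E_internal": 0.0, "G_PB": 0.25, "G_SA": 0.05,
}
DEFAULT_COMPONENT_NOISE = {
    "E_vdw": 0.8, "E_ele": 1.5, "E_internal": 3.0, "G_PB": 1.2, "G_SA": 0.3,
}

#: Internal-energy streams are snapped to this grid (≈1e-6 kcal/mol, below
#: any physical signal).  Receptor and ligand internal energies then sum
#: exactly in floating point, so the 1traj internal-energy cancellation is
#: bit-exact even in the presence of noise — as it is for real
#: single-trajectory extraction, where the complex file *is* the sum.
_INTERNAL_QUANTUM = 2.0**-20


def _quantize_internal(values: np.ndarray) -> np.ndarray:
    return np.round(values / _INTERNAL_QUANTUM) * _INTERNAL_QUANTUM


@dataclass(frozen=True)
class EsmacsSeriesSpec:
    """Synthetic end-point ensembles with planted binding free energies.

    ``true_affinity_map`` plants the mean interaction + solvation free
    energy per compound (what 1traj should recover);
    ``receptor_adaptation_offsets`` plants per-compound shifts of the mean
    receptor energy (what 1traj-ar should add back, relative to the series
    mean).  ``slope``/``intercept`` record the linear link between the true
    score and pIC50 used when the map was constructed.
    """

    true_affinity_map: Mapping[str, float]
    slope: float = -1.3726
    intercept: float = 0.0
    n_replicas: int = 25
    n_frames: int = 400
    component_noise_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_NOISE)
    )
    between_replica_sd: float = 1.0
    receptor_adaptation_offsets: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    n_compounds: int | None = None

    def __post_init__(self) -> None:
        if not self.true_affinity_map:
            raise ValueError("true_affinity_map must not be empty")
        if self.n_compounds is not None and self.n_compounds != len(self.true_affinity_map):
            raise ValueError("n_compounds disagrees with true_affinity_map")
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if self.n_frames < 1:
            raise ValueError("need at least 1 frame")
        if self.between_replica_sd < 0:
            raise ValueError("between_replica_sd must be non-negative")
        for comp, sd in self.component_noise_sds.items():
            if comp not in ENERGY_COMPONENTS:
                raise ValueError(f"unknown energy component {comp!r}")
            if sd < 0:
                raise ValueError(f"noise SD for {comp} must be non-negative")


def gen_esmacs_dataset(spec: EsmacsSeriesSpec) -> pd.DataFrame:
    """Per-frame energy tables per compound, species and replica.

    Columns: compound_id, species, replica, frame, E_vdw, E_ele,
    E_internal, G_PB, G_SA.  Receptor and ligand frames are generated
    first; complex frames are their component-wise sum plus an interaction
    term, exactly as single-trajectory extraction implies — so
    complex = receptor + ligand + interaction holds bit-for-bit, the
    interaction internal energy is identically zero, and the mean
    interaction + solvation energy per compound equals the planted truth.
    """
    sds = {c: float(spec.component_noise_sds.get(c, 0.0)) for c in ENERGY_COMPONENTS}
    n_f = spec.n_frames
    chunks: list[pd.DataFrame] = []

    for cid in sorted(spec.true_affinity_map):
        truth = float(spec.true_affinity_map[cid])
        adaptation = float(spec.receptor_adaptation_offsets.get(cid, 0.0))
        rec_mean = dict(_RECEPTOR_BASE)
        rec_mean["E_internal"] += adaptation
        int_mean = {c: truth * _INTERACTION_SPLIT[c] for c in ENERGY_COMPONENTS}

        for rep in range(spec.n_replicas):
            rng = child_rng(spec.seed, "esmacs", cid, rep)
            rep_offset = rng.normal(0.0, spec.between_replica_sd)
            rec = {c: rec_mean[c] + rng.normal(0.0, sds[c], n_f) for c in ENERGY_COMPONENTS}
            lig = {c: _LIGAND_BASE[c] + rng.normal(0.0, sds[c], n_f) for c in ENERGY_COMPONENTS}
            rec["E_internal"] = _quantize_internal(rec["E_internal"])
            lig["E_internal"] = _quantize_internal(lig["E_internal"])
            inter = {
                c: int_mean[c]
                + (rep_offset if c == "E_vdw" else 0.0)
                + (rng.normal(0.0, sds[c], n_f) if _INTERACTION_SPLIT[c] > 0 else np.zeros(n_f))
                for c in ENERGY_COMPONENTS
            }
            cplx = {c: rec[c] + lig[c] + inter[c] for c in ENERGY_COMPONENTS}

            for species, comp in (("complex", cplx), ("receptor", rec), ("ligand", lig)):
                chunk = pd.DataFrame(comp)
                chunk.insert(0, "frame", np.arange(n_f))
                chunk.insert(0, "replica", rep)
                chunk.insert(0, "species", species)
                chunk.insert(0, "compound_id", cid)
                chunks.append(chunk)

    return pd.concat(chunks, ignore_index=True)


# --------------------------------------------------------------------------
# compound series


@dataclass(frozen=True)
class CompoundSeriesSpec:
    """Layout of the congeneric series: subgroup sizes, activity range, censoring."""

    subgroup_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES)
    )
    pIC50_range: tuple[float, float] = (5.03, 8.37)
    n_charged: int = 10
    n_censored: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {str(k): int(v) for k, v in self.subgroup_sizes.items()}
        object.__setattr__(self, "subgroup_sizes", sizes)
        for code, count in sizes.items():
            if code not in _SUBGROUP_CATEGORIES:
                raise ValueError(f"unknown subgroup code {code!r}")
            if count < 0:
                raise ValueError("subgroup counts must be non-negative")
        lo, hi = self.pIC50_range
        if not lo < hi:
            raise ValueError("pIC50 range must have min < max")
        if self.n_charged < 0 or self.n_censored < 0:
            raise ValueError("counts must be non-negative")


def gen_compound_series(spec: CompoundSeriesSpec) -> pd.DataFrame:
    """Compound table with subgroup labels, activities, charge and censoring.

    Columns: compound_id, pIC50, charged, categories (comma-joined),
    censored, minor_cat3, subgroup.  The sole subgroup-0 compound is the
    hub L30; the first subgroup-1 compound is the hub L2.  In subgroup 14
    up to four compounds additionally carry a minor category-3 change (a
    single H→F substitution), mirroring how such compounds are grouped in
    practice.  Censored compounds get pIC50 = 5.00 and the censored flag.
    """
    rng = child_rng(spec.seed, "compounds")
    rows: list[dict] = []
    next_num = 1

    def fresh_id() -> str:
        nonlocal next_num
        while next_num in (2, 30):  # reserved for the hubs
            next_num += 1
        cid = f"L{next_num}"
        next_num += 1
        return cid

    for code in sorted(spec.subgroup_sizes, key=lambda c: (len(c), c)):
        count = spec.subgroup_sizes[code]
        cats = _SUBGROUP_CATEGORIES[code]
        n_minor = min(4, count - 1) if code == "14" else 0
        for i in range(count):
            if code == "0" and i == 0:
                cid = "L30"
            elif code == "1" and i == 0:
                cid = "L2"
            else:
                cid = fresh_id()
            minor = i < n_minor
            rows.append(
                {
                    "compound_id": cid,
                    "charged": 0,
                    "categories": ",".join(map(str, (1, 3, 4) if minor else cats)),
                    "minor_cat3": int(minor),
                    "subgroup": code,
                }
            )

    charged_codes = [c for c in sorted(spec.subgroup_sizes) if c != "0"] or ["1"]
    for _ in range(spec.n_charged):
        code = charged_codes[int(rng.integers(len(charged_codes)))]
        rows.append(
            {
                "compound_id": fresh_id(),
                "charged": 1,
                "categories": ",".join(map(str, _SUBGROUP_CATEGORIES[code])),
                "minor_cat3": 0,
                "subgroup": code,
            }
        )

    table = pd.DataFrame(rows)
    lo, hi = spec.pIC50_range
    table["pIC50"] = rng.uniform(lo, hi, size=len(table))
    table["censored"] = 0

    eligible = [i for i, r in table.iterrows() if r["compound_id"] not in ("L30", "L2")]
    if spec.n_censored > len(eligible):
        raise ValueError("more censored compounds requested than non-hub compounds")
    censored_idx = rng.choice(eligible, size=spec.n_censored, replace=False)
    table.loc[censored_idx, "pIC50"] = _CENSORED_PIC50
    table.loc[censored_idx, "censored"] = 1

    # the spec range is the *observed* assay range: pin the measured extremes
    measured = table.index[table["censored"] == 0]
    if len(measured) >= 2:
        table.loc[table.loc[measured, "pIC50"].idxmin(), "pIC50"] = lo
        table.loc[table.loc[measured, "pIC50"].idxmax(), "pIC50"] = hi

    cols = ["compound_id", "pIC50", "charged", "categories", "censored", "minor_cat3", "subgroup"]
    return table[cols]


# --------------------------------------------------------------------------
# layout and truth helpers


def edges_from_truth(
    pairs: Sequence[tuple[str, str]],
    truth_map: Mapping[str, float],
) -> list[tuple[str, str, float]]:
    """Edge truths ΔΔG(a→b) = g(b) − g(a) from per-compound absolute scores.

    Built this way the planted network is exactly cycle-consistent: every
    closed loop of planted ΔΔG values sums to zero.
    """
    return [(a, b, float(truth_map[b]) - float(truth_map[a])) for a, b in pairs]


def two_hub_pairs(
    compound_ids: Sequence[str],
    hubs: tuple[str, str] = ("L30", "L2"),
    n_shared: int = 17,
) -> list[tuple[str, str]]:
    """Star-of-two-hubs pairing: hub→hub, shared targets on both hubs, rest split.

    The first ``n_shared`` non-hub compounds are paired with both hubs
    (enabling closed hub triangles); the remainder alternate between the
    hubs.  With 85 non-hub compounds and 17 shared this yields the familiar
    1 + 2·17 + 68 = 103-edge layout.
    """
    h1, h2 = hubs
    others = [c for c in compound_ids if c not in hubs]
    if n_shared > len(others):
        raise ValueError("n_shared exceeds the number of non-hub compounds")
    pairs: list[tuple[str, str]] = [(h1, h2)]
    for c in others[:n_shared]:
        pairs.append((h1, c))
        pairs.append((h2, c))
    for i, c in enumerate(others[n_shared:]):
        pairs.append((h1, c) if i % 2 == 0 else (h2, c))
    return pairs


def noise_sd_for_pearson(slope: float, pic50_sd: float, r: float) -> float:
    """Score-noise SD giving population Pearson |r| for a linear score–pIC50 link."""
    if not 0 < abs(r) <= 1:
        raise ValueError("r must lie in (0, 1]")
    return abs(slope) * pic50_sd * math.sqrt(1.0 / r**2 - 1.0)


def plant_affinities(
    compounds: pd.DataFrame,
    slope: float = -1.3726,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """True binding scores linked linearly to pIC50 plus Gaussian scatter.

    The default slope −1.3726 kcal/mol per log unit is −RT·ln10 at 300 K,
    so a noiseless map reproduces the experimental free energies exactly.
    """
    rng = child_rng(seed, "plant-affinities")
    scores = (
        slope * compounds["pIC50"].to_numpy()
        + intercept
        + rng.normal(0.0, noise_sd, size=len(compounds))
    )
    return dict(zip(compounds["compound_id"].astype(str), map(float, scores)))
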