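"""ESMACS end-point binding free energy estimation.

The estimator is MMPBSA without an entropy term: a frame's free energy is
the sum of its molecular-mechanics components (van der Waals, electrostatic,
internal) and implicit-solvent terms (Poisson–Boltzmann polar, surface-area
nonpolar).  In the 1traj protocol the complex, receptor and ligand
conformations are all extracted from the complex trajectory, so per frame

    ΔG_frame = G(complex) − G(receptor) − G(ligand)

and the large, noisy internal-energy terms cancel exactly.  Frames are
averaged within each replica, replicas averaged with equal weight, and the
uncertainty is a bootstrap over replica means (frames within a replica are
autocorrelated, so resampling is done at the replica level only).

1traj-ar adds a receptor adaptation energy expressed relative to the series:
the per-compound mean receptor energy minus the grand mean over compounds.
Because the planted offsets are independent of the interaction energies,
this widens the spread of the estimates; relative adaptations sum to zero
across the series by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stable_hash

__all__ = [
    "SPECIES",
    "ENERGY_COMPONENTS",
    "EnergyFrame",
    "EnsembleEstimate",
    "AdaptationTable",
    "frame_free_energy",
    "bootstrap_se",
    "one_traj_estimate",
    "receptor_adaptation_relative",
    "one_traj_ar_estimate",
    "analyze_energy_table",
]

SPECIES = ("complex", "receptor", "ligand")
ENERGY_COMPONENTS = ("E_vdw", "E_ele", "E_internal", "G_PB", "G_SA")
MM_COMPONENTS = ("E_vdw", "E_ele", "E_internal")


@dataclass(frozen=True)
class EnergyFrame:
    """MM + solvation components of one trajectory frame, kcal/mol."""

    species: str
    replica: int
    frame: int
    E_vdw: float
    E_ele: float
    E_internal: float
    G_PB: float
    G_SA: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")


@dataclass(frozen=True)
class EnsembleEstimate:
    """A free energy with replica provenance and bootstrap uncertainty."""

    value: float
    se: float
    n_replicas: int
    replica_means: tuple[float, ...]
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n_replicas != len(self.replica_means):
            raise ValueError("n_replicas must equal len(replica_means)")
        if self.replica_means and not np.isclose(
            self.value, float(np.mean(self.replica_means)), rtol=1e-9, atol=1e-9
        ):
            raise ValueError("value must equal the mean of replica_means")


@dataclass(frozen=True)
class AdaptationTable:
    """Per-compound receptor adaptation energies relative to the series mean."""

    mean_receptor_energy: Mapping[str, float]
    grand_mean: float
    relative_adaptation: Mapping[str, float]
    se: Mapping[str, float]


class DataError(ValueError):
    """Raised for non-finite or malformed energy data."""


def frame_free_energy(frame) -> float | pd.Series:
    """MMPBSA free energy of a frame: ΣE_MM + G_PB + G_SA, no entropy term.

    Accepts an :class:`EnergyFrame` (returns float) or a DataFrame with the
    component columns (returns a Series, one value per row).  A non-finite
    component raises :class:`DataError` naming the offending column.
    """
    if isinstance(frame, pd.DataFrame):
        for col in ENERGY_COMPONENTS:
            if col not in frame.columns:
                raise DataError(f"missing energy column {col!r}")
            values = pd.to_numeric(frame[col], errors="coerce")
            if not np.isfinite(values).all():
                raise DataError(f"non-finite value in column {col!r}")
        return frame[list(ENERGY_COMPONENTS)].sum(axis=1)
    total = 0.0
    for col in ENERGY_COMPONENTS:
        value = float(getattr(frame, col))
        if not np.isfinite(value):
            raise DataError(f"non-finite value in component {col!r}")
        total += value
    return total


def bootstrap_se(
    replica_means: Sequence[float],
    B: int = 5000,
    seed: int = 0,
) -> float:
    """Bootstrap SE of the ensemble mean from replica means.

    Resamples the replica means with replacement B times and returns the SD
    of the resampled means.  Values are put in canonical (sorted) order
    before resampling so the result is invariant to replica labelling for a
    fixed seed.
    """
    values = np.sort(np.asarray(replica_means, dtype=float))
    if values.size < 2:
        raise ValueError("bootstrap requires at least two replica means")
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    return float(np.std(values[idx].mean(axis=1), ddof=1))


def _replica_component_means(df: pd.DataFrame) -> pd.DataFrame:
    """Per-replica means of each energy component (rows indexed by replica)."""
    return df.groupby("replica", sort=True)[list(ENERGY_COMPONENTS)].mean()


def one_traj_estimate(
    frames: pd.DataFrame,
    B: int = 5000,
    seed: int = 0,
    discard_frames: int = 0,
) -> EnsembleEstimate:
    """1traj estimate for one compound from its complex/receptor/ligand frames.

    ``frames`` holds all three species for a single compound with columns
    species, replica, frame and the five energy components; the (replica,
    frame) index sets must match across species.  ``discard_frames`` drops
    the first N frames of each replica (equilibration carry-over) before
    averaging.
    """
    if discard_frames:
        cutoff = frames.groupby(["species", "replica"])["frame"].transform(
            lambda f: np.sort(f)[min(discard_frames, len(f) - 1)]
        )
        frames = frames[frames["frame"] >= cutoff]

    frame_free_energy(frames)  # validates components are present and finite

    by_species = {}
    for sp in SPECIES:
        sub = frames[frames["species"] == sp]
        if sub.empty:
            raise ValueError(f"no frames for species {sp!r}")
        by_species[sp] = sub.set_index(["replica", "frame"])

    index = by_species["complex"].index
    for sp in ("receptor", "ligand"):
        missing = index.symmetric_difference(by_species[sp].index)
        if len(missing):
            pairs = sorted(missing.tolist())[:10]
            raise ValueError(
                f"(replica, frame) sets differ between complex and {sp}; "
                f"first mismatches: {pairs}"
            )

    cols = list(ENERGY_COMPONENTS)
    delta = (
        by_species["complex"][cols]
        - by_species["receptor"].loc[index, cols]
        - by_species["ligand"].loc[index, cols]
    ).reset_index()

    rep_means = _replica_component_means(delta)
    rep_totals = rep_means.sum(axis=1)
    value = float(rep_totals.mean())
    se = bootstrap_se(rep_totals.to_numpy(), B=B, seed=seed)
    components = {f"d{c}": float(rep_means[c].mean()) for c in ENERGY_COMPONENTS}
    return EnsembleEstimate(
        value=value,
        se=se,
        n_replicas=len(rep_totals),
        replica_means=tuple(float(v) for v in rep_totals),
        components=components,
    )


def receptor_adaptation_relative(
    receptor_frames: pd.DataFrame,
    energy: str = "total",
    B: int = 5000,
    seed: int = 0,
) -> AdaptationTable:
    """Receptor adaptation energies relative to the series average.

    ``receptor_frames`` holds receptor-species frames for every compound
    (column compound_id).  Each compound's mean receptor energy is the
    replica-mean of frame-means; the relative adaptation is that mean minus
    the unweighted grand mean over compounds, so adaptations sum to zero.
    ``energy`` selects the full MMPBSA energy ("total") or the MM term alone
    ("mm_only").
    """
    if energy not in ("total", "mm_only"):
        raise ValueError(f"energy must be 'total' or 'mm_only', got {energy!r}")
    cols = list(ENERGY_COMPONENTS if energy == "total" else MM_COMPONENTS)

    compounds = sorted(receptor_frames["compound_id"].unique())
    if len(compounds) < 2:
        raise ValueError("relative adaptation is undefined for a single compound")

    means: dict[str, float] = {}
    ses: dict[str, float] = {}
    for cid in compounds:
        sub = receptor_frames[receptor_frames["compound_id"] == cid]
        rep_totals = sub.groupby("replica", sort=True)[cols].mean().sum(axis=1)
        means[cid] = float(rep_totals.mean())
        cid_seed = (int(seed) + stable_hash(("adaptation", cid))) % (2**31)
        ses[cid] = (
            bootstrap_se(rep_totals.to_numpy(), B=B, seed=cid_seed)
            if len(rep_totals) > 1
            else 0.0
        )
    grand = float(np.mean(list(means.values())))
    relative = {cid: means[cid] - grand for cid in compounds}
    return AdaptationTable(
        mean_receptor_energy=means, grand_mean=grand, relative_adaptation=relative, se=ses
    )


def one_traj_ar_estimate(
    one_traj: EnsembleEstimate,
    adaptation: float,
    adaptation_se: float = 0.0,
) -> EnsembleEstimate:
    """1traj-ar: shift a 1traj estimate by the relative receptor adaptation.

    The adaptation SE (bootstrap over the receptor replica means) combines
    with the 1traj SE in quadrature.
    """
    if not (np.isfinite(adaptation) and np.isfinite(adaptation_se)):
        raise ValueError("adaptation and its SE must be finite")
    return EnsembleEstimate(
        value=one_traj.value + adaptation,
        se=float(np.hypot(one_traj.se, adaptation_se)),
        n_replicas=one_traj.n_replicas,
        replica_means=tuple(m + adaptation for m in one_traj.replica_means),
        components={**one_traj.components, "adaptation": float(adaptation)},
    )


def analyze_energy_table(
    table: pd.DataFrame,
    protocol: str = "1traj",
    B: int = 5000,
    seed: int = 0,
    discard_frames: int = 0,
    adaptation_energy: str = "total",
) -> pd.DataFrame:
    """Per-compound ESMACS estimates from a multi-compound energy table.

    Returns a DataFrame with compound_id, dG, se, n_replicas and the
    component breakdown.  ``protocol`` is "1traj" or "1traj-ar".
    """
    if protocol not in ("1traj", "1traj-ar"):
        raise ValueError(f"protocol must be '1traj' or '1traj-ar', got {protocol!r}")

    estimates: dict[str, EnsembleEstimate] = {}
    for cid, sub in table.groupby("compound_id", sort=True):
        cid_seed = (int(seed) + stable_hash(("1traj", cid))) % (2**31)
        estimates[str(cid)] = one_traj_estimate(
            sub, B=B, seed=cid_seed, discard_frames=discard_frames
        )

    if protocol == "1traj-ar":
        receptor = table[table["species"] == "receptor"]
        adap = receptor_adaptation_relative(
            receptor, energy=adaptation_energy, B=B, seed=seed
        )
        estimates = {
            cid: one_traj_ar_estimate(
                est, adap.relative_adaptation[cid], adap.se[cid]
            )
            for cid, est in estimates.items()
        }

    rows = []
    for cid, est in estimates.items():
        row = {"compound_id": cid, "dG": est.value, "se": est.se, "n_replicas": est.n_replicas}
        row.update(est.components)
        rows.append(row)
    return pd.DataFrame(rows)
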