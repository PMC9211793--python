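"""Congeneric-series evaluation: affinity conversion, subgrouping, ranking.

Experimental activities arrive as pIC50 (−log10 IC50).  For comparison with
calculated free energies they are converted with ΔG = −RT·ln(10)·pIC50, so
one log unit corresponds to ≈1.37 kcal/mol at 300 K.  Compounds are
stratified by net charge and by where their scaffold is modified
(modification categories 1–4: ether at the hydrophobic position, pyridyl at
the hinge, central aryl at the bridge, lactam substituent at the solvent
position), and calculated-vs-experimental agreement is summarised per
stratum with Pearson r, Spearman ρ, Kendall τ-b and the sample covariance.

Censored compounds — those with no detectable activity, recorded at the
pIC50 floor of 5.00 — are kept in the headline statistics, with a
sensitivity rerun excluding them reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CENSORED_PIC50",
    "Compound",
    "RankingStats",
    "SubgroupReport",
    "pic50_to_dg",
    "pic50_span",
    "assign_subgroup",
    "ranking_stats",
    "evaluate_series",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol·K)
CENSORED_PIC50 = 5.00

#: category set → subgroup code; {1,3,4} maps to 14 only when the
#: category-3 change is minor (a single H→F substitution).
_SUBGROUP_CODES: dict[frozenset[int], str] = {
    frozenset(): "0",
    frozenset({1}): "1",
    frozenset({2}): "2",
    frozenset({3}): "3",
    frozenset({4}): "4",
    frozenset({3, 4}): "34",
    frozenset({1, 4}): "14",
}


@dataclass(frozen=True)
class Compound:
    compound_id: str
    pIC50: float
    charged: bool = False
    categories: frozenset[int] = frozenset()
    censored: bool = False
    minor_cat3: bool = False

    def __post_init__(self) -> None:
        if self.pIC50 < 0:
            raise ValueError("pIC50 must be non-negative")
        if self.censored and not np.isclose(self.pIC50, CENSORED_PIC50):
            raise ValueError(f"censored compounds carry pIC50 = {CENSORED_PIC50}")
        object.__setattr__(self, "categories", frozenset(self.categories))


@dataclass(frozen=True)
class RankingStats:
    pearson_r: float
    spearman_rho: float
    kendall_tau: float
    covariance: float


@dataclass(frozen=True)
class SubgroupReport:
    code: str
    n: int
    stats: RankingStats | None
    note: str = ""
    n_censored: int = 0
    stats_excluding_censored: RankingStats | None = None


def pic50_to_dg(pic50, T: float = 300.0):
    """Binding free energy −RT·ln(10)·pIC50 in kcal/mol (scalar or array).

    Differences of outputs are experimental ΔΔG values; the mapping is
    linear and strictly decreasing in pIC50.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    dg = -GAS_CONSTANT_KCAL * T * np.log(10.0) * np.asarray(pic50, dtype=float) + 0.0
    return float(dg) if np.ndim(pic50) == 0 else dg


def pic50_span(pic50s: Iterable[float]) -> float:
    """max − min of the series' pIC50 values, in log units."""
    values = np.asarray(list(pic50s), dtype=float)
    if values.size == 0:
        raise ValueError("empty pIC50 series")
    return float(values.max() - values.min())


def assign_subgroup(compound: Compound) -> str:
    """Modification-category subgroup code of a compound.

    Single categories give codes "1"–"4", the empty set "0", {3,4} → "34"
    and {1,4} → "14".  A {1,3,4} compound whose category-3 change is a lone
    H→F substitution is grouped into "14" (the change is too minor to
    matter); any other combination is "unclassified" with a warning.
    """
    cats = frozenset(compound.categories)
    if cats in _SUBGROUP_CODES:
        return _SUBGROUP_CODES[cats]
    if cats == frozenset({1, 3, 4}) and compound.minor_cat3:
        return "14"
    warnings.warn(
        f"compound {compound.compound_id}: category set {sorted(cats)} has no "
        "subgroup code; labelled 'unclassified'",
        stacklevel=2,
    )
    return "unclassified"


def ranking_stats(calc: Sequence[float], exp: Sequence[float]) -> RankingStats:
    """Pearson r, Spearman ρ (mid-ranks), Kendall τ-b and sample covariance.

    Both series must have equal length ≥ 3 and be non-constant (correlation
    coefficients are undefined for a constant series).  Covariance uses the
    n−1 denominator and is reported on the kcal/mol scale (kcal²/mol²).
    """
    x = np.asarray(calc, dtype=float)
    y = np.asarray(exp, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 points for ranking statistics")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    tau = stats.kendalltau(x, y, variant="b").statistic
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return RankingStats(float(r), float(rho), float(tau), cov)


def _stratum_members(compounds: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return compounds
    if stratum == "charged":
        return compounds[compounds["charged"].astype(bool)]
    if stratum == "neutral":
        return compounds[~compounds["charged"].astype(bool)]
    codes = stratum.split("+")
    return compounds[
        (~compounds["charged"].astype(bool)) & compounds["subgroup"].isin(codes)
    ]


def _safe_stats(calc: np.ndarray, exp: np.ndarray) -> RankingStats | None:
    try:
        return ranking_stats(calc, exp)
    except ValueError:
        return None


def evaluate_series(
    compounds: pd.DataFrame,
    estimates: Mapping[str, float] | pd.DataFrame,
    strata: Sequence[str] = ("all", "charged", "neutral"),
    temperature: float = 300.0,
) -> list[SubgroupReport]:
    """Per-stratum agreement between calculated and experimental ΔG.

    ``compounds`` is the series table (compound_id, pIC50, charged,
    censored, and subgroup — derived from categories if absent);
    ``estimates`` maps compound_id to calculated ΔG (or is a DataFrame with
    compound_id/dG columns).  Subgroup strata such as "1", "14" or "1+14"
    contain neutral compounds only, matching how the series is reported.
    Censored compounds stay in the headline statistics; each report carries
    a sensitivity recomputation without them.
    """
    compounds = compounds.copy()
    if "subgroup" not in compounds.columns:
        compounds["subgroup"] = [
            assign_subgroup(
                Compound(
                    compound_id=str(row.compound_id),
                    pIC50=float(row.pIC50),
                    charged=bool(row.charged),
                    categories=_parse_categories(row.categories),
                    censored=bool(row.censored),
                    minor_cat3=bool(getattr(row, "minor_cat3", False)),
                )
            )
            for row in compounds.itertuples()
        ]
    if isinstance(estimates, pd.DataFrame):
        estimates = dict(zip(estimates["compound_id"].astype(str), estimates["dG"]))

    missing = set(compounds["compound_id"].astype(str)) - set(estimates)
    reports: list[SubgroupReport] = []
    for stratum in strata:
        members = _stratum_members(compounds, stratum)
        lacking = set(members["compound_id"].astype(str)) & missing
        if lacking:
            raise ValueError(
                f"stratum {stratum!r}: no estimate for {sorted(lacking)[:5]}"
            )
        n = len(members)
        n_censored = int(members["censored"].astype(bool).sum())
        if n < 3:
            reports.append(
                SubgroupReport(stratum, n, None, note="insufficient n", n_censored=n_censored)
            )
            continue
        calc = np.asarray([estimates[str(c)] for c in members["compound_id"]])
        exp = pic50_to_dg(members["pIC50"].to_numpy(), T=temperature)
        headline = _safe_stats(calc, exp)
        note = "" if headline is not None else "undefined (constant series)"
        kept = ~members["censored"].astype(bool).to_numpy()
        sensitivity = None
        if n_censored and kept.sum() >= 3:
            sensitivity = _safe_stats(calc[kept], exp[kept])
        reports.append(
            SubgroupReport(
                code=stratum,
                n=n,
                stats=headline,
                note=note,
                n_censored=n_censored,
                stats_excluding_censored=sensitivity,
            )
        )
    return reports


def _parse_categories(value) -> frozenset[int]:
    """Parse a comma-joined category string (or iterable) into a set of ints."""
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(int(v) for v in value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(",") if tok.strip())
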