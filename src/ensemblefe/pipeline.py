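"""End-to-end pipeline: generate → end-point/TI analysis → network → series report.

A run is described by a YAML config (see ``RunConfig``).  The generator
plants per-compound truth; the two free-energy engines recover it; the
network stage does discrepancy accounting and offset correction; the
series stage reports ranking statistics per stratum.  Identical config and
seed give byte-identical outputs (all floats are serialised with a pinned
format), and every run writes a manifest recording the config hash, input
and output checksums, per-stage runtimes and the seeds consumed.

The generated study includes a deliberate systematic bias: compounds
carrying the common hydrophobic-group change are shifted on the calculated
side by ``common_change_bias`` kcal/mol, so edges from the hub lacking the
group (L30) inherit the bias while edges between group-carrying compounds
cancel it — reproducing the situation in which a single reference-pair
discrepancy can correct a whole edge subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as efio
from ._rng import child_rng
from .esmacs import analyze_energy_table
from .network import (
    PerturbationNetwork,
    TransformationEdge,
    apply_common_change_offset,
    cycle_closure,
    directional_agreement_report,
    enumerate_hub_triangles,
    mean_signed_error,
)
from .series import GAS_CONSTANT_KCAL, evaluate_series, pic50_to_dg
from .synthetic import (
    DEFAULT_LAMBDA_SCHEDULE,
    CompoundSeriesSpec,
    EsmacsSeriesSpec,
    TISeriesSpec,
    edges_from_truth,
    gen_compound_series,
    gen_esmacs_dataset,
    gen_ti_dataset,
    plant_affinities,
    two_hub_pairs,
)
from .ties import analyze_dudl_table

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "COMMON_CHANGE_TAG"]

log = logging.getLogger("ensemblefe")

COMMON_CHANGE_TAG = "common-change:CH->iPr"


@dataclass
class RunConfig:
    """Validated run configuration; CLI flags override YAML keys."""

    out_dir: str
    seed: int
    bootstrap: int = 1000
    temperature: float = 300.0
    # compound series
    subgroup_sizes: dict = field(default_factory=dict)  # empty → generator default
    pic50_range: tuple[float, float] = (5.03, 8.37)
    n_charged: int = 10
    n_censored: int = 5
    score_noise_sd: float = 0.6  # scatter of true score about the pIC50 line
    # end-point ensembles
    protocol: str = "1traj"
    adaptation_energy: str = "total"
    esmacs_n_replicas: int = 25
    esmacs_n_frames: int = 400
    esmacs_between_replica_sd: float = 1.0
    adaptation_offset_sd: float = 2.0
    discard_frames: int = 0
    # TI ensembles
    lambda_schedule: tuple[float, ...] = DEFAULT_LAMBDA_SCHEDULE
    ti_n_replicas: int = 5
    ti_n_samples: int = 400
    ti_within_sd: float = 0.3
    ti_between_sd: float = 0.2
    n_shared_targets: int = 17
    common_change_bias: float = -1.28
    hubs: tuple[str, str] = ("L30", "L2")
    # network
    flag_threshold: float = 0.5
    offset_mode: str = "reference-pair"  # "reference-pair" | "fit" | a number
    # series
    strata: tuple[str, ...] = ("all", "charged", "neutral", "1", "14", "1+14")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (every stochastic stage consumes it)")
        if self.bootstrap < 100:
            raise ValueError("bootstrap resamples must be >= 100")
        if self.protocol not in ("1traj", "1traj-ar"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.offset_mode not in ("reference-pair", "fit"):
            try:
                float(self.offset_mode)
            except (TypeError, ValueError):
                raise ValueError(
                    "offset_mode must be 'reference-pair', 'fit', or a number"
                ) from None
        self.out_dir = str(self.out_dir)
        self.hubs = tuple(self.hubs)
        self.strata = tuple(self.strata)
        self.lambda_schedule = tuple(float(v) for v in self.lambda_schedule)
        self.pic50_range = tuple(float(v) for v in self.pic50_range)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str]  # relative path → sha256
    stage_runtimes: dict[str, float]
    stages: list[str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _has_common_group(row) -> bool:
    """Whether a compound carries the shared hydrophobic-group change."""
    cats = {int(t) for t in str(row.categories).split(",") if t.strip()}
    return 1 in cats or row.compound_id == "L2"


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest written alongside the outputs."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    runtimes: dict[str, float] = {}
    stages: list[str] = []
    rt_ln10 = GAS_CONSTANT_KCAL * config.temperature * np.log(10.0)

    def stage(name):
        stages.append(name)
        log.info("[%s] starting", name)
        return time.perf_counter()

    def done(name, t0):
        runtimes[name] = round(time.perf_counter() - t0, 4)
        log.info("[%s] finished in %.2fs", name, runtimes[name])

    try:
        # ---- generate -----------------------------------------------------
        t0 = stage("generate")
        series_kwargs = dict(
            pIC50_range=config.pic50_range,
            n_charged=config.n_charged,
            n_censored=config.n_censored,
            seed=config.seed,
        )
        if config.subgroup_sizes:
            series_kwargs["subgroup_sizes"] = config.subgroup_sizes
        cspec = CompoundSeriesSpec(**series_kwargs)
        compounds = gen_compound_series(cspec)
        outputs["compounds.tsv"] = efio.write_compound_table(compounds, out / "compounds.tsv")

        exp_dg = {
            str(r.compound_id): pic50_to_dg(r.pIC50, T=config.temperature)
            for r in compounds.itertuples()
        }
        truth = plant_affinities(
            compounds,
            slope=-rt_ln10,
            noise_sd=config.score_noise_sd,
            seed=config.seed,
        )
        adapt_rng = child_rng(config.seed, "adaptation-offsets")
        adaptation = {
            cid: float(adapt_rng.normal(0.0, config.adaptation_offset_sd))
            for cid in sorted(truth)
        }
        espec = EsmacsSeriesSpec(
            true_affinity_map=truth,
            slope=-rt_ln10,
            n_replicas=config.esmacs_n_replicas,
            n_frames=config.esmacs_n_frames,
            between_replica_sd=config.esmacs_between_replica_sd,
            receptor_adaptation_offsets=adaptation,
            seed=config.seed,
        )
        energies = gen_esmacs_dataset(espec)
        outputs["energies.csv"] = efio.write_energy_table(energies, out / "energies.csv")

        neutral = compounds[~compounds["charged"].astype(bool)]
        has_group = {str(r.compound_id): _has_common_group(r) for r in compounds.itertuples()}
        calc_truth = {
            cid: exp_dg[cid] + (config.common_change_bias if has_group[cid] else 0.0)
            for cid in exp_dg
        }
        pairs = two_hub_pairs(
            list(neutral["compound_id"].astype(str)),
            hubs=config.hubs,
            n_shared=min(config.n_shared_targets, max(len(neutral) - 2, 0)),
        )
        ti_edges = edges_from_truth(pairs, calc_truth)
        tspec = TISeriesSpec(
            edges=tuple(ti_edges),
            lambda_schedule=config.lambda_schedule,
            n_replicas=config.ti_n_replicas,
            n_samples_per_window=config.ti_n_samples,
            within_replica_sd=config.ti_within_sd,
            between_replica_sd=config.ti_between_sd,
            seed=config.seed,
        )
        dudl = gen_ti_dataset(tspec)
        outputs["dudl.csv"] = efio.write_dudl_table(dudl, out / "dudl.csv")
        done("generate", t0)

        # ---- esmacs -------------------------------------------------------
        t0 = stage("esmacs")
        estimates = analyze_energy_table(
            energies,
            protocol=config.protocol,
            B=config.bootstrap,
            seed=config.seed,
            discard_frames=config.discard_frames,
            adaptation_energy=config.adaptation_energy,
        )
        estimates_path = out / "esmacs_estimates.tsv"
        estimates.to_csv(estimates_path, sep="\t", index=False, float_format="%.6f")
        outputs["esmacs_estimates.tsv"] = estimates_path
        done("esmacs", t0)

        # ---- ties ---------------------------------------------------------
        t0 = stage("ties")
        edge_results = analyze_dudl_table(dudl, B=config.bootstrap, seed=config.seed)
        edges = []
        for r in edge_results:
            # the common change in its growing direction only: ref lacks the
            # hydrophobic group, target carries it (as in L30 -> L2)
            tag = (
                COMMON_CHANGE_TAG
                if not has_group[r.ref_id] and has_group[r.target_id]
                else ""
            )
            edges.append(
                TransformationEdge(
                    ref_id=r.ref_id,
                    target_id=r.target_id,
                    ddG_calc=r.ddG_calc,
                    se_calc=r.se,
                    ddG_exp=exp_dg[r.target_id] - exp_dg[r.ref_id],
                    tags=frozenset({tag} if tag else ()),
                )
            )
        edge_df = pd.DataFrame(
            {
                "edge_id": [e.edge_id for e in edges],
                "ref_id": [e.ref_id for e in edges],
                "target_id": [e.target_id for e in edges],
                "ddG_calc": [e.ddG_calc for e in edges],
                "se_calc": [e.se_calc for e in edges],
                "ddG_exp": [e.ddG_exp for e in edges],
                "tags": [";".join(sorted(e.tags)) for e in edges],
            }
        )
        outputs["edges.tsv"] = efio.write_edge_table(edge_df, out / "edges.tsv")
        done("ties", t0)

        # ---- network ------------------------------------------------------
        t0 = stage("network")
        report = network_report(
            edges,
            hubs=config.hubs,
            offset_mode=config.offset_mode,
            flag_threshold=config.flag_threshold,
        )
        network_path = out / "network_report.json"
        network_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        outputs["network_report.json"] = network_path
        done("network", t0)

        # ---- evaluate -----------------------------------------------------
        t0 = stage("evaluate")
        reports = evaluate_series(
            compounds,
            estimates,
            strata=config.strata,
            temperature=config.temperature,
        )
        series_payload = {
            "temperature_K": config.temperature,
            "convention": "experiment converted to ΔG via −RT·ln10·pIC50",
            "strata": [_report_payload(r) for r in reports],
        }
        series_path = out / "series_report.json"
        series_path.write_text(json.dumps(series_payload, indent=2, sort_keys=True) + "\n")
        outputs["series_report.json"] = series_path
        done("evaluate", t0)
    except Exception:
        log.error("pipeline aborted in stage %r; earlier outputs preserved", stages[-1])
        raise

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        outputs={name: _sha256(path) for name, path in outputs.items()},
        stage_runtimes=runtimes,
        stages=stages,
    )
    manifest.write(out / "manifest.json")
    return manifest


def network_report(
    edges: list[TransformationEdge],
    hubs: tuple[str, str] = ("L30", "L2"),
    offset_mode: str = "reference-pair",
    flag_threshold: float = 0.5,
) -> dict:
    """Discrepancy accounting for a two-hub perturbation network.

    Reports per-hub-subgroup mean signed error, directional agreement,
    hub-triangle cycle closure, and offset correction of the common-change
    subset.  ``offset_mode`` selects how the offset is obtained: from the
    hub→hub reference pair's discrepancy, fitted as −MSE of the subset, or
    supplied as a number.
    """
    net = PerturbationNetwork(edges)
    h1, h2 = hubs
    report: dict = {"n_edges": len(edges), "flag_threshold_kcal_mol": flag_threshold}

    for hub in hubs:
        sub = [e for e in edges if hub in (e.ref_id, e.target_id)]
        if sub:
            frac, used, excluded = directional_agreement_report(sub)
            report[f"hub_{hub}"] = {
                "n": len(sub),
                "mse_kcal_mol": mean_signed_error(sub),
                "directional_agreement": frac,
                "sign_ties_excluded": excluded,
            }
    frac, used, excluded = directional_agreement_report(edges)
    report["directional_agreement"] = frac
    report["directional_agreement_n_used"] = used
    report["sign_ties_excluded"] = excluded
    report["mse_kcal_mol"] = mean_signed_error(edges)

    triangles = enumerate_hub_triangles(net, hubs)
    cycle_payload = []
    for cyc in triangles:
        rep = cycle_closure(net, cyc, flag_threshold=flag_threshold)
        cycle_payload.append(
            {
                "nodes": list(rep.nodes),
                "calc_sum": rep.calc_sum,
                "discrepancy_sum": rep.discrepancy_sum,
                "flagged_legs": list(rep.flagged_legs),
            }
        )
    report["hub_triangles"] = cycle_payload

    common = [e for e in edges if COMMON_CHANGE_TAG in e.tags]
    if common:
        if offset_mode == "reference-pair":
            ref_edge, direction = net.find_edge(h1, h2)
            offset = -direction * (ref_edge.ddG_calc - ref_edge.ddG_exp)
            corrected = apply_common_change_offset(common, offset=offset)
            mode = "reference-pair"
        elif offset_mode == "fit":
            corrected = apply_common_change_offset(common, fit=True)
            mode = "fitted"
        else:
            corrected = apply_common_change_offset(common, offset=float(offset_mode))
            mode = "supplied"
        report["common_change"] = {
            "tag": COMMON_CHANGE_TAG,
            "n": len(common),
            "offset_mode": mode,
            "offset_kcal_mol": corrected.offset,
            "mse_before": corrected.mse_before,
            "mse_after": corrected.mse_after,
        }
    return report


def _report_payload(report) -> dict:
    payload = {
        "code": report.code,
        "n": report.n,
        "n_censored": report.n_censored,
        "note": report.note,
    }
    for label, s in (
        ("stats", report.stats),
        ("stats_excluding_censored", report.stats_excluding_censored),
    ):
        payload[label] = (
            None
            if s is None
            else {
                "pearson_r": s.pearson_r,
                "spearman_rho": s.spearman_rho,
                "kendall_tau": s.kendall_tau,
                "covariance": s.covariance,
            }
        )
    return payload
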