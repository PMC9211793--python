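"""Generator contracts: planted truth, decomposition, determinism."""

import numpy as np
import pandas as pd
import pytest

from ensemblefe.esmacs import ENERGY_COMPONENTS, one_traj_estimate
from ensemblefe.synthetic import (
    DEFAULT_LAMBDA_SCHEDULE,
    CompoundSeriesSpec,
    EsmacsSeriesSpec,
    TISeriesSpec,
    edges_from_truth,
    gen_compound_series,
    gen_esmacs_dataset,
    gen_ti_dataset,
    noise_sd_for_pearson,
    plant_affinities,
    two_hub_pairs,
)
from ensemblefe.ties import analyze_dudl_table

ZERO_NOISE = {c: 0.0 for c in ENERGY_COMPONENTS}


class TestTiGenerator:
    def test_noiseless_recovery_is_exact(self, noiseless_ti_table):
        table, truths = noiseless_ti_table
        for r in analyze_dudl_table(table, B=150, seed=0):
            assert r.ddG_calc == pytest.approx(truths[r.edge_id], abs=1e-9)

    def test_planted_reference_pair_value(self):
        spec = TISeriesSpec(
            edges=(("L30", "L2", -2.88),),
            n_samples_per_window=5,
            within_replica_sd=0.0,
            between_replica_sd=0.0,
            seed=1,
        )
        (result,) = analyze_dudl_table(gen_ti_dataset(spec), B=150, seed=0)
        assert result.ddG_calc == pytest.approx(-2.88, abs=1e-9)
        assert result.se == pytest.approx(0.0, abs=1e-9)

    def test_recovery_is_unbiased_over_many_edges(self):
        """Mean signed recovery error ≈ 0 within 3·SE (brute-force averaging)."""
        n_edges = 120
        rng = np.random.default_rng(0)
        truths = rng.normal(0.0, 2.0, n_edges)
        edges = tuple((f"R{i}", f"T{i}", float(t)) for i, t in enumerate(truths))
        spec = TISeriesSpec(
            edges=edges,
            n_samples_per_window=6,
            within_replica_sd=0.3,
            between_replica_sd=0.2,
            seed=23,
        )
        results = analyze_dudl_table(gen_ti_dataset(spec), B=120, seed=0)
        truth_map = {f"R{i}~T{i}": float(t) for i, t in enumerate(truths)}
        errors = np.array([r.ddG_calc - truth_map[r.edge_id] for r in results])
        se = errors.std(ddof=1) / np.sqrt(n_edges)
        assert abs(errors.mean()) < 3 * se

    def test_doubling_window_density_stays_within_trapezoid_bound(self):
        """Planted truth is quadrature-consistent on each schedule."""
        coarse = DEFAULT_LAMBDA_SCHEDULE
        fine = tuple(
            sorted(set(coarse) | {0.5 * (a + b) for a, b in zip(coarse[:-1], coarse[1:])})
        )
        results = {}
        for schedule in (coarse, fine):
            spec = TISeriesSpec(
                edges=(("A", "B", -2.0),),
                lambda_schedule=schedule,
                n_samples_per_window=4,
                within_replica_sd=0.0,
                between_replica_sd=0.0,
                seed=2,
            )
            (r,) = analyze_dudl_table(gen_ti_dataset(spec), B=150, seed=0)
            results[len(schedule)] = r.ddG_calc
        # coarse-grid trapezoid error bound for the quadratic profiles:
        # |error| ≤ Σ h³·max|f''|/12 with |f''| = 2|c| ≤ ~24 at coeff SD 4
        bound = sum(
            (b - a) ** 3 * 24.0 / 12.0 for a, b in zip(coarse[:-1], coarse[1:])
        )
        assert abs(results[len(coarse)] - results[len(fine)]) < max(bound, 1e-9)

    def test_same_seed_same_bytes(self):
        spec = TISeriesSpec(edges=(("A", "B", 1.0),), n_samples_per_window=4, seed=5)
        pd.testing.assert_frame_equal(gen_ti_dataset(spec), gen_ti_dataset(spec))

    def test_adding_replicas_preserves_existing_streams(self):
        base = TISeriesSpec(edges=(("A", "B", 1.0),), n_samples_per_window=4, n_replicas=3, seed=5)
        more = TISeriesSpec(edges=(("A", "B", 1.0),), n_samples_per_window=4, n_replicas=5, seed=5)
        small = gen_ti_dataset(base)
        big = gen_ti_dataset(more)
        merged = big[big["replica"] < 3].reset_index(drop=True)
        pd.testing.assert_frame_equal(small, merged)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            TISeriesSpec(edges=(("A", "B", 1.0),), lambda_schedule=(0.0, 0.5, 0.9))


class TestEsmacsGenerator:
    def test_complex_decomposes_bitwise(self):
        spec = EsmacsSeriesSpec(true_affinity_map={"A": -40.0}, n_replicas=3, n_frames=10, seed=7)
        table = gen_esmacs_dataset(spec)
        wide = table.pivot_table(
            index=["replica", "frame"], columns="species",
            values="E_internal", aggfunc="first",
        )
        # interaction carries no internal term, so complex = receptor + ligand
        assert (wide["complex"] == wide["receptor"] + wide["ligand"]).all()

    def test_noiseless_planted_value_exact(self, noiseless_esmacs_table):
        table, truth = noiseless_esmacs_table
        for cid, planted in truth.items():
            est = one_traj_estimate(table[table["compound_id"] == cid], B=150, seed=0)
            assert est.value == planted

    def test_planted_correlation_recovered(self):
        """r = 0.9 planted between score and pIC50 is recovered at n=67."""
        rng = np.random.default_rng(1)
        pic50 = rng.uniform(5.03, 8.37, 67)
        compounds = pd.DataFrame(
            {"compound_id": [f"L{i}" for i in range(67)], "pIC50": pic50}
        )
        sd = noise_sd_for_pearson(-1.3726, pic50.std(ddof=1), 0.9)
        hits = 0
        for seed in range(20):
            truth = plant_affinities(compounds, noise_sd=sd, seed=seed)
            scores = np.array([truth[f"L{i}"] for i in range(67)])
            r = np.corrcoef(scores, pic50)[0, 1]
            if -0.97 <= r <= -0.8:  # negative slope: lower ΔG = higher pIC50
                hits += 1
        assert hits >= 18

    def test_equal_adaptation_offsets_change_nothing_relative(self):
        truth = {"A": -40.0, "B": -30.0}
        kwargs = dict(
            true_affinity_map=truth, n_replicas=3, n_frames=4,
            component_noise_sds=ZERO_NOISE, between_replica_sd=0.0, seed=3,
        )
        flat = gen_esmacs_dataset(EsmacsSeriesSpec(**kwargs, receptor_adaptation_offsets={}))
        shifted = gen_esmacs_dataset(
            EsmacsSeriesSpec(**kwargs, receptor_adaptation_offsets={"A": 5.0, "B": 5.0})
        )
        for cid in truth:
            a = one_traj_estimate(flat[flat["compound_id"] == cid], B=150, seed=0)
            b = one_traj_estimate(shifted[shifted["compound_id"] == cid], B=150, seed=0)
            assert a.value == pytest.approx(b.value, abs=1e-9)

    def test_same_seed_same_bytes(self):
        spec = EsmacsSeriesSpec(true_affinity_map={"A": -40.0}, n_replicas=2, n_frames=5, seed=1)
        pd.testing.assert_frame_equal(gen_esmacs_dataset(spec), gen_esmacs_dataset(spec))


class TestCompoundGenerator:
    def test_default_fixture_subgroup_counts(self, default_compounds):
        neutral = default_compounds[default_compounds["charged"] == 0]
        counts = neutral["subgroup"].value_counts().to_dict()
        assert counts["1"] == 36
        assert counts["14"] == 31
        assert counts["1"] + counts["14"] == 67
        assert counts == {"1": 36, "14": 31, "4": 26, "3": 25, "34": 14, "2": 7, "0": 1}

    def test_hubs_present(self, default_compounds):
        ids = set(default_compounds["compound_id"])
        assert {"L30", "L2"} <= ids
        assert (
            default_compounds.loc[default_compounds["compound_id"] == "L30", "subgroup"].item()
            == "0"
        )

    def test_censoring_count_and_floor(self):
        table = gen_compound_series(CompoundSeriesSpec(n_censored=5, seed=3))
        censored = table[table["censored"] == 1]
        assert len(censored) == 5
        assert (censored["pIC50"] == 5.00).all()

    def test_single_subgroup_of_one(self):
        table = gen_compound_series(
            CompoundSeriesSpec(subgroup_sizes={"0": 1}, n_charged=0, n_censored=0, seed=0)
        )
        assert len(table) == 1
        assert table["subgroup"].item() == "0"

    def test_minor_cat3_compounds_sit_in_subgroup_14(self, default_compounds):
        minor = default_compounds[default_compounds["minor_cat3"] == 1]
        assert len(minor) == 4
        assert (minor["subgroup"] == "14").all()
        assert (minor["categories"] == "1,3,4").all()

    def test_same_seed_same_bytes(self):
        spec = CompoundSeriesSpec(seed=2)
        pd.testing.assert_frame_equal(gen_compound_series(spec), gen_compound_series(spec))


class TestLayoutHelpers:
    def test_edges_from_truth_are_cycle_consistent(self):
        truth = {"A": -10.0, "B": -12.5, "C": -9.0}
        edges = edges_from_truth([("A", "B"), ("B", "C"), ("C", "A")], truth)
        assert sum(g for _, _, g in edges) == pytest.approx(0.0, abs=1e-12)

    def test_two_hub_layout_sizes(self):
        ids = ["L30", "L2"] + [f"L{i}" for i in range(100, 185)]  # 85 others
        pairs = two_hub_pairs(ids, hubs=("L30", "L2"), n_shared=17)
        assert len(pairs) == 103
        assert pairs.count(("L30", "L2")) == 1
        both = [c for c in ids[2:] if ("L30", c) in pairs and ("L2", c) in pairs]
        assert len(both) == 17
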