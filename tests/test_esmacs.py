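"""End-point (1traj / 1traj-ar) estimation and replica bootstrap."""

import numpy as np
import pandas as pd
import pytest

from ensemblefe.esmacs import (
    ENERGY_COMPONENTS,
    DataError,
    EnergyFrame,
    analyze_energy_table,
    bootstrap_se,
    frame_free_energy,
    one_traj_ar_estimate,
    one_traj_estimate,
    receptor_adaptation_relative,
)
from ensemblefe.synthetic import EsmacsSeriesSpec, gen_esmacs_dataset

ZERO_NOISE = {c: 0.0 for c in ENERGY_COMPONENTS}


def _frame(species="complex", replica=0, frame=0, **components):
    values = dict.fromkeys(ENERGY_COMPONENTS, 0.0)
    values.update(components)
    return EnergyFrame(species=species, replica=replica, frame=frame, **values)


def _receptor_df(compound_values):
    """Receptor frames whose total energy per compound is as given (2 replicas)."""
    rows = []
    for cid, total in compound_values.items():
        for rep in range(2):
            rows.append(
                dict(
                    compound_id=cid, species="receptor", replica=rep, frame=0,
                    E_vdw=total, E_ele=0.0, E_internal=0.0, G_PB=0.0, G_SA=0.0,
                )
            )
    return pd.DataFrame(rows)


class TestFrameFreeEnergy:
    def test_zero_components(self):
        assert frame_free_energy(_frame()) == 0.0

    def test_component_sum(self):
        frame = _frame(E_vdw=-10.0, E_ele=-20.0, E_internal=100.0, G_PB=-35.0, G_SA=5.0)
        assert frame_free_energy(frame) == 40.0

    def test_nan_component_names_the_column(self):
        with pytest.raises(DataError, match="G_PB"):
            frame_free_energy(_frame(G_PB=float("nan")))


class TestBootstrapSe:
    def test_identical_replica_means_give_zero(self):
        assert bootstrap_se([3.0] * 10, B=500, seed=0) == 0.0

    def test_matches_closed_form_se_of_mean(self):
        rng = np.random.default_rng(42)
        means = rng.normal(0.0, 1.0, size=25)
        se = bootstrap_se(means, B=5000, seed=1)
        assert se == pytest.approx(0.2, rel=0.25)

    def test_seed_determinism_and_order_invariance(self):
        values = [1.0, -0.5, 2.2, 0.1, 0.9]
        assert bootstrap_se(values, B=500, seed=7) == bootstrap_se(values[::-1], B=500, seed=7)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se([1.0], B=500, seed=0)


class TestOneTraj:
    def test_zero_interaction_gives_zero_estimate(self):
        """When receptor+ligand equals complex frame-wise, everything cancels."""
        rng = np.random.default_rng(3)
        rows = []
        for rep in range(3):
            for fr in range(4):
                # dyadic values: receptor+ligand sums are exact in binary
                rec = dict(zip(ENERGY_COMPONENTS, (rng.normal(0, 50, 5) * 1024).round() / 1024))
                lig = dict(zip(ENERGY_COMPONENTS, (rng.normal(0, 5, 5) * 1024).round() / 1024))
                cplx = {c: rec[c] + lig[c] for c in ENERGY_COMPONENTS}
                for sp, comp in (("complex", cplx), ("receptor", rec), ("ligand", lig)):
                    rows.append(dict(compound_id="X", species=sp, replica=rep, frame=fr, **comp))
        est = one_traj_estimate(pd.DataFrame(rows), B=200, seed=0)
        assert est.value == 0.0
        assert est.components["dE_internal"] == 0.0

    def test_planted_noiseless_value_recovered_exactly(self, noiseless_esmacs_table):
        table, truth = noiseless_esmacs_table
        est = one_traj_estimate(table[table["compound_id"] == "A"], B=200, seed=0)
        assert est.value == truth["A"]
        assert est.se == 0.0

    def test_value_equals_component_sum(self):
        spec = EsmacsSeriesSpec(
            true_affinity_map={"A": -33.0}, n_replicas=4, n_frames=10, seed=9
        )
        est = one_traj_estimate(gen_esmacs_dataset(spec), B=200, seed=0)
        comp_sum = sum(v for k, v in est.components.items() if k.startswith("d"))
        assert est.value == pytest.approx(comp_sum, rel=1e-9)

    def test_replica_label_permutation_leaves_value_unchanged(self):
        spec = EsmacsSeriesSpec(
            true_affinity_map={"A": -20.0}, n_replicas=4, n_frames=5, seed=2
        )
        table = gen_esmacs_dataset(spec)
        base = one_traj_estimate(table, B=300, seed=5)
        permuted = table.copy()
        permuted["replica"] = (permuted["replica"] + 2) % 4
        perm = one_traj_estimate(permuted, B=300, seed=5)
        assert perm.value == pytest.approx(base.value, abs=1e-12)
        assert perm.se == pytest.approx(base.se, abs=1e-12)

    def test_mismatched_frame_sets_reported(self, noiseless_esmacs_table):
        table, _ = noiseless_esmacs_table
        sub = table[table["compound_id"] == "A"]
        broken = sub[~((sub["species"] == "ligand") & (sub["frame"] == 0))]
        with pytest.raises(ValueError, match="ligand"):
            one_traj_estimate(broken, B=200, seed=0)

    def test_coverage_of_planted_value_under_replica_noise(self):
        """|estimate − truth| < 4·SE in ≥95% of seeds (normal-theory coverage)."""
        hits = 0
        for seed in range(100):
            spec = EsmacsSeriesSpec(
                true_affinity_map={"A": -40.0},
                n_replicas=25,
                n_frames=2,
                component_noise_sds=ZERO_NOISE,
                between_replica_sd=1.0,
                seed=seed,
            )
            est = one_traj_estimate(gen_esmacs_dataset(spec), B=400, seed=seed)
            if abs(est.value + 40.0) < 4 * est.se:
                hits += 1
        assert hits >= 95


class TestReceptorAdaptation:
    def test_identical_receptors_have_zero_adaptation(self):
        table = _receptor_df({"A": -1000.0, "B": -1000.0, "C": -1000.0})
        adap = receptor_adaptation_relative(table, B=200, seed=0)
        assert all(v == 0.0 for v in adap.relative_adaptation.values())

    def test_deviations_from_grand_mean(self):
        adap = receptor_adaptation_relative(_receptor_df({"A": -1000.0, "B": -996.0}), B=200, seed=0)
        assert adap.grand_mean == -998.0
        assert adap.relative_adaptation == {"A": -2.0, "B": 2.0}

    def test_adaptations_sum_to_zero(self):
        spec = EsmacsSeriesSpec(
            true_affinity_map={c: -30.0 for c in "ABCDE"},
            n_replicas=3,
            n_frames=5,
            receptor_adaptation_offsets={"A": 3.0, "B": -1.0, "C": 0.5, "D": 2.0, "E": -4.5},
            seed=6,
        )
        table = gen_esmacs_dataset(spec)
        adap = receptor_adaptation_relative(table[table["species"] == "receptor"], B=200, seed=0)
        assert sum(adap.relative_adaptation.values()) == pytest.approx(0.0, abs=1e-6)

    def test_planted_offsets_recovered(self):
        offsets = {"A": 3.0, "B": -1.0, "C": -2.0}
        spec = EsmacsSeriesSpec(
            true_affinity_map={c: -30.0 for c in offsets},
            n_replicas=8,
            n_frames=10,
            receptor_adaptation_offsets=offsets,
            seed=13,
        )
        table = gen_esmacs_dataset(spec)
        adap = receptor_adaptation_relative(table[table["species"] == "receptor"], B=400, seed=1)
        centred = {c: v - np.mean(list(offsets.values())) for c, v in offsets.items()}
        for cid, planted in centred.items():
            tol = 4 * max(adap.se[cid], 0.05)
            assert adap.relative_adaptation[cid] == pytest.approx(planted, abs=tol)

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError):
            receptor_adaptation_relative(_receptor_df({"A": -1000.0}), B=200, seed=0)


class TestOneTrajAr:
    def test_zero_adaptation_is_identity(self, noiseless_esmacs_table):
        table, _ = noiseless_esmacs_table
        est = one_traj_estimate(table[table["compound_id"] == "A"], B=200, seed=0)
        same = one_traj_ar_estimate(est, 0.0)
        assert same.value == est.value
        assert same.se == est.se

    def test_shift_and_quadrature_se(self, noiseless_esmacs_table):
        table, truth = noiseless_esmacs_table
        est = one_traj_estimate(table[table["compound_id"] == "A"], B=200, seed=0)
        shifted = one_traj_ar_estimate(est, 3.0, 0.0)
        assert shifted.value == pytest.approx(truth["A"] + 3.0)
        assert shifted.se == est.se

    def test_heterogeneous_adaptation_widens_the_spread(self):
        """Independent planted adaptation offsets add variance across compounds."""
        rng = np.random.default_rng(0)
        truth = {f"C{i}": float(v) for i, v in enumerate(rng.normal(-35, 2, 12))}
        offsets = {c: float(v) for c, v in zip(truth, rng.normal(0, 3, 12))}
        spec = EsmacsSeriesSpec(
            true_affinity_map=truth,
            n_replicas=4,
            n_frames=8,
            receptor_adaptation_offsets=offsets,
            seed=3,
        )
        table = gen_esmacs_dataset(spec)
        one = analyze_energy_table(table, protocol="1traj", B=300, seed=0)
        ar = analyze_energy_table(table, protocol="1traj-ar", B=300, seed=0)
        assert ar["dG"].std() >= one["dG"].std()

    def test_equal_offsets_make_protocols_identical(self):
        """A constant adaptation is removed by the relative-term construction."""
        truth = {"A": -40.0, "B": -30.0, "C": -35.0}
        spec = EsmacsSeriesSpec(
            true_affinity_map=truth,
            n_replicas=3,
            n_frames=5,
            component_noise_sds=ZERO_NOISE,
            between_replica_sd=0.0,
            receptor_adaptation_offsets={c: 7.5 for c in truth},
            seed=8,
        )
        table = gen_esmacs_dataset(spec)
        one = analyze_energy_table(table, protocol="1traj", B=300, seed=0)
        ar = analyze_energy_table(table, protocol="1traj-ar", B=300, seed=0)
        assert np.allclose(one["dG"], ar["dG"], atol=1e-6)
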