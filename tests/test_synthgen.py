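"""Generators: determinism, moment identities, conservation, roundtrips."""

import numpy as np
import pandas as pd
import pytest

from hogpipe import ImageParams, SimulationConfig, dynamics, glycerol, synthgen


class TestDualReporter:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_cells=100, seed=5)
        t1, _ = synthgen.simulate_dual_reporter(cfg)
        t2, _ = synthgen.simulate_dual_reporter(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        t3, _ = synthgen.simulate_dual_reporter(cfg, replicate=1)
        assert not np.allclose(t1["yfp"], t3["yfp"])

    def test_zero_variance_outputs_equal_mean(self):
        cfg = SimulationConfig(n_cells=10, eta2_int_true=0, eta2_ext_true=0, mean_output=1000)
        t, _ = synthgen.simulate_dual_reporter(cfg)
        assert (t["yfp"] == 1000.0).all()
        assert (t["tdtomato"] == 1000.0).all()

    def test_additive_moment_identities_at_large_n(self):
        """var(x/mu) -> int+ext; cov between channels -> ext;
        half the variance of the normalized difference -> int."""
        cfg = SimulationConfig(
            n_cells=200_000, seed=8, eta2_int_true=0.12, eta2_ext_true=0.15, mean_output=1000
        )
        t, _ = synthgen.simulate_dual_reporter(cfg)
        a, b = t["yfp"].to_numpy() / 1000, t["tdtomato"].to_numpy() / 1000
        assert np.var(a) == pytest.approx(0.27, abs=0.01)
        assert np.cov(a, b, ddof=0)[0, 1] == pytest.approx(0.15, abs=0.01)
        assert 0.5 * np.var(a - b) == pytest.approx(0.12, abs=0.01)

    def test_lognormal_family_mean_one_factors(self):
        cfg = SimulationConfig(
            n_cells=200_000,
            seed=12,
            eta2_int_true=0.1,
            eta2_ext_true=0.2,
            noise_family="multiplicative-lognormal",
        )
        t, truth = synthgen.simulate_dual_reporter(cfg)
        assert truth.extrinsic_factor.mean() == pytest.approx(1.0, abs=0.01)
        assert (t["yfp"] > 0).all()  # lognormal products stay positive
        assert t["yfp"].mean() == pytest.approx(1000, rel=0.02)

    def test_lognormal_intrinsic_estimator_bias(self):
        """Under the multiplicative family the difference-based estimator
        converges to eta2_int * (1 + eta2_ext), not eta2_int."""
        eta_i, eta_e = 0.1, 0.3
        cfg = SimulationConfig(
            n_cells=400_000,
            seed=13,
            eta2_int_true=eta_i,
            eta2_ext_true=eta_e,
            noise_family="multiplicative-lognormal",
        )
        t, _ = synthgen.simulate_dual_reporter(cfg)
        a = t["yfp"].to_numpy() / t["yfp"].mean()
        b = t["tdtomato"].to_numpy() / t["tdtomato"].mean()
        est = 0.5 * np.var(a - b)
        assert est == pytest.approx(eta_i * (1 + eta_e), rel=0.03)
        assert abs(est - eta_i) > 5 * abs(est - eta_i * (1 + eta_e))

    def test_negative_outputs_are_retained(self):
        cfg = SimulationConfig(n_cells=50_000, seed=3, eta2_int_true=0.5, eta2_ext_true=0.5)
        t, _ = synthgen.simulate_dual_reporter(cfg)
        assert (t["yfp"] < 0).any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eta2_int_true": -0.1},
            {"eta2_ext_true": float("nan")},
            {"mean_output": 0},
            {"n_cells": 1},
            {"noise_family": "uniform"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestFieldImage:
    def test_zero_cells_is_pure_background(self):
        cfg = SimulationConfig(
            n_cells=2, seed=0, image_params=ImageParams(n_cells=0, background=50.0)
        )
        images, truth = synthgen.simulate_field_image(cfg)
        assert (images["yfp"] == 50.0).all()
        assert truth.mask.max() == 0

    def test_noise_free_conservation_is_exact(self, noiseless_field):
        images, truth = noiseless_field
        sel = truth.mask == 1
        for ch in ("yfp", "tdtomato"):
            integrated = images[ch][sel].sum() - truth.extra["background"] * sel.sum()
            assert integrated == pytest.approx(truth.totals[ch][0], rel=1e-9)

    def test_mask_labels_match_cell_ids(self, bright_field):
        _, truth = bright_field
        labels = np.unique(truth.mask)
        assert list(labels) == list(range(0, 21))
        for ch, totals in truth.totals.items():
            assert totals.shape == (20,)

    def test_determinism(self):
        cfg = SimulationConfig(n_cells=2, seed=6, image_params=ImageParams(n_cells=5))
        i1, t1 = synthgen.simulate_field_image(cfg)
        i2, t2 = synthgen.simulate_field_image(cfg)
        assert np.array_equal(i1["yfp"], i2["yfp"])
        assert np.array_equal(t1.mask, t2.mask)

    def test_placement_error_when_field_too_crowded(self):
        params = ImageParams(shape=(64, 64), radius_range=(10.0, 12.0), n_cells=30)
        cfg = SimulationConfig(n_cells=2, seed=0, image_params=params)
        with pytest.raises(RuntimeError, match="place"):
            synthgen.simulate_field_image(cfg)

    def test_requires_image_params(self):
        with pytest.raises(ValueError, match="image_params"):
            synthgen.simulate_field_image(SimulationConfig(n_cells=2))


class TestPhosphoTimecourse:
    TIMEPOINTS = [0, 2.5, 5, 10, 15, 20, 30]

    def test_constant_curve_when_base_peak_plateau_equal(self):
        lanes, truth = synthgen.simulate_phospho_timecourse(
            0.2, 0.2, 5, 8, 0.2, self.TIMEPOINTS, noise_cv=0.0, seed=0
        )
        frac = lanes["phospho"] / (lanes["phospho"] + lanes["unphospho"])
        assert np.allclose(frac, 0.2)

    def test_noise_free_roundtrip_recovers_generative_curve(self):
        lanes, truth = synthgen.simulate_phospho_timecourse(
            0.05, 0.35, 5, 8, 0.08, self.TIMEPOINTS, noise_cv=0.0, seed=0
        )
        series = dynamics.blot_fraction_series(lanes)
        assert np.allclose(series["fraction"], truth.extra["fraction"])
        # curve peaks at peak_time with the requested peak fraction
        assert series["fraction"].max() == pytest.approx(0.35)
        assert series.loc[series["fraction"].idxmax(), "time"] == 5

    def test_mean_recovered_auc_matches_truth(self):
        """Monte-Carlo: over replicate noisy draws, the mean trapezoidal
        AUC of recovered fractions is within 3 SEM of the analytic AUC."""
        aucs = []
        for rep in range(100):
            lanes, truth = synthgen.simulate_phospho_timecourse(
                0.05, 0.35, 5, 8, 0.08, self.TIMEPOINTS, noise_cv=0.1, seed=900 + rep
            )
            series = dynamics.blot_fraction_series(lanes)
            aucs.append(dynamics.auc(series["time"], series["fraction"]))
        true_auc = synthgen.phospho_curve_auc(0.05, 0.35, 5, 8, 0.08, 30)
        sem = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        # small discretisation offset between trapezoid and the exact integral
        trap_truth = dynamics.auc(
            self.TIMEPOINTS,
            synthgen.phospho_fraction_curve(np.array(self.TIMEPOINTS), 0.05, 0.35, 5, 8, 0.08),
        )
        assert abs(trap_truth - true_auc) / true_auc < 0.05
        assert abs(np.mean(aucs) - trap_truth) < 3 * sem

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="fraction"):
            synthgen.simulate_phospho_timecourse(0.1, 1.2, 5, 8, 0.1, self.TIMEPOINTS)

    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            synthgen.simulate_phospho_timecourse(0.1, 0.3, 5, 8, 0.1, [0, 10, 5])


class TestGlycerolAssay:
    def test_zero_noise_roundtrip_to_machine_precision(self):
        table = synthgen.simulate_glycerol_assay(
            0.004, od=[0.4, 0.5, 0.6], vrel=[1.0, 1.1, 1.2], noise_cv=0.0
        )
        out = glycerol.convert_table(table)
        assert np.allclose(out["pmol_per_cell"], 0.004, rtol=1e-12)

    def test_doubling_od_doubles_concentration(self):
        t1 = synthgen.simulate_glycerol_assay(0.004, od=[0.5], vrel=[1.0])
        t2 = synthgen.simulate_glycerol_assay(0.004, od=[1.0], vrel=[1.0])
        assert t2["concentration_ng_per_ul"][0] == pytest.approx(
            2 * t1["concentration_ng_per_ul"][0]
        )

    def test_mean_recovery_bias_below_one_percent(self):
        table = synthgen.simulate_glycerol_assay(
            0.004, od=[0.5] * 50, vrel=[1.0] * 50, noise_cv=0.05, seed=31
        )
        out = glycerol.convert_table(table)
        assert abs(out["pmol_per_cell"].mean() / 0.004 - 1) < 0.01

    def test_rejects_nonpositive_od(self):
        with pytest.raises(ValueError, match="positive"):
            synthgen.simulate_glycerol_assay(0.004, od=[0.0], vrel=[1.0])
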