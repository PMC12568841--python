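"""GRT drifts, LBA races and architecture compositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import facesft as fs
from facesft.rule_models import (bivariate_drift, lba_channel_sample,
                                 lba_race, marginal_drift, model_predictions,
                                 simulate_model)


class TestDrifts:
    def test_mean_at_bound_splits_mass(self):
        assert marginal_drift(1.0, 0.5, 1.0) == (0.5, 0.5)

    def test_unit_standardized_distance(self):
        v_t, v_c = marginal_drift(1.5, 0.5, 1.0, target_side="above")
        assert v_t == pytest.approx(0.84134, abs=1e-5)

    def test_below_side_mirrors(self):
        above = marginal_drift(1.3, 0.7, 1.0, "above")
        below = marginal_drift(0.7, 0.7, 1.0, "below")
        assert above[0] == pytest.approx(below[0])

    @given(st.floats(-3, 3), st.floats(0.05, 4), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization(self, mu, sigma, bound):
        v_t, v_c = marginal_drift(mu, sigma, bound)
        assert v_t + v_c == pytest.approx(1.0, abs=1e-12)

    def test_bivariate_independence_product(self):
        v_t, v_c = bivariate_drift(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        assert v_t == pytest.approx(0.25)
        v_t, _ = bivariate_drift(2.0, 2.0, 1.0, 1.0, 1.0, 1.0)
        assert v_t == pytest.approx(0.84134 ** 2, abs=1e-4)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(0.1, 3),
           st.floats(0.1, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bivariate_normalization(self, mx, my, sx, sy):
        v_t, v_c = bivariate_drift(mx, my, sx, sy, 0.5, 0.5)
        assert v_t + v_c == pytest.approx(1.0, abs=1e-12)


def _lba_defective_pdf(t, v, s, b, A):
    """Analytic single-accumulator first-passage density (start ~ U(0, A),
    rate ~ N(v, s)); negative-rate mass never finishes."""
    z1 = (b - A - t * v) / (t * s)
    z2 = (b - t * v) / (t * s)
    return (1.0 / A) * (-v * stats.norm.cdf(z1) + s * stats.norm.pdf(z1)
                        + v * stats.norm.cdf(z2) - s * stats.norm.pdf(z2))


def _lba_defective_cdf(t, v, s, b, A):
    z1 = (b - A - t * v) / (t * s)
    z2 = (b - t * v) / (t * s)
    return (1.0 + ((b - A - t * v) / A) * stats.norm.cdf(z1)
            - ((b - t * v) / A) * stats.norm.cdf(z2)
            + (t * s / A) * (stats.norm.pdf(z1) - stats.norm.pdf(z2)))


class TestLBARace:
    def test_degenerate_race_time_is_distance_over_rate(self, lba):
        params = fs.LBAParams(A=0.0, b_target=1000.0, b_contrast=1000.0,
                              s=1e-9, t0=0.0)
        winner, t = lba_channel_sample(params, 1.0, 1e-6,
                                       np.random.default_rng(0))
        assert winner == "first"
        assert t == pytest.approx(1000.0, rel=1e-6)

    def test_lower_threshold_wins_at_equal_rates(self):
        params = fs.LBAParams(A=0.0, b_target=800.0, b_contrast=1200.0,
                              s=1e-9, t0=0.0)
        winner, t = lba_channel_sample(params, 0.5, 0.5,
                                       np.random.default_rng(1))
        assert winner == "first"
        assert t == pytest.approx(1600.0, rel=1e-6)

    def test_winner_time_mean_matches_analytic_density(self):
        # oracle: numeric integration of f1 S2 + f2 S1, conditioned on at
        # least one accumulator finishing
        v1, v2, s, b, A = 0.7, 0.3, 0.15, 1000.0, 300.0
        _, t = lba_race(v1, v2, b, b, A, s, 1_000_000,
                        np.random.default_rng(7))
        sim_mean = t.mean()

        def integrand(u):
            f1 = _lba_defective_pdf(u, v1, s, b, A)
            f2 = _lba_defective_pdf(u, v2, s, b, A)
            S1 = 1.0 - _lba_defective_cdf(u, v1, s, b, A)
            S2 = 1.0 - _lba_defective_cdf(u, v2, s, b, A)
            return u * (f1 * S2 + f2 * S1)

        norm = 1.0 - stats.norm.cdf(-v1 / s) * stats.norm.cdf(-v2 / s)
        num, _ = integrate.quad(integrand, 1e-6, 1e6, limit=400)
        assert sim_mean == pytest.approx(num / norm, rel=0.01)

    def test_threshold_monotonically_slows_target_wins(self, grt):
        times = []
        for b in (900.0, 1400.0):
            params = fs.LBAParams(A=200.0, b_target=b, b_contrast=1200.0,
                                  s=0.1, t0=0.0)
            won, t = lba_race(0.8, 0.2, params.b_target, params.b_contrast,
                              params.A, params.s, 20_000,
                              np.random.default_rng(3))
            times.append(t[won].mean())
        assert times[0] < times[1]


class TestArchitectures:
    def test_mixture_boundary_matches_pure_serial(self, design, grt, lba):
        serial = fs.ModelSpec(architecture="serial_st", lba=lba, grt=grt,
                              p_x=0.6)
        mixed = fs.ModelSpec(architecture="mixed_serial_parallel", lba=lba,
                             grt=grt, p_x=0.6, p_serial=1.0, m=1.3,
                             A_parallel=42.0)
        _, rt_s = simulate_model(serial, 1, 1, 100_000, seed=5)
        _, rt_m = simulate_model(mixed, 1, 1, 100_000, seed=6)
        ks = stats.ks_2samp(rt_s, rt_m).statistic
        assert ks < 0.01

    def test_degenerate_serial_contrast_short_circuit(self, design):
        # first channel always resolves contrast instantly-deterministically
        grt = fs.GRTPerception(mu_x=(0.0, 1.25, 2.5), mu_y=(0.0, 1.25, 2.5),
                               sigma_x=0.01, sigma_y=0.01, bound_x=10.0,
                               bound_y=-10.0)
        lba = fs.LBAParams(A=0.0, b_target=1000.0, b_contrast=1000.0,
                           s=1e-9, t0=100.0)
        spec = fs.ModelSpec(architecture="serial_st", lba=lba, grt=grt,
                            p_x=1.0)
        resp, rts = simulate_model(spec, 2, 2, 200, seed=0)
        assert (resp == "contrast").all()
        assert np.allclose(rts, 1000.0 / 1.0 + 100.0, rtol=1e-6)

    def test_pure_contaminant_is_uniform_with_fair_guess(self, grt, lba):
        spec = fs.ModelSpec(architecture="mixed_serial_contaminant", lba=lba,
                            grt=grt, p0=1.0, contaminant_range=(300.0, 2300.0))
        resp, rts = simulate_model(spec, 1, 1, 20_000, seed=8)
        assert rts.min() >= 300.0 and rts.max() <= 2300.0
        # uniformity: compare to the uniform CDF
        ks = stats.kstest(rts, stats.uniform(300, 2000).cdf).statistic
        assert ks < 0.02
        guess = (resp == "target").mean()
        assert abs(guess - 0.5) < 3 * np.sqrt(0.25 / 20_000) + 0.01

    def test_contaminant_without_range_rejected(self, grt, lba):
        spec = fs.ModelSpec(architecture="mixed_parallel_contaminant",
                            lba=lba, grt=grt, p0=0.1)
        with pytest.raises(ValueError, match="contaminant"):
            simulate_model(spec, 1, 1, 100, seed=0)

    def test_all_rts_at_least_t0(self, serial_spec, parallel_spec,
                                 coactive_spec):
        for spec in (serial_spec, parallel_spec, coactive_spec):
            _, rts = simulate_model(spec, 1, 1, 5000, seed=2)
            assert (rts >= spec.lba.t0).all()

    def test_free_drift_uses_per_stimulus_rates(self, lba):
        nu = {r: 0.9 for r in ("HH", "HL", "LH", "LL", "Ex", "Ix", "Ey",
                               "Iy", "R")}
        nu["LL"] = 0.55
        spec = fs.ModelSpec(architecture="free_drift", lba=lba, nu=nu)
        resp_hh, _ = simulate_model(spec, 2, 2, 10_000, seed=3)
        resp_ll, _ = simulate_model(spec, 1, 1, 10_000, seed=3)
        assert (resp_hh == "target").mean() > (resp_ll == "target").mean()

    def test_unknown_architecture_rejected(self, grt, lba):
        with pytest.raises(ValueError):
            fs.ModelSpec(architecture="telepathic", lba=lba, grt=grt)


class TestPredictions:
    def test_quantiles_monotone_and_probs_sum_to_one(self, serial_spec,
                                                     design):
        pred = model_predictions(serial_spec, design, n_sim=2000, seed=0)
        by_stim = pred.groupby(["x_level", "y_level"])["p"].sum()
        assert np.allclose(by_stim, 1.0)
        filled = pred.dropna(subset=["q25"])
        assert (filled["q25"] <= filled["q50"]).all()
        assert (filled["q50"] <= filled["q75"]).all()

    def test_serial_prediction_mic_is_additive(self, serial_spec, design,
                                               simulate_items):
        items = simulate_items(serial_spec, 30_000, seed=1)
        assert abs(fs.mic_from_samples(items)) < 10.0
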