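"""Survivor-function statistics, factorial contrasts and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import facesft as fs
from facesft.sft import (classify_architecture,
                         contrast_category_tests, ks_dominance_suite, mic,
                         mic_from_samples, rts_by_item, sic,
                         sic_deflection_tests, summarize_sic_shape,
                         survivor_fn, target_category_anova)


class TestSurvivor:
    def test_counting_definition(self):
        est = survivor_fn([100, 200, 300], np.array([0.0, 150.0, 300.0]))
        assert est.S == pytest.approx([1.0, 2 / 3, 0.0])  # strict P(T > t)

    def test_non_increasing(self):
        rng = np.random.default_rng(0)
        rts = rng.lognormal(6.5, 0.4, 500)
        est = survivor_fn(rts, np.sort(rng.uniform(0, 3000, 200)))
        assert (np.diff(est.S) <= 0).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            survivor_fn([], np.array([1.0]))


class TestMIC:
    def test_additive_means_give_zero(self):
        assert mic(1000, 900, 800, 700) == 0.0

    def test_observed_aligned_participant_means(self):
        # double difference of printed correct means for one observer
        assert mic(1041, 749, 894, 710) == 108.0

    def test_observed_misaligned_participant_means(self):
        assert mic(1964, 1530, 1492, 1236) == 178.0

    @given(st.floats(-500, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        base = dict(LL=1300.0, LH=1100.0, HL=1000.0, HH=850.0)
        shifted = [base[k] + shift for k in ("LL", "LH", "HL", "HH")]
        assert mic(*shifted) == pytest.approx(
            mic(base["LL"], base["LH"], base["HL"], base["HH"]), abs=1e-6)

    def test_non_finite_mean_rejected(self):
        with pytest.raises(ValueError):
            mic(np.nan, 1.0, 2.0, 3.0)


class TestSIC:
    def test_identical_samples_give_zero_curve(self):
        rng = np.random.default_rng(1)
        s = rng.lognormal(6.5, 0.3, 300)
        res = sic({k: s for k in ("LL", "LH", "HL", "HH")}, n_boot=50, seed=0)
        assert np.allclose(res.sic, 0.0)
        assert res.mic == pytest.approx(0.0)

    def test_matched_pairs_cancel(self):
        rng = np.random.default_rng(2)
        fast = rng.normal(700, 80, 400)
        slow = rng.normal(900, 80, 400)
        res = sic({"LL": slow, "LH": slow, "HL": fast, "HH": fast}, n_boot=0)
        assert np.allclose(res.sic, 0.0)

    def test_integral_equals_mic(self):
        rng = np.random.default_rng(3)
        samples = {k: rng.lognormal(6.5 + 0.1 * i, 0.3, 200 + 17 * i)
                   for i, k in enumerate(("LL", "LH", "HL", "HH"))}
        res = sic(samples, n_boot=0)
        assert res.integral() == pytest.approx(res.mic, abs=1e-6)

    def test_parallel_exhaustive_max_composition_is_negative(self):
        # two exponential channels composed by max: closed-form survivor
        # S_max(t) = 1 - (1-e^(-a t))(1-e^(-b t)) predicts SIC(t) <= 0
        rng = np.random.default_rng(4)
        rate = {"L": 1 / 400.0, "H": 1 / 250.0}
        n = 4000
        samples = {}
        for key in ("LL", "LH", "HL", "HH"):
            a = rng.exponential(1 / rate[key[0]], n)
            b = rng.exponential(1 / rate[key[1]], n)
            samples[key] = np.maximum(a, b)
        res = sic(samples, n_boot=0)
        # oracle: analytic SIC of max-composed exponentials is <= 0
        t = res.t_grid[1:]
        def smax(ra, rb):
            return 1 - (1 - np.exp(-ra * t)) * (1 - np.exp(-rb * t))
        analytic = (smax(rate["L"], rate["L"]) - smax(rate["L"], rate["H"])) \
            - (smax(rate["H"], rate["L"]) - smax(rate["H"], rate["H"]))
        assert (analytic <= 1e-12).all()
        assert (res.sic[1:] <= np.abs(analytic) + 0.05).all()

    def test_bootstrap_bands_cover_zero_for_null(self):
        rng = np.random.default_rng(5)
        s = rng.normal(800, 100, 300)
        res = sic({k: rng.normal(800, 100, 300)
                   for k in ("LL", "LH", "HL", "HH")}, n_boot=200, seed=1)
        inside = (res.boot_lower <= 0) & (0 <= res.boot_upper)
        assert inside.mean() > 0.9

    def test_empty_item_rejected(self):
        with pytest.raises(ValueError):
            sic({"LL": [1.0], "LH": [1.0], "HL": [1.0], "HH": []})


class TestDominance:
    def test_identical_samples_fail_verdict(self):
        rng = np.random.default_rng(0)
        s = rng.normal(800, 100, 300)
        table, verdict = ks_dominance_suite(
            {k: s for k in ("LL", "LH", "HL", "HH")})
        assert not verdict
        assert (table["p"] > 0.05).all()

    def test_statistic_is_max_ecdf_difference(self):
        a = np.arange(1.0, 11.0)
        b = a + np.array([0, 0, 0, 0, 0, 0, 0, 3, 3, 3], float)
        table, _ = ks_dominance_suite(
            {"HH": a, "HL": b, "LH": b + 5, "LL": b + 10})
        row = table.set_index("test").loc["S_HH > S_HL"]
        assert row["statistic"] == pytest.approx(0.3)

    def test_shifted_channels_pass_verdict(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = {
                "HH": rng.normal(700, 150, 400),
                "HL": rng.normal(850, 150, 400),
                "LH": rng.normal(850, 150, 400),
                "LL": rng.normal(1000, 150, 400),
            }
            hits += ks_dominance_suite(samples)[1]
        assert hits >= 9  # ordering detected in essentially every run

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_dominance_suite({"LL": [1.0], "LH": [1, 2],
                                "HL": [1, 2], "HH": [1, 2]})


class TestDeflections:
    def test_null_sic_has_zero_deflections(self):
        rng = np.random.default_rng(1)
        s = rng.normal(800, 100, 200)
        res = sic({k: s for k in ("LL", "LH", "HL", "HH")}, n_boot=0)
        out = sic_deflection_tests(res, n_resample=200, seed=0)
        assert out["d_plus"] == 0.0 and out["d_minus"] == 0.0
        assert out["p_plus"] > 0.5 and out["p_minus"] > 0.5

    def test_parallel_architecture_shows_negative_deflection_only(
            self, parallel_spec, simulate_items):
        plus_sig = minus_sig = 0
        for seed in range(6):
            items = simulate_items(parallel_spec, 400, seed)
            res = sic(items, n_boot=0)
            out = sic_deflection_tests(res, n_resample=300, seed=seed)
            plus_sig += out["p_plus"] < 0.05
            minus_sig += out["p_minus"] < 0.05
        assert minus_sig >= 5
        assert plus_sig <= 1

    def test_coactive_architecture_shows_positive_deflection(
            self, coactive_spec, simulate_items):
        plus_sig = 0
        for seed in range(6):
            items = simulate_items(coactive_spec, 400, seed)
            res = sic(items, n_boot=0)
            out = sic_deflection_tests(res, n_resample=300, seed=seed)
            plus_sig += out["p_plus"] < 0.05
        assert plus_sig >= 5

    def test_serial_architecture_balances_areas(self, serial_spec, simulate_items):
        # equal-area S-shape: the integral (= MIC) is tiny relative to the
        # deflection magnitudes
        for seed in range(3):
            items = simulate_items(serial_spec, 2000, seed)
            res = sic(items, n_boot=0)
            scale = max(res.d_plus, res.d_minus) * \
                (res.t_grid[-1] - res.t_grid[0])
            assert abs(res.integral()) < 0.12 * scale


def _one_participant(spec, design, seed, n=200):
    truth = fs.GroundTruth(model_spec=spec, design=design,
                           n_trials_per_item=n, seed=seed)
    return fs.simulate_rt_dataset(truth).df


class TestTargetAnova:
    def _balanced_frame(self, rng, effects=None):
        effects = effects or {}
        rows = []
        for session in (2, 3, 4):
            for top in ("H", "L"):
                for bottom in ("H", "L"):
                    for _ in range(4):
                        rt = 900 + effects.get("top", 0) * (top == "H") \
                            + effects.get("bottom", 0) * (bottom == "H") \
                            + effects.get("session", 0) * session \
                            + rng.normal(0, 40)
                        rows.append({
                            "participant": "p1", "session": session,
                            "x_level": 2 if bottom == "H" else 1,
                            "y_level": 2 if top == "H" else 1,
                            "rt_ms": rt, "correct": True,
                            "role": ("H" if bottom == "H" else "L")
                                    + ("H" if top == "H" else "L"),
                        })
        return pd.DataFrame(rows)

    @staticmethod
    def _brute_force_f(df):
        """Classical balanced three-way fixed-effects decomposition."""
        y = df["rt_ms"].to_numpy()
        grand = y.mean()
        factors = {"session": df["session"], "top": df["top"],
                   "bottom": df["bottom"]}
        def cell_means(*names):
            return df.groupby(list(names))["rt_ms"].mean()
        n = len(df)
        ss = {}
        for name, col in factors.items():
            means = df.groupby(col)["rt_ms"].mean()
            counts = df.groupby(col).size()
            ss[name] = float((counts * (means - grand) ** 2).sum())
        import itertools
        for a, b in itertools.combinations(factors, 2):
            means = cell_means(a, b)
            counts = df.groupby([a, b]).size()
            ma = df.groupby(a)["rt_ms"].mean()
            mb = df.groupby(b)["rt_ms"].mean()
            dev = means.copy()
            for (va, vb), m in means.items():
                dev.loc[(va, vb)] = m - ma[va] - mb[vb] + grand
            ss[f"{a}:{b}"] = float((counts * dev ** 2).sum())
        means3 = cell_means("session", "top", "bottom")
        counts3 = df.groupby(["session", "top", "bottom"]).size()
        m_ab = cell_means("session", "top")
        m_ac = cell_means("session", "bottom")
        m_bc = cell_means("top", "bottom")
        m_a = df.groupby("session")["rt_ms"].mean()
        m_b = df.groupby("top")["rt_ms"].mean()
        m_c = df.groupby("bottom")["rt_ms"].mean()
        dev3 = means3.copy()
        for (va, vb, vc), m in means3.items():
            dev3.loc[(va, vb, vc)] = (m - m_ab[(va, vb)] - m_ac[(va, vc)]
                                      - m_bc[(vb, vc)] + m_a[va] + m_b[vb]
                                      + m_c[vc] - grand)
        ss["session:top:bottom"] = float((counts3 * dev3 ** 2).sum())
        fitted = means3.loc[list(zip(df["session"], df["top"],
                                     df["bottom"]))].to_numpy()
        ss_err = float(((y - fitted) ** 2).sum())
        dfs = {"session": 2, "top": 1, "bottom": 1, "session:top": 2,
               "session:bottom": 2, "top:bottom": 1, "session:top:bottom": 2}
        df_err = n - 12
        return {k: (ss[k] / dfs[k]) / (ss_err / df_err) for k in dfs}, ss_err

    def test_f_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(7)
        df = self._balanced_frame(rng, {"top": 60, "bottom": 30,
                                        "session": -15})
        table = target_category_anova(df).set_index("effect")
        labelled = df.copy()
        labelled["top"] = np.where(labelled.y_level == 2, "H", "L")
        labelled["bottom"] = np.where(labelled.x_level == 2, "H", "L")
        oracle, _ = self._brute_force_f(labelled)
        pairs = {"session": "session", "top": "top", "bottom": "bottom",
                 "session:top": "session:top",
                 "session:bottom": "session:bottom",
                 "top:bottom": "top:bottom",
                 "session:top:bottom": "session:top:bottom"}
        for effect, key in pairs.items():
            assert table.loc[effect, "F"] == pytest.approx(oracle[key],
                                                           rel=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        df = self._balanced_frame(rng, {"top": 40})
        f1 = target_category_anova(df)["F"].to_numpy()
        df2 = df.copy()
        df2["rt_ms"] += 500.0
        f2 = target_category_anova(df2)["F"].to_numpy()
        assert np.allclose(f1, f2)

    def test_null_data_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = self._balanced_frame(rng)
            table = target_category_anova(df)
            hits += int((table["p"] < 0.05).any())
        assert hits <= 4  # 7 tests at alpha = .05 under the null

    def test_empty_cell_reported(self):
        rng = np.random.default_rng(9)
        df = self._balanced_frame(rng)
        df = df[~((df.session == 3) & (df.x_level == 2) & (df.y_level == 2))]
        with pytest.raises(ValueError, match="cell"):
            target_category_anova(df)


class TestContrastTests:
    def test_identical_samples_give_null_stats(self, design):
        rng = np.random.default_rng(0)
        rows = []
        base = rng.normal(900, 90, 200)
        for role, (x, y) in (("R", (0, 0)), ("Ix", (1, 0)), ("Ex", (2, 0)),
                             ("Iy", (0, 1)), ("Ey", (0, 2))):
            for rt in base:
                rows.append({"participant": "p1", "x_level": x, "y_level": y,
                             "rt_ms": rt, "correct": True, "role": role})
        table = contrast_category_tests(pd.DataFrame(rows))
        assert np.allclose(table["t"], 0.0, atol=1e-9)
        assert np.allclose(table["cohens_d"], 0.0, atol=1e-9)

    def test_fixed_order_serial_slows_first_dimension_interior(
            self, design, grt, lba):
        # lips always processed first: lips-varying interior item needs the
        # second (eyes) channel more often at x1 than x2, so Ix runs slower
        # than Ex while the eyes-varying items stay equivalent
        spec = fs.ModelSpec(architecture="serial_st", lba=lba, grt=grt,
                            p_x=1.0)
        df = _one_participant(spec, design, seed=0, n=400)
        table = contrast_category_tests(df).set_index("comparison")
        lips = table.loc["E_bottom - I_bottom"]
        assert lips["mean_diff"] < 0 and lips["p"] < 0.05
        eyes = table.loc["E_top - I_top"]
        assert eyes["p"] > 0.05

    def test_parallel_interior_exterior_equivalent(self, design,
                                                   parallel_spec):
        nonsig = 0
        for seed in range(8):
            df = _one_participant(parallel_spec, design, seed, n=400)
            table = contrast_category_tests(df).set_index("comparison")
            ie = table.loc[["E_top - I_top", "E_bottom - I_bottom"]]
            nonsig += int((ie["p"] >= 0.05).all())
        assert nonsig >= 7  # at alpha .05 the null holds in most runs

    def test_parallel_redundant_is_fastest(self, design, parallel_spec):
        for seed in range(5):
            df = _one_participant(parallel_spec, design, seed, n=400)
            means = df[df.correct].groupby("role")["rt_ms"].mean()
            assert means["R"] <= means[["Ix", "Ex", "Iy", "Ey"]].min()

    def test_missing_role_rejected(self, design):
        df = pd.DataFrame({"participant": ["p"], "x_level": [0],
                           "y_level": [0], "rt_ms": [700.0],
                           "correct": [True], "role": ["R"]})
        with pytest.raises(ValueError):
            contrast_category_tests(df)


class TestClassification:
    @pytest.mark.parametrize("shape, mic_sig, pattern, both, expected", [
        ("positive", True, {"top": "I<E", "bottom": "I<E"}, False,
         ["Coactive"]),
        ("s-shaped", False, {"top": "I=E", "bottom": "I=E"}, False,
         ["Parallel ST", "Serial ST"]),
        ("s-shaped-mostly-positive", False, {"top": "I=E", "bottom": "I>E"},
         False, ["Serial ST"]),
        ("s-shaped", False, {"top": "I<E", "bottom": "I>E"}, False,
         ["Serial ST"]),
        ("s-shaped", False, {"top": "I<E", "bottom": "I>E"}, True,
         ["Coactive", "Serial ST"]),
        ("mostly-negative", False, {"top": "I<E", "bottom": "I<E"}, False,
         ["Parallel ST"]),
    ])
    def test_rule_table(self, shape, mic_sig, pattern, both, expected):
        assert classify_architecture(shape, mic_sig, pattern, both) == expected

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture("wiggly", False,
                                  {"top": "I=E", "bottom": "I=E"})

    def test_generators_classified_consistently(self, design, serial_spec,
                                                parallel_spec, coactive_spec):
        """End-to-end: simulated architectures yield labels containing the
        generating architecture in >= 80% of seeded runs."""
        truth_label = {"serial_st": "Serial ST", "parallel_st": "Parallel ST",
                       "coactive": "Coactive"}
        for spec in (serial_spec, parallel_spec, coactive_spec):
            hits = 0
            n_runs = 7
            for seed in range(n_runs):
                df = _one_participant(spec, design, seed, n=400)
                items = rts_by_item(df)
                res = sic(items, n_boot=0)
                defl = sic_deflection_tests(res, n_resample=300, seed=seed)
                shape, both = summarize_sic_shape(defl, res.sic, res.t_grid)
                table = contrast_category_tests(df).set_index("comparison")
                pattern = {}
                for dim, comp in (("top", "E_top - I_top"),
                                  ("bottom", "E_bottom - I_bottom")):
                    row = table.loc[comp]
                    pattern[dim] = ("I=E" if row["p"] >= 0.05 else
                                    ("I<E" if row["mean_diff"] > 0 else "I>E"))
                boot = [mic_from_samples(
                    {k: np.random.default_rng((seed, b)).choice(v, v.size)
                     for k, v in items.items()}) for b in range(60)]
                mic_sig = abs(res.mic) > 3 * np.std(boot)
                labels = classify_architecture(shape, bool(mic_sig), pattern,
                                               both)
                hits += truth_label[spec.architecture] in labels
            assert hits >= int(0.8 * n_runs)
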