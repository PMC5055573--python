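"""Spearman screening, logistic calibration, thresholds, subgroups."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pmidelim import (
    LogisticCurve,
    MarkerLogit,
    PanelCalibration,
    ThresholdUndefinedError,
    spearman_presence_vs_add,
    subgroup_filter,
    thresholds_from_fit,
)
from pmidelim.calibration import LN19

from oracles import brute_permutation_p, brute_spearman


class TestSpearman:
    def test_step_pattern(self):
        res = spearman_presence_vs_add([1, 2, 3, 4], [0, 0, 1, 1], min_minority=1)
        assert res.rho == pytest.approx(0.8944271909999159, abs=1e-12)

    def test_antisymmetry(self):
        res = spearman_presence_vs_add([1, 2, 3, 4], [1, 1, 0, 0], min_minority=1)
        assert res.rho == pytest.approx(-0.8944271909999159, abs=1e-12)

    def test_constant_presence_is_few_cases(self):
        res = spearman_presence_vs_add([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        assert res.status == "few cases"
        assert math.isnan(res.rho)

    def test_small_minority_is_few_cases(self):
        add = np.arange(40.0)
        y = np.zeros(40)
        y[-3:] = 1  # 3 in the minority class
        assert spearman_presence_vs_add(add, y).status == "few cases"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(8, 30))
            add = np.round(rng.uniform(0, 36, n), 1)  # ties possible
            y = (rng.random(n) < 0.5).astype(float)
            if y.sum() in (0, n):
                continue
            res = spearman_presence_vs_add(add, y, min_minority=1)
            assert res.rho == pytest.approx(brute_spearman(add, y), abs=1e-12)

    def test_exact_permutation_matches_full_enumeration(self):
        rng = np.random.default_rng(13)
        for n in (6, 7, 8):
            for _ in range(3):
                add = rng.uniform(0, 36, n)
                y = np.zeros(n)
                y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
                res = spearman_presence_vs_add(add, y, min_minority=1)
                assert res.method == "exact-permutation"
                assert res.p_value == pytest.approx(
                    brute_permutation_p(add, y), abs=1e-12
                )


CTNT_DP2 = LogisticCurve.from_thresholds("ctnt_dp2", 9.4, 28.2)


def simulate(curve, n, seed, add_max=40.0):
    rng = np.random.default_rng(seed)
    add = rng.uniform(0, add_max, n)
    y = (rng.random(n) < curve.prob(add)).astype(float)
    return add, y


class TestMarkerLogit:
    def test_threshold_recovery_large_n(self):
        """Mean recovered thresholds over seeds match the generating curve;
        each seed stays within ~4 sampling SDs."""
        p50s, p95s = [], []
        for seed in range(20):
            add, y = simulate(CTNT_DP2, 2000, seed=seed)
            res = MarkerLogit(y, add).fit()
            assert res.converged and not res.separation
            p50s.append(res.p50_add)
            p95s.append(res.p95_add)
        assert np.mean(p50s) == pytest.approx(9.4, abs=0.5)
        assert np.mean(p95s) == pytest.approx(28.2, abs=1.5)
        assert np.all(np.abs(np.array(p50s) - 9.4) < 1.8)
        assert np.all(np.abs(np.array(p95s) - 28.2) < 3.4)

    def test_bias_shrinks_with_n(self):
        errs = []
        for n in (100, 1000, 10000):
            add, y = simulate(CTNT_DP2, n, seed=202)
            res = MarkerLogit(y, add).fit()
            errs.append(abs(res.p50_add - 9.4))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.3

    def test_loglike_monotone_over_iterations(self):
        for seed in range(5):
            add, y = simulate(CTNT_DP2, 200, seed=seed)
            res = MarkerLogit(y, add).fit()
            hist = res.llf_history
            assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_matches_reference_mle(self):
        """Independent cross-check against statsmodels' Logit."""
        sm = pytest.importorskip("statsmodels.api")
        add, y = simulate(CTNT_DP2, 500, seed=7)
        ours = MarkerLogit(y, add).fit()
        ref = sm.Logit(y, sm.add_constant(add)).fit(disp=0)
        assert ours.params == pytest.approx(ref.params, abs=1e-6)

    def test_separation_flagged_without_estimates(self):
        add = np.arange(20.0)
        y = (add >= 10).astype(float)
        res = MarkerLogit(y, add).fit()
        assert res.separation and not res.converged
        assert math.isnan(res.p50_add)
        with pytest.raises(ThresholdUndefinedError):
            res.threshold(0.95)

    def test_firth_rescues_separated_data(self):
        add = np.arange(20.0)
        y = (add >= 10).astype(float)
        res = MarkerLogit(y, add).fit(firth=True)
        assert res.separation and res.converged
        assert np.all(np.isfinite(res.params))
        assert 5.0 < res.p50_add < 15.0

    def test_null_data_flagged_wide(self):
        rng = np.random.default_rng(55)
        add = rng.uniform(0, 36, 500)
        y = (rng.random(500) < 0.5).astype(float)
        res = MarkerLogit(y, add).fit()
        assert res.wide

    def test_input_validation(self):
        with pytest.raises(ValueError, match="binary"):
            MarkerLogit([0, 1, 2, 0, 1, 0], np.arange(6.0))
        with pytest.raises(ValueError, match="both presence classes"):
            MarkerLogit(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError, match="at least 6"):
            MarkerLogit([0, 1, 0], [1.0, 2.0, 3.0])


class TestThresholds:
    def test_p50_is_inflection_point(self):
        curve = LogisticCurve("x", -1.4722, 0.15662)
        assert curve.threshold(0.5) == pytest.approx(-curve.beta0 / curve.beta1)

    def test_published_anchor_round_trip(self):
        assert CTNT_DP2.threshold(0.95) == pytest.approx(28.2, abs=1e-9)
        assert CTNT_DP2.threshold(0.5) == pytest.approx(9.4, abs=1e-9)

    def test_unit_slope_p95_is_ln19(self):
        curve = LogisticCurve("x", 0.0, 1.0)
        assert curve.threshold(0.95) == pytest.approx(LN19, abs=1e-12)

    def test_strictly_increasing_in_p(self):
        ts = [CTNT_DP2.threshold(p) for p in (0.1, 0.3, 0.5, 0.7, 0.9, 0.95)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_zero_slope_rejected(self):
        with pytest.raises(ThresholdUndefinedError):
            thresholds_from_fit(LogisticCurve("flat", 0.0, 0.0), 0.95)

    def test_accepts_fit_results(self):
        add, y = simulate(CTNT_DP2, 400, seed=3)
        res = MarkerLogit(y, add).fit()
        assert thresholds_from_fit(res, 0.5) == pytest.approx(res.p50_add)


class TestSubgroups:
    def frame(self, **cols):
        base = {"age": [50.0], "bmi": [25.0], "sex": ["F"]}
        base.update(cols)
        n = max(len(v) for v in base.values())
        return pd.DataFrame({k: v * n if len(v) == 1 else v for k, v in base.items()})

    def test_age_rule_strict(self):
        df = self.frame(age=[2.0, 18.0, 50.0, 80.0, 90.0])
        assert subgroup_filter(df, "age_corrected")["age"].tolist() == [50.0]

    def test_bmi_rule_strict(self):
        df = self.frame(bmi=[10.7, 19.0, 26.2, 30.0, 50.4])
        assert subgroup_filter(df, "bmi_corrected")["bmi"].tolist() == [26.2]

    def test_total_is_identity(self):
        df = self.frame(age=[10.0, 85.0])
        assert subgroup_filter(df, "total") is df

    def test_sex_rules(self):
        df = self.frame(sex=["F", "M", "F"])
        assert len(subgroup_filter(df, "female")) == 2
        assert len(subgroup_filter(df, "male")) == 1

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown subgroup"):
            subgroup_filter(self.frame(), "adults_only")


class TestPanelCalibration:
    def make_data(self, seed=0, n=200, null_product=False):
        rng = np.random.default_rng(seed)
        add = rng.uniform(0, 36, n)
        data = pd.DataFrame(
            {
                "add": add,
                "age": rng.uniform(5, 90, n),
                "bmi": rng.uniform(15, 40, n),
                "sex": rng.choice(["F", "M"], n),
                "ctnt_dp2": (rng.random(n) < CTNT_DP2.prob(add)).astype(int),
                "always_on": np.ones(n, dtype=int),
            }
        )
        if null_product:
            data["null_dp"] = (rng.random(n) < 0.5).astype(int)
        return data

    def test_table_schema_and_statuses(self):
        data = self.make_data(null_product=True)
        results = PanelCalibration(
            data, ["ctnt_dp2", "always_on", "null_dp"]
        ).fit(subgroups=("total", "age_corrected"))
        t = results.table
        assert set(t.columns) >= {
            "product", "group", "n", "n_absent", "n_present",
            "rho", "p_value", "p50_add", "p95_add", "status",
        }
        by = t.set_index(["product", "rule"])
        assert by.loc[("always_on", "total"), "status"] == "few cases"
        assert by.loc[("null_dp", "total"), "status"] == "no significant correlation"
        assert by.loc[("ctnt_dp2", "total"), "status"] == "ok"
        assert (
            by.loc[("ctnt_dp2", "total"), ["n_absent", "n_present"]].sum()
            == by.loc[("ctnt_dp2", "total"), "n"]
        )

    def test_regression_gated_on_significance(self):
        data = self.make_data(null_product=True)
        results = PanelCalibration(data, ["ctnt_dp2", "null_dp"]).fit()
        assert results.get("ctnt_dp2", "total") is not None
        assert results.get("null_dp", "total") is None

    def test_null_product_gated_in_most_replicates(self):
        """Type-I error of the p <= 0.01 gate on a flat-presence product."""
        fitted = 0
        n_reps = 150
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            add = rng.uniform(0, 36, 40)
            y = (rng.random(40) < 0.5).astype(float)
            if min(y.sum(), 40 - y.sum()) < 4:
                continue
            res = spearman_presence_vs_add(add, y)
            fitted += res.p_value <= 0.01
        assert fitted <= 0.05 * n_reps

    def test_missing_calls_dropped_per_product(self):
        data = self.make_data(n=100)
        data.loc[:9, "ctnt_dp2"] = np.nan
        results = PanelCalibration(data, ["ctnt_dp2"]).fit()
        assert results.get("ctnt_dp2", "total").nobs == 90

    def test_empty_subgroup_marked(self):
        data = self.make_data(n=50)
        data["sex"] = "F"
        t = PanelCalibration(data, ["ctnt_dp2"]).fit(subgroups=("male",)).table
        assert t.iloc[0]["status"] == "empty"

    def test_p_display_floor(self):
        data = self.make_data(n=400)
        t = PanelCalibration(data, ["ctnt_dp2"]).fit().table
        row = t.set_index(["product", "rule"]).loc[("ctnt_dp2", "total")]
        assert row["p_value"] < 5e-4 and row["p_display"] == "0.000"

    def test_summary_and_json_round_trip(self, tmp_path):
        from pmidelim.calibration import load_curves

        results = PanelCalibration(self.make_data(), ["ctnt_dp2"]).fit()
        assert "ctnt_dp2" in results.summary()
        out = tmp_path / "cal.json"
        results.to_json(out)
        curves = load_curves(out)
        assert curves[("ctnt_dp2", "total")].beta1 == pytest.approx(
            results.get("ctnt_dp2").beta1
        )
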