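"""Synthetic cohort generator: determinism, nesting, moments, file round trip."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmidelim import (
    GeneratorConfig,
    MarkerSpec,
    TraceConfig,
    call_marker_set,
    cohort_frame,
    cohort_to_files,
    generate_cohort,
    generate_lane_traces,
    read_cohort,
)
from pmidelim.cohort import TruncNormal


def truncnorm_mean(t: TruncNormal) -> float:
    a, b = (t.lo - t.mean) / t.sd, (t.hi - t.mean) / t.sd
    return float(stats.truncnorm.mean(a, b, loc=t.mean, scale=t.sd))


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = cohort_frame(generate_cohort(GeneratorConfig(n_cases=30, seed=9)))
        b = cohort_frame(generate_cohort(GeneratorConfig(n_cases=30, seed=9)))
        c = cohort_frame(generate_cohort(GeneratorConfig(n_cases=30, seed=10)))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_default_cohort_structure(self, cohort40):
        df = cohort_frame(cohort40)
        assert len(df) == 40
        assert (df["add"] >= 0).all()
        # generated ADD span overlaps the calibrated observation range
        assert df["add"].min() < 10 and df["add"].max() > 20
        assert df["sex"].isin(["F", "M"]).all()
        assert set(df["cause_class"]).issubset(
            {"internal", "trauma", "intoxication", "unknown"}
        )

    def test_true_add_consistent_with_profile(self, cohort40):
        from pmidelim import compute_add

        for case in cohort40:
            assert case.true_add == pytest.approx(
                compute_add(case.profile, case.pmi_h), abs=1e-12
            )

    def test_nesting_never_violated(self):
        cases = generate_cohort(GeneratorConfig(n_cases=2000, seed=17))
        for c in cases:
            p = c.true_presence
            assert not (p["desmin_dp2"] == 1 and p["desmin_dp1"] == 0)
            assert not (p["desmin_dp3"] == 1 and (p["desmin_dp1"] == 0 or p["desmin_dp2"] == 0))

    def test_all_cooled_zero_ambient_time(self):
        """With certain cooling that always outlasts the PMI, ADD = pmi/24 * 4."""
        cfg = replace(
            GeneratorConfig(n_cases=50, seed=3),
            cooling_fraction=1.0,
            cooling_time_h=TruncNormal(500.0, 1.0, 92.9, 1000.0),
            max_scene_h=0.0,
        )
        for c in generate_cohort(cfg):
            assert c.true_add == pytest.approx(c.pmi_h / 24 * 4, abs=1e-9)

    def test_moments_match_configured_distributions(self):
        cfg = GeneratorConfig(n_cases=10000, seed=21)
        df = cohort_frame(generate_cohort(cfg))
        for col, dist in (("age", cfg.age_y), ("bmi", cfg.bmi)):
            se = df[col].std() / np.sqrt(len(df))
            assert abs(df[col].mean() - truncnorm_mean(dist)) < 3 * se
        # PMI is a cooled/uncooled mixture of truncated normals
        pmi_target = cfg.cooling_fraction * truncnorm_mean(cfg.pmi_h) + (
            1 - cfg.cooling_fraction
        ) * truncnorm_mean(cfg.pmi_h_uncooled)
        se = df["pmi_h"].std() / np.sqrt(len(df))
        assert abs(df["pmi_h"].mean() - pmi_target) < 3 * se
        sex_se = np.sqrt(0.575 * 0.425 / len(df))
        assert abs((df["sex"] == "F").mean() - cfg.female_fraction) < 3 * sex_se

    def test_marginal_presence_matches_curve_at_p50(self):
        """Empirical presence frequency of cTnT dp2 near its P50 is ~0.5."""
        df = cohort_frame(generate_cohort(GeneratorConfig(n_cases=10000, seed=29)))
        band = df[(df["add"] >= 9.0) & (df["add"] <= 9.8)]
        assert len(band) > 100
        assert band["ctnt_dp2"].mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_config_rejected_before_draws(self):
        with pytest.raises(ValueError):
            GeneratorConfig(cooling_fraction=1.5).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(
                markers=(MarkerSpec("a", 1, 5), MarkerSpec("b", 1, 5, parent="zz"))
            ).validate()
        with pytest.raises(ValueError):
            MarkerSpec("bad", 10, 5)

    def test_extreme_slope_factor_flattens_extremes(self):
        cfg = replace(
            GeneratorConfig(n_cases=4000, seed=5), extreme_slope_factor=0.25
        )
        df = cohort_frame(generate_cohort(cfg))
        extreme = ~(
            df["age"].between(18, 80, inclusive="neither")
            & df["bmi"].between(19, 30, inclusive="neither")
        )
        # flattened curve raises presence probability far below P50
        low = df[df["add"] < 4]
        assert (
            low[extreme.loc[low.index]]["ctnt_dp2"].mean()
            > low[~extreme.loc[low.index]]["ctnt_dp2"].mean()
        )


class TestLaneTraces:
    def test_zero_noise_round_trip_exact(self, panel, cohort40):
        for case in cohort40[:15]:
            traces = generate_lane_traces(
                case, panel, TraceConfig(noise_sd=0.0, drift_amp=0.0), seed=2
            )
            calls = call_marker_set(traces, panel)
            assert {k: calls.presence[k] for k in case.true_presence} == case.true_presence

    def test_forced_half_percent_called_absent(self, panel, cohort40):
        case = replace(cohort40[0], true_presence=dict.fromkeys(cohort40[0].true_presence, 1))
        cfg = TraceConfig(
            noise_sd=0.0, drift_amp=0.0, forced_area_frac={"ctnt_dp2": 0.005}
        )
        calls = call_marker_set(generate_lane_traces(case, panel, cfg, seed=2), panel)
        assert calls.presence["ctnt_dp2"] == 0
        assert calls.presence["ctnt_dp1"] == 1

    def test_high_noise_degrades_gracefully(self, panel, cohort40):
        """SNR ~2: calls may err but nothing crashes and output stays binary."""
        cfg = TraceConfig(noise_sd=28.0)
        assert cfg.snr() == pytest.approx(2.0, rel=0.05)
        for case in cohort40[:5]:
            calls = call_marker_set(generate_lane_traces(case, panel, cfg, seed=2), panel)
            assert all(v in (0, 1, "missing") for v in calls.presence.values())

    def test_deterministic_given_seed(self, panel, cohort40):
        t1 = generate_lane_traces(cohort40[0], panel, seed=4)
        t2 = generate_lane_traces(cohort40[0], panel, seed=4)
        for assay in t1:
            np.testing.assert_array_equal(t1[assay].intensities, t2[assay].intensities)


class TestFileRoundTrip:
    def test_write_read_equal(self, tmp_path, cohort40):
        out = cohort_to_files(cohort40, tmp_path / "cohort")
        cases, profiles, calls = read_cohort(out)
        df = cohort_frame(cohort40)
        assert cases["id"].tolist() == df["id"].tolist()
        np.testing.assert_allclose(cases["add"], df["add"], atol=1e-9)
        merged = cases.merge(calls, on="id")
        for m in cohort40[0].true_presence:
            assert merged[m].tolist() == df[m].tolist()

    def test_empty_cohort_valid_files(self, tmp_path):
        out = cohort_to_files([], tmp_path / "empty")
        cases, profiles, calls = read_cohort(out)
        assert len(cases) == 0 and profiles == {}

    def test_rewrite_byte_identical(self, tmp_path, cohort40):
        d1 = cohort_to_files(cohort40, tmp_path / "a", traces=True, seed=6)
        d2 = cohort_to_files(cohort40, tmp_path / "b", traces=True, seed=6)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*.csv"))
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*.csv"))
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
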