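"""Generator: allocation arithmetic, distributional targets, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialcua import (
    GeneratorTruth,
    TrialDesign,
    apply_missingness,
    generate_trial,
    null_truth,
    target_d_design,
    target_d_truth,
    truth_summary,
)
from trialcua.synthetic import MISSINGNESS_KEYS


class TestAllocation:
    def test_largest_remainder_reproduces_published_strata(self):
        d = TrialDesign(n_total=1868, group_props=(1357 / 1868, 288 / 1868, 223 / 1868))
        assert d.stratum_sizes() == {
            "minimal_mild": 1357,
            "moderate": 288,
            "severe": 223,
        }

    def test_preset_arm_splits(self):
        assert target_d_design().arm_sizes() == {
            "minimal_mild": (679, 678),
            "moderate": (143, 145),
            "severe": (111, 112),
        }

    def test_degenerate_two_participants_single_stratum(self):
        d = TrialDesign(n_total=2, group_props=(1.0, 0.0, 0.0), n_clinics=1)
        df = generate_trial(d, target_d_truth(), seed=0)
        assert len(df) == 2
        assert set(df["arm"]) == {"intervention", "control"}
        assert (df["group"] == "minimal_mild").all()

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(group_props=(0.5, 0.3, 0.3)), "sum to 1"),
            (dict(n_total=10, n_clinics=14), "n_clinics"),
            (dict(horizons=(0.0, 1.0, 0.25)), "increasing"),
        ],
    )
    def test_invalid_design_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            TrialDesign(**kwargs)


class TestGeneration:
    def test_seed_determinism_byte_identical(self, small_design, truth, unit_costs):
        a = generate_trial(small_design, truth, seed=5, unit_costs=unit_costs)
        b = generate_trial(small_design, truth, seed=5, unit_costs=unit_costs)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = generate_trial(small_design, truth, seed=6, unit_costs=unit_costs)
        assert not a["utility_0m"].equals(c["utility_0m"])

    def test_baseline_fields_complete(self, preset_records):
        assert not preset_records.isna().any().any()

    def test_cost_skewness_positive_per_cell(self, preset_records, unit_costs):
        from trialcua.costing import value_resource_use

        valued = value_resource_use(preset_records, unit_costs, "w1")["hc_component_w1"]
        for (g, a), idx in preset_records.groupby(["group", "arm"], observed=True).groups.items():
            assert stats.skew(valued.loc[idx]) > 0, (g, a)

    def test_utility_range_respected(self, preset_records):
        for col in ("utility_0m", "utility_3m", "utility_12m"):
            assert preset_records[col].between(-0.04, 1.0).all()

    def test_null_truth_contrasts_centered_at_zero(self, unit_costs):
        """Large-sample Monte-Carlo check that a null generator produces
        no arm contrast in either costs or utilities."""
        d = TrialDesign(n_total=50_000, group_props=(0.726, 0.155, 0.119), n_clinics=14)
        # zero intervention component: the null applies to the health-sector
        # total, so utilization alone is only null when delivery is free
        truth = null_truth(
            intervention_component={g: 0.0 for g in ("minimal_mild", "moderate", "severe")}
        )
        df = generate_trial(d, truth, seed=11, unit_costs=unit_costs)
        from trialcua.costing import value_resource_use

        cost = value_resource_use(df, unit_costs, "w1")["hc_component_w1"]
        for series in (cost, df["utility_12m"]):
            gi = series[df["arm"] == "intervention"]
            gc = series[df["arm"] == "control"]
            diff = gi.mean() - gc.mean()
            se = np.sqrt(gi.var(ddof=1) / len(gi) + gc.var(ddof=1) / len(gc))
            assert abs(diff) < 3 * se

    def test_utility_cell_means_match_truth(self, unit_costs):
        """Location-solved truncated normals hit the target means exactly
        in expectation (checked at Monte-Carlo scale)."""
        d = TrialDesign(n_total=50_000, group_props=(1.0, 0.0, 0.0), n_clinics=2)
        truth = target_d_truth(clinic_sd_utility=0.0)  # isolate the location solver
        df = generate_trial(d, truth, seed=3, unit_costs=unit_costs)
        ctrl = df[df["arm"] == "control"]
        target = truth.control_utility["minimal_mild"][2]
        se = ctrl["utility_12m"].std(ddof=1) / np.sqrt(len(ctrl))
        assert abs(ctrl["utility_12m"].mean() - target) < 3 * se

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError, match="control_health_cost"):
            GeneratorTruth(control_health_cost={"minimal_mild": (-5.0, 10.0)})
        with pytest.raises(ValueError, match="missingness_targets"):
            GeneratorTruth(missingness_targets=(0.4, 1.0, 0.4, 0.4))


class TestMissingness:
    def test_realized_rates_near_targets_at_preset_scale(self, preset_records, truth):
        miss = apply_missingness(preset_records, truth, "MAR", seed=19)
        realized = {
            "ruq_3m": miss["ru_gp_w1"].isna().mean(),
            "ruq_12m": miss["ru_gp_w2"].isna().mean(),
            "aqol_3m": miss["utility_3m"].isna().mean(),
            "aqol_12m": miss["utility_12m"].isna().mean(),
        }
        for key, target in zip(MISSINGNESS_KEYS, truth.missingness_targets):
            assert abs(realized[key] - target) <= 0.02, (key, realized[key])

    def test_calibration_tight_at_large_n(self, unit_costs, truth):
        d = TrialDesign(n_total=20_000, group_props=(0.726, 0.155, 0.119), n_clinics=14)
        df = generate_trial(d, truth, seed=21, unit_costs=unit_costs)
        miss = apply_missingness(df, truth, "MAR", seed=22)
        assert abs(miss["utility_12m"].isna().mean() - 0.66) < 0.015

    def test_zero_targets_leave_records_unchanged(self, preset_records):
        truth0 = target_d_truth(missingness_targets=(0.0, 0.0, 0.0, 0.0))
        out = apply_missingness(preset_records, truth0, "MAR", seed=1)
        pd.testing.assert_frame_equal(out, preset_records)

    def test_targets_at_or_above_one_rejected(self, preset_records):
        bad = target_d_truth(missingness_targets=(0.46, 0.6, 0.49, 0.99))
        object.__setattr__(bad, "missingness_targets", (0.46, 0.6, 0.49, 1.0))
        with pytest.raises(ValueError):
            apply_missingness(preset_records, bad, "MAR", seed=1)

    def test_mar_education_gradient(self, unit_costs):
        """A strong negative education coefficient concentrates missingness
        in the lowest-education tertile."""
        d = TrialDesign(n_total=20_000, group_props=(1.0, 0.0, 0.0), n_clinics=2)
        truth = target_d_truth(
            mar_coefficients={"education": -1.0},
            missingness_targets=(0.5, 0.0, 0.0, 0.0),
        )
        df = generate_trial(d, truth, seed=31, unit_costs=unit_costs)
        miss = apply_missingness(df, truth, "MAR", seed=32)
        rate = miss.groupby("education")["ru_gp_w1"].apply(lambda s: s.isna().mean())
        assert rate.loc[1] > rate.loc[3]

    def test_baseline_untouched_and_mcar_unbiased(self, preset_records, truth):
        miss = apply_missingness(preset_records, truth, "MCAR", seed=44)
        baseline = [c for c in preset_records.columns if not c.endswith(("_w1", "_w2", "_3m", "_12m"))]
        pd.testing.assert_frame_equal(miss[baseline], preset_records[baseline])
        cc = miss["utility_12m"].dropna()
        full = preset_records["utility_12m"]
        se = full.std(ddof=1) * np.sqrt(1 / len(cc) + 1 / len(full))
        assert abs(cc.mean() - full.mean()) < 3 * se


class TestTruthSummary:
    def test_single_stratum_delta_cost(self):
        d = TrialDesign(n_total=100, group_props=(1.0, 0.0, 0.0), n_clinics=2)
        truth = GeneratorTruth(
            control_health_cost={"minimal_mild": (1000.0, 1.0)},
            cost_ratio_3m=0.9,
            cost_ratio_12m=0.9,
            intervention_component={"minimal_mild": 0.0},
        )
        ts = truth_summary(d, truth)
        assert ts["delta_cost"]["health_sector"]["3m"] == pytest.approx(-100.0)

    def test_two_strata_mixture(self):
        d = TrialDesign(n_total=100, group_props=(0.5, 0.5, 0.0), n_clinics=2)
        truth = GeneratorTruth(
            control_health_cost={"minimal_mild": (1000.0, 1.0), "moderate": (2000.0, 1.0)},
            cost_ratio_3m=0.9,
            cost_ratio_12m=0.9,
            intervention_component={"minimal_mild": 0.0, "moderate": 0.0},
        )
        ts = truth_summary(d, truth)
        assert ts["delta_cost"]["health_sector"]["3m"] == pytest.approx(-150.0)

    def test_preset_qaly_difference_exact(self):
        ts = truth_summary(target_d_design(), target_d_truth())
        assert ts["delta_qaly"]["12m"] == pytest.approx(0.011)
        assert ts["delta_qaly"]["3m"] == pytest.approx(0.002)
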