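"""Decision layer: ICER trichotomy, angular CIs, CEAC identities, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from trialcua.cea import (
    DOMINANT,
    DOMINATED,
    bootstrap_cea,
    ceac,
    icer,
    icer_percentile_ci,
    quadrant_counts,
    summarize_cell,
)
from trialcua.costing import InterventionCostSchedule
from trialcua.dataset import build_analysis_dataset, derive_outcomes
from trialcua.estimation import GlmSpec, fit_glm
from trialcua.imputation import ImputationSpec


class TestIcer:
    @pytest.mark.parametrize(
        "dc,de,expected",
        [
            (-155.0, 0.011, DOMINANT),
            (100.0, -0.01, DOMINATED),
            (500.0, 0.01, 50_000.0),
            (-500.0, -0.01, 50_000.0),  # SW: savings per QALY forgone
            (100.0, 0.0, np.inf),
            (-100.0, 0.0, -np.inf),
        ],
    )
    def test_point_classification(self, dc, de, expected):
        assert icer(dc, de) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            icer(np.nan, 0.01)

    def test_trichotomy_conserves_draws(self):
        rng = np.random.default_rng(0)
        dc, de = rng.normal(0, 200, 500), rng.normal(0, 0.01, 500)
        labels = [icer(c, e) for c, e in zip(dc, de)]
        n_dom = sum(1 for x in labels if x == DOMINANT)
        n_ded = sum(1 for x in labels if x == DOMINATED)
        n_num = sum(1 for x in labels if not isinstance(x, str))
        assert n_dom + n_ded + n_num == 500
        counts = quadrant_counts(dc, de)
        assert sum(counts.values()) == 500
        assert counts["SE"] == n_dom


class TestCeac:
    def test_hand_enumeration_at_threshold(self):
        dc = np.array([100.0, -50.0, 150.0])
        de = np.array([0.001, 0.002, 0.003])
        out = ceac(dc, de, [50_000.0])
        # NMBs are -50, +150, 0; ties count as not cost-effective
        assert out["probability"].iloc[0] == pytest.approx(1 / 3)

    def test_all_dominant_draws_give_probability_one(self):
        out = ceac(np.full(10, -5.0), np.full(10, 0.01), [0.0, 50_000.0, 1e9])
        assert (out["probability"] == 1.0).all()

    def test_limits_are_exact_closed_forms(self):
        rng = np.random.default_rng(3)
        dc, de = rng.normal(10, 300, 2000), rng.normal(0.001, 0.01, 2000)
        out = ceac(dc, de, [0.0, 1e9]).set_index("lambda")
        assert out.loc[0.0, "probability"] == (dc < 0).mean()
        assert out.loc[1e9, "probability"] == (de > 0).mean()

    def test_nmb_rule_matches_quadrant_decomposition(self):
        """P(NMB>0) must equal P(SE) + P(NE & ICER<lam) + P(SW & |ICER|>lam)."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(20, 200)
            dc = rng.normal(rng.normal(0, 100), 300, n)
            de = rng.normal(rng.normal(0, 0.005), 0.01, n)
            lam = rng.uniform(0, 120_000)
            se = (de > 0) & (dc < 0)
            ne = (de > 0) & (dc >= 0)
            sw = (de < 0) & (dc < 0)
            oracle = (
                se.sum()
                + (ne & (dc < lam * de)).sum()
                + (sw & (dc / de > lam)).sum()
                + ((de == 0) & (dc < 0)).sum()
            ) / n
            got = ceac(dc, de, [lam])["probability"].iloc[0]
            assert got == pytest.approx(oracle)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.zeros(3), np.zeros(3), [-1.0, 5.0])


class TestAngularCI:
    def test_all_ne_draws_bracket_angular_mass(self):
        rng = np.random.default_rng(5)
        B = 400
        icers = rng.uniform(10_000, 90_000, B)
        de = rng.uniform(0.005, 0.02, B)
        dc = icers * de
        lo, hi = icer_percentile_ci(dc, de)
        assert 10_000 <= lo <= hi <= 90_000
        # brute-force oracle: sort by angle independently
        ang = np.sort(np.arctan2(dc, de))
        oracle_lo = np.tan(ang[int(np.floor(0.025 * (B - 1)))])
        oracle_hi = np.tan(ang[int(np.ceil(0.975 * (B - 1)))])
        assert lo == pytest.approx(oracle_lo, rel=1e-9)
        assert hi == pytest.approx(oracle_hi, rel=1e-9)

    def test_four_quadrant_spread_reports_dominance_labels(self):
        """Mostly dominant draws with a >2.5% dominated tail reproduce the
        'Dominant to Dominated' interval style."""
        rng = np.random.default_rng(6)
        dc = np.concatenate(
            [
                -rng.uniform(50, 300, 920),  # SE: dominant
                rng.uniform(50, 300, 40),  # NE
                rng.uniform(50, 300, 30),  # NW: dominated
                -rng.uniform(50, 300, 10),  # SW
            ]
        )
        de = np.concatenate(
            [
                rng.uniform(0.001, 0.02, 960),
                -rng.uniform(0.001, 0.02, 40),
            ]
        )
        lo, hi = icer_percentile_ci(dc, de)
        assert lo == DOMINANT
        assert hi == DOMINATED

    def test_identical_draws_degenerate_interval(self):
        dc, de = np.full(50, -100.0), np.full(50, 0.01)
        assert icer_percentile_ci(dc, de) == (DOMINANT, DOMINANT)

    def test_raw_mode_quantiles(self):
        rng = np.random.default_rng(8)
        de = rng.uniform(0.005, 0.02, 200)
        vals = rng.uniform(1_000, 99_000, 200)
        lo, hi = icer_percentile_ci(vals * de, de, mode="raw")
        assert lo == pytest.approx(np.quantile(vals, 0.025), rel=0.05)
        assert hi == pytest.approx(np.quantile(vals, 0.975), rel=0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="40"):
            icer_percentile_ci(np.zeros(10), np.ones(10))


class TestBootstrap:
    def test_deterministic_given_seed(self, small_analysis, schedule):
        spec = ImputationSpec(m=1, n_iterations=3, seed=0)
        kw = dict(B=5, seed=3, perspectives=("health_sector",), horizons=("12m",))
        a = bootstrap_cea(small_analysis, spec, schedule, **kw)
        b = bootstrap_cea(small_analysis, spec, schedule, **kw)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_single_replicate_identity_on_complete_data(
        self, small_records, unit_costs, schedule
    ):
        """B=1 without resampling on complete data reproduces the m=1
        point estimates from the estimation module."""
        analysis = build_analysis_dataset(small_records, unit_costs)
        spec = ImputationSpec(m=1, seed=0)
        draws = bootstrap_cea(
            analysis,
            spec,
            schedule,
            B=1,
            seed=1,
            perspectives=("health_sector",),
            horizons=("12m",),
            resample=False,
        )
        dc, de = draws.cell("health_sector", "12m")
        derived = derive_outcomes(analysis, schedule)
        cfit = fit_glm(derived, GlmSpec("health_sector_cost", "12m"))
        qfit = fit_glm(derived, GlmSpec("qaly", "12m"))
        assert dc[0] == pytest.approx(cfit.adj_mean_intervention - cfit.adj_mean_control)
        assert de[0] == pytest.approx(qfit.adj_mean_intervention - qfit.adj_mean_control)

    def test_forced_quadrant(self, schedule):
        """When every intervention participant is cheaper and healthier the
        draw cloud must sit entirely in the dominant quadrant."""
        rng = np.random.default_rng(13)
        n = 240
        arm = np.array(["intervention", "control"] * (n // 2))
        df = pd.DataFrame(
            {
                "id": np.arange(n),
                "arm": arm,
                "group": "minimal_mild",
                "clinic": rng.integers(0, 2, n),
                "age": rng.integers(18, 66, n),
                "gender": "female",
                "education": rng.integers(1, 4, n),
                "employment": "employed",
                "health_care_card": False,
                "long_term_illness": False,
                "lives_alone": False,
                "past_psych_visits": 0,
                "antidepressant_use": False,
                "phq9_baseline": rng.integers(2, 20, n),
                "utility_0m": 0.6,
                "utility_3m": np.where(arm == "intervention", 0.9, 0.3),
                "utility_12m": np.where(arm == "intervention", 0.9, 0.3),
                "hs_util_w1": np.where(arm == "intervention", 100.0, 5000.0)
                * rng.uniform(0.8, 1.2, n),
                "hs_util_w2": np.where(arm == "intervention", 100.0, 5000.0)
                * rng.uniform(0.8, 1.2, n),
                "prod_w1": 0.0,
                "prod_w2": 0.0,
            }
        )
        draws = bootstrap_cea(
            df,
            ImputationSpec(m=1, seed=0),
            schedule,
            B=8,
            seed=5,
            perspectives=("health_sector",),
            horizons=("12m",),
        )
        dc, de = draws.cell("health_sector", "12m")
        assert (dc < 0).all() and (de > 0).all()

    def test_summary_and_export_deterministic(self, tmp_path):
        rng = np.random.default_rng(1)
        dc, de = rng.normal(-100, 150, 200), rng.normal(0.01, 0.006, 200)
        res = summarize_cell(float(dc.mean()), float(de.mean()), dc, de)
        assert sum(res.quadrant_counts.values()) == 200
        assert res.icer_point == DOMINANT
        assert 0 <= res.p_ce_at_threshold <= 1
        from trialcua.cea import export_decision_outputs

        p1 = export_decision_outputs(res, dc, de, tmp_path / "a")
        p2 = export_decision_outputs(res, dc, de, tmp_path / "b")
        assert p1["plane_csv"].read_bytes() == p2["plane_csv"].read_bytes()
        assert p1["ceac_csv"].read_bytes() == p2["ceac_csv"].read_bytes()
        assert p1["summary_json"].read_bytes() == p2["summary_json"].read_bytes()
        assert len(pd.read_csv(p1["ceac_csv"])) == len(res.ceac)
        assert len(pd.read_csv(p1["plane_csv"])) == 200
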