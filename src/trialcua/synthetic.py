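"""Synthetic two-arm trial generator with known ground truth.

Emulates a 1:1 randomised primary-care depression trial stratified by a
three-level prognostic group (minimal/mild, moderate, severe): right-skewed
health-care and productivity costs, AQoL-8D-range utility trajectories at
0/3/12 months, and missing-at-random follow-up loss at configurable rates.
Every distributional target is recorded in :class:`GeneratorTruth`, and
:func:`truth_summary` returns the closed-form expected arm contrasts so the
full analysis pipeline can be tested for parameter recovery.

Mechanics worth knowing:

* Utilities are drawn from normals truncated to the instrument range by
  location-solving (the location parameter is found numerically so the
  truncated mean equals the target cell mean *exactly*), not by clipping.
* A participant's valued health-care cost is generated by drawing a gamma
  "spend" target and decomposing it into Poisson category counts with means
  ``share_c * spend / unit_cost_c``; valuing the counts back through the
  unit-cost table recovers the gamma mean exactly while keeping quantities
  integer and the cost distribution right-skewed.
* A Gaussian copula links utilities and costs within participant; the
  cost-utility cross-correlation defaults to 0 (independence given stratum).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, ndtr

from . import schema
from .costing import UnitCostTable

_TIME_INDEX = {0.0: 0, 0.25: 1, 1.0: 2}

#: instrument x wave keys for missingness targets, in canonical order
MISSINGNESS_KEYS = ("ruq_3m", "ruq_12m", "aqol_3m", "aqol_12m")


# ---------------------------------------------------------------------------
# design and truth


@dataclass(frozen=True)
class TrialDesign:
    """Trial size, stratification and allocation."""

    n_total: int = 1868
    group_props: tuple[float, float, float] = (1357 / 1868, 288 / 1868, 223 / 1868)
    n_clinics: int = 14
    allocation_ratio: tuple[int, int] = (1, 1)
    horizons: tuple[float, float, float] = (0.0, 0.25, 1.0)
    #: optional explicit per-stratum (intervention, control) counts; when
    #: given they override prop-based sizing and must sum to n_total
    arm_counts: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        props = np.asarray(self.group_props, dtype=float)
        if not np.all((props >= 0) & (props < 1 + 1e-9)):
            raise ValueError(f"group_props out of (0,1): {self.group_props}")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"group_props must sum to 1, got {props.sum()!r}")
        if self.n_total < 2 * self.n_clinics:
            raise ValueError("n_total must be at least 2 x n_clinics")
        h = self.horizons
        if h[0] != 0 or not (h[0] < h[1] < h[2]):
            raise ValueError(f"horizons must be strictly increasing from 0: {h}")
        if min(self.allocation_ratio) < 1:
            raise ValueError(f"invalid allocation_ratio {self.allocation_ratio}")
        if self.arm_counts is not None:
            total = sum(a + b for a, b in self.arm_counts.values())
            if total != self.n_total:
                raise ValueError(
                    f"arm_counts sum to {total}, expected n_total={self.n_total}"
                )

    def stratum_sizes(self) -> dict[str, int]:
        """Stratum sizes by largest-remainder rounding of group_props."""
        if self.arm_counts is not None:
            return {g: a + b for g, (a, b) in self.arm_counts.items()}
        raw = np.asarray(self.group_props) * self.n_total
        base = np.floor(raw).astype(int)
        short = self.n_total - base.sum()
        order = np.argsort(-(raw - base))  # largest fractional remainders first
        base[order[:short]] += 1
        return dict(zip(schema.GROUPS, (int(x) for x in base)))

    def arm_sizes(self) -> dict[str, tuple[int, int]]:
        """(intervention, control) counts per stratum.

        Explicit ``arm_counts`` win; otherwise a deterministic alternating
        assignment resolves any within-stratum imbalance (intervention gets
        the extra participant in odd strata under 1:1 allocation).
        """
        if self.arm_counts is not None:
            return dict(self.arm_counts)
        a, b = self.allocation_ratio
        out = {}
        for g, n in self.stratum_sizes().items():
            pattern = np.tile(
                np.array([0] * a + [1] * b), n // (a + b) + 1
            )[:n]
            out[g] = (int((pattern == 0).sum()), int((pattern == 1).sum()))
        return out


def _as_group_map(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        return {g: float(v) for g, v in value.items()}
    return {g: float(value) for g in schema.GROUPS}


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters of the synthetic trial.

    Defaults reproduce the target_d preset: control-arm window cost means
    and utility means calibrated to the trial's published magnitudes, a
    uniform per-stratum multiplicative arm effect on cumulative health-sector
    cost (0.99 at 3 m, 0.91 at 12 m) and an additive utility shift giving a
    QALY difference of 0.002 at 3 m and 0.011 at 12 m.
    """

    # control-arm mean valued health-care cost per window (w1 = 0-3 m, w2 = 3-12 m)
    control_health_cost: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "minimal_mild": (509.0, 1056.0),
            "moderate": (947.0, 1187.0),
            "severe": (966.0, 1666.0),
        }
    )
    # multiplicative arm effect on cumulative health-sector totals
    cost_ratio_3m: float | dict = 0.99
    cost_ratio_12m: float | dict = 0.91
    # control-arm mean productivity cost per window
    control_prod_cost: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "minimal_mild": (4347.0, 11404.0),
            "moderate": (4349.0, 11763.0),
            "severe": (3571.0, 10528.0),
        }
    )
    prod_ratio_3m: float | dict = 1.084
    prod_ratio_12m: float | dict = 0.986
    cost_shape: float | dict = 0.35
    prod_shape: float = 0.5
    # control-arm utility means at (0, 3, 12) months
    control_utility: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "minimal_mild": (0.650, 0.654, 0.674),
            "moderate": (0.440, 0.424, 0.528),
            "severe": (0.340, 0.340, 0.412),
        }
    )
    # additive intervention-arm shift at (0, 3, 12) months, identical across strata
    utility_arm_shift: tuple[float, float, float] = (0.0, 0.016, 0.008)
    utility_sd: float = 0.2
    # fractions missing for (RUQ 3m, RUQ 12m, AQoL 3m, AQoL 12m)
    missingness_targets: tuple[float, float, float, float] = (0.46, 0.60, 0.49, 0.66)
    # per-person intervention cost charged in w1 (screening + treatment);
    # must match the costing schedule used downstream for truths to carry over
    intervention_component: dict[str, float] = field(
        default_factory=lambda: {"minimal_mild": 14.96, "moderate": 132.96, "severe": 676.96}
    )
    copula_cost_utility: float = 0.0
    utility_time_corr: float = 0.6
    cost_window_corr: float = 0.5
    clinic_sd_utility: float = 0.02
    clinic_sd_logcost: float = 0.05
    # value shares of health-care spend by RUQ category
    ru_value_shares: dict[str, float] = field(
        default_factory=lambda: {
            "gp": 0.30,
            "psychologist": 0.20,
            "psychiatrist": 0.05,
            "diagnostic_test": 0.10,
            "medication_script": 0.15,
            "hospital_day": 0.12,
            "ed_visit": 0.05,
            "community_mh": 0.03,
        }
    )
    prod_paid_share: float = 0.6
    # MAR missingness log-odds coefficients on standardised baseline covariates
    mar_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.25,
            "gender_female": -0.20,
            "education": -0.35,
            "past_psych_visits": 0.15,
        }
    )
    # latent correlation between 3 m and 12 m missingness within an instrument
    wave_dependence: float = 0.0
    phq9_mean: dict[str, float] = field(
        default_factory=lambda: {"minimal_mild": 6.0, "moderate": 11.0, "severe": 16.0}
    )
    phq9_sd: float = 4.0

    def __post_init__(self) -> None:
        for g, (w1, w2) in self.control_health_cost.items():
            if w1 <= 0 or w2 <= 0:
                raise ValueError(f"control_health_cost[{g!r}] must be positive")
        for g, (w1, w2) in self.control_prod_cost.items():
            if w1 < 0 or w2 < 0:
                raise ValueError(f"control_prod_cost[{g!r}] must be nonnegative")
        for g, us in self.control_utility.items():
            for u in us:
                if not (schema.UTILITY_MIN <= u <= schema.UTILITY_MAX):
                    raise ValueError(
                        f"control_utility[{g!r}] outside instrument range: {u}"
                    )
        for t in self.missingness_targets:
            if not (0 <= t < 1):
                raise ValueError(
                    f"missingness_targets must be in [0,1), got {self.missingness_targets}"
                )
        if abs(sum(self.ru_value_shares.values()) - 1.0) > 1e-9:
            raise ValueError("ru_value_shares must sum to 1")
        if not (0 <= self.prod_paid_share <= 1):
            raise ValueError("prod_paid_share must be in [0,1]")

    # -- derived expectations -------------------------------------------------

    def cost_ratio(self, group: str, horizon: str) -> float:
        r = self.cost_ratio_3m if horizon == "3m" else self.cost_ratio_12m
        return _as_group_map(r, "cost_ratio")[group]

    def prod_ratio(self, group: str, horizon: str) -> float:
        r = self.prod_ratio_3m if horizon == "3m" else self.prod_ratio_12m
        return _as_group_map(r, "prod_ratio")[group]

    def health_cost_mean(self, group: str, arm: str, window: str) -> float:
        """Mean valued health-care use (excl. intervention component)."""
        w1c, w2c = self.control_health_cost[group]
        if arm == "control":
            return w1c if window == "w1" else w2c
        # intervention arm: back out utilization so cumulative totals hit
        # ratio x control totals with the intervention component in w1
        m3c, m12c = w1c, w1c + w2c
        r3, r12 = self.cost_ratio(group, "3m"), self.cost_ratio(group, "12m")
        if window == "w1":
            m = r3 * m3c - self.intervention_component[group]
        else:
            m = r12 * m12c - r3 * m3c
        if m <= 0:
            raise ValueError(
                f"implied intervention health-care mean nonpositive for "
                f"group={group!r} window={window!r} (cost ratios too small "
                f"relative to intervention_component)"
            )
        return m

    def prod_cost_mean(self, group: str, arm: str, window: str) -> float:
        w1c, w2c = self.control_prod_cost[group]
        if arm == "control":
            return w1c if window == "w1" else w2c
        r3, r12 = self.prod_ratio(group, "3m"), self.prod_ratio(group, "12m")
        if window == "w1":
            return r3 * w1c
        m = r12 * (w1c + w2c) - r3 * w1c
        if m < 0:
            raise ValueError(f"implied intervention productivity mean negative ({group})")
        return m

    def utility_mean(self, group: str, arm: str, t_index: int) -> float:
        u = self.control_utility[group][t_index]
        if arm == "intervention":
            u = u + self.utility_arm_shift[t_index]
        return u

    @property
    def true_qaly_diff_3m(self) -> float:
        s0, s3, _ = self.utility_arm_shift
        return 0.25 * (s0 + s3) / 2.0

    @property
    def true_qaly_diff(self) -> float:
        """Additive 12-month QALY arm effect implied by the utility shifts."""
        _, s3, s12 = self.utility_arm_shift
        return self.true_qaly_diff_3m + 0.75 * (s3 + s12) / 2.0


def target_d_design() -> TrialDesign:
    """Preset reproducing the published design constants, including the
    exact per-stratum arm splits (679/678, 143/145, 111/112)."""
    # exact count-based proportions (the rounded percentages 72.6/15.4/11.9
    # do not sum to 1); largest-remainder sizing recovers 1357/288/223
    return TrialDesign(
        n_total=1868,
        group_props=(1357 / 1868, 288 / 1868, 223 / 1868),
        n_clinics=14,
        arm_counts={
            "minimal_mild": (679, 678),
            "moderate": (143, 145),
            "severe": (111, 112),
        },
    )


def target_d_truth(**overrides) -> GeneratorTruth:
    return GeneratorTruth(**overrides)


def null_truth(**overrides) -> GeneratorTruth:
    """Truth with no arm effect on costs, productivity or utilities."""
    base = dict(
        cost_ratio_3m=1.0,
        cost_ratio_12m=1.0,
        prod_ratio_3m=1.0,
        prod_ratio_12m=1.0,
        utility_arm_shift=(0.0, 0.0, 0.0),
    )
    base.update(overrides)
    return GeneratorTruth(**base)


# ---------------------------------------------------------------------------
# truncated-normal location solving


def _truncnorm_mean(loc: float, sd: float) -> float:
    a = (schema.UTILITY_MIN - loc) / sd
    b = (schema.UTILITY_MAX - loc) / sd
    return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))


_loc_cache: dict[tuple[float, float], float] = {}


def _solve_truncnorm_loc(target_mean: float, sd: float) -> float:
    """Location such that the [-0.04, 1]-truncated normal mean hits target."""
    key = (round(target_mean, 12), round(sd, 12))
    if key not in _loc_cache:
        f = lambda loc: _truncnorm_mean(loc, sd) - target_mean
        _loc_cache[key] = optimize.brentq(
            f, target_mean - 5 * sd, target_mean + 5 * sd, xtol=1e-12
        )
    return _loc_cache[key]


# ---------------------------------------------------------------------------
# generation


def _copula_cholesky(truth: GeneratorTruth) -> np.ndarray:
    """Cholesky factor of the 7-variable latent correlation:
    (u0, u3, u12, hc_w1, hc_w2, prod_w1, prod_w2)."""
    c = np.eye(7)
    ru, rc, rcu = truth.utility_time_corr, truth.cost_window_corr, truth.copula_cost_utility
    c[:3, :3] = ru
    c[3:, 3:] = rc
    c[:3, 3:] = rcu
    c[3:, :3] = rcu
    np.fill_diagonal(c, 1.0)
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "latent correlation matrix not positive definite; lower "
            "utility_time_corr / cost_window_corr / copula_cost_utility"
        ) from exc


def generate_trial(
    design: TrialDesign, truth: GeneratorTruth, seed: int, unit_costs: UnitCostTable | None = None
) -> pd.DataFrame:
    """Generate the complete (pre-missingness) participant table.

    Regeneration with the same arguments is bit-identical.  ``unit_costs``
    is needed to decompose spend targets into category counts and defaults
    to the packaged table.
    """
    if unit_costs is None:
        unit_costs = UnitCostTable.default()
    ss = np.random.SeedSequence(seed)
    rng_cov, rng_clinic, rng_latent, rng_counts = (
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4)
    )

    arm_sizes = design.arm_sizes()
    groups, arms = [], []
    for g in schema.GROUPS:
        n_i, n_c = arm_sizes.get(g, (0, 0))
        n_g = n_i + n_c
        if n_g == 0:
            continue
        # deterministic alternating interleave of the two arms
        seq = []
        i_left, c_left = n_i, n_c
        for k in range(n_g):
            if (k % 2 == 0 and i_left > 0) or c_left == 0:
                seq.append("intervention")
                i_left -= 1
            else:
                seq.append("control")
                c_left -= 1
        groups.extend([g] * n_g)
        arms.extend(seq)
    n = len(groups)
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": pd.Categorical(arms, categories=schema.ARMS),
            "group": pd.Categorical(groups, categories=schema.GROUPS),
        }
    )
    df["clinic"] = rng_clinic.integers(0, design.n_clinics, size=n)

    # baseline covariates
    df["age"] = rng_cov.integers(18, 66, size=n)
    df["gender"] = np.where(rng_cov.random(n) < 0.81, "female", "male")
    df["education"] = rng_cov.integers(1, 4, size=n)  # tertiles 1..3
    df["employment"] = rng_cov.choice(
        ["employed", "unemployed", "not_in_labour_force"], size=n, p=[0.62, 0.08, 0.30]
    )
    df["health_care_card"] = rng_cov.random(n) < 0.30
    df["long_term_illness"] = rng_cov.random(n) < 0.35
    df["lives_alone"] = rng_cov.random(n) < 0.15
    df["past_psych_visits"] = rng_cov.poisson(1.2, size=n)
    df["antidepressant_use"] = rng_cov.random(n) < 0.30
    phq_mu = df["group"].map(truth.phq9_mean).astype(float).to_numpy()
    df["phq9_baseline"] = np.clip(
        np.rint(rng_cov.normal(phq_mu, truth.phq9_sd)), 0, 27
    ).astype(int)

    # clinic effects: additive on utility location, multiplicative on cost
    clinic_u = rng_clinic.normal(0.0, truth.clinic_sd_utility, size=design.n_clinics)
    s2 = truth.clinic_sd_logcost**2
    clinic_c = np.exp(rng_clinic.normal(-s2 / 2.0, truth.clinic_sd_logcost, size=design.n_clinics))
    cu = clinic_u[df["clinic"].to_numpy()]
    cc = clinic_c[df["clinic"].to_numpy()]

    # latent Gaussian copula -> uniforms
    L = _copula_cholesky(truth)
    Z = rng_latent.standard_normal((n, 7)) @ L.T
    U = ndtr(Z)
    np.clip(U, 1e-12, 1 - 1e-12, out=U)

    # utilities: truncated normal with exact cell means, clinic shift on location
    sd = truth.utility_sd
    for t_idx, col in enumerate(schema.UTILITY_COLUMNS):
        loc = np.empty(n)
        for g in schema.GROUPS:
            for arm in schema.ARMS:
                mask = (np.asarray(groups) == g) & (np.asarray(arms) == arm)
                if mask.any():
                    loc[mask] = _solve_truncnorm_loc(truth.utility_mean(g, arm, t_idx), sd)
        loc = loc + cu
        a = (schema.UTILITY_MIN - loc) / sd
        b = (schema.UTILITY_MAX - loc) / sd
        df[col] = stats.truncnorm.ppf(U[:, t_idx], a, b, loc=loc, scale=sd)

    # health-care spend targets -> gamma draws -> Poisson category counts
    shape_map = _as_group_map(truth.cost_shape, "cost_shape")
    shares = np.array([truth.ru_value_shares[c] for c in schema.RU_CATEGORIES])
    units = np.array([unit_costs.unit_costs[c] for c in schema.RU_CATEGORIES])
    for w_idx, w in enumerate(schema.WINDOWS):
        mean = np.empty(n)
        shape = np.empty(n)
        for g in schema.GROUPS:
            for arm in schema.ARMS:
                mask = (np.asarray(groups) == g) & (np.asarray(arms) == arm)
                if mask.any():
                    mean[mask] = truth.health_cost_mean(g, arm, w)
                    shape[mask] = shape_map[g]
        spend = stats.gamma.ppf(U[:, 3 + w_idx], a=shape, scale=mean / shape) * cc
        lam = spend[:, None] * shares[None, :] / units[None, :]
        counts = rng_counts.poisson(lam)
        for j, cat in enumerate(schema.RU_CATEGORIES):
            df[schema.ru_column(cat, w)] = counts[:, j]

    # productivity spend targets -> days off paid/unpaid
    for w_idx, w in enumerate(schema.WINDOWS):
        mean = np.empty(n)
        for g in schema.GROUPS:
            for arm in schema.ARMS:
                mask = (np.asarray(groups) == g) & (np.asarray(arms) == arm)
                if mask.any():
                    mean[mask] = max(truth.prod_cost_mean(g, arm, w), 1e-9)
        spend = stats.gamma.ppf(U[:, 5 + w_idx], a=truth.prod_shape, scale=mean / truth.prod_shape) * cc
        df[f"days_off_paid_{w}"] = truth.prod_paid_share * spend / unit_costs.wage_rate_paid
        df[f"days_off_unpaid_{w}"] = (
            (1 - truth.prod_paid_share) * spend / unit_costs.wage_rate_unpaid
        )
    return df


# ---------------------------------------------------------------------------
# missingness


def _mar_linear_predictor(df: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Standardised-covariate linear predictor for the MAR mechanism."""
    design = {
        "age": df["age"].astype(float),
        "gender_female": (df["gender"] == "female").astype(float),
        "education": df["education"].astype(float),
        "past_psych_visits": df["past_psych_visits"].astype(float),
    }
    eta = np.zeros(len(df))
    for name, beta in coefficients.items():
        if name not in design:
            raise KeyError(f"unknown MAR covariate {name!r}")
        x = design[name].to_numpy()
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta = eta + beta * z
    return eta


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept such that mean(expit(alpha + eta)) = target (to 1e-6)."""
    f = lambda a: float(np.mean(expit(a + eta))) - target
    return optimize.brentq(f, -30.0, 30.0, xtol=1e-10)


def apply_missingness(
    df: pd.DataFrame, truth: GeneratorTruth, mechanism: str = "MAR", seed: int = 0
) -> pd.DataFrame:
    """Set follow-up instrument values to missing.

    RUQ missingness blanks all resource-use quantities and days off for the
    wave; AQoL missingness blanks the wave's utility weight.  Baseline
    fields are never touched.  Under MAR the probability depends on age,
    gender, education and past psychologist/counsellor visits through a
    logistic model whose intercept is solved numerically to hit the target
    rate in expectation.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for t in truth.missingness_targets:
        if not (0 <= t < 1):
            raise ValueError(f"missingness target {t} not in [0,1)")
    targets = dict(zip(MISSINGNESS_KEYS, truth.missingness_targets))
    out = df.copy()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    eta = (
        _mar_linear_predictor(df, truth.mar_coefficients)
        if mechanism == "MAR"
        else np.zeros(len(df))
    )
    rho = truth.wave_dependence
    blanks = {
        "ruq_3m": schema.ruq_columns("w1"),
        "ruq_12m": schema.ruq_columns("w2"),
        "aqol_3m": ["utility_3m"],
        "aqol_12m": ["utility_12m"],
    }
    for instrument in ("ruq", "aqol"):
        z3 = rng.standard_normal(len(df))
        z12 = rho * z3 + np.sqrt(1 - rho**2) * rng.standard_normal(len(df))
        for wave, z in (("3m", z3), ("12m", z12)):
            key = f"{instrument}_{wave}"
            target = targets[key]
            if target == 0:
                continue
            p = expit(_solve_intercept(eta, target) + eta)
            miss = ndtr(z) < p
            out.loc[miss, blanks[key]] = np.nan
    return out


# ---------------------------------------------------------------------------
# analytic expectations


def truth_summary(design: TrialDesign, truth: GeneratorTruth) -> dict:
    """Closed-form expected arm means and contrasts under the generator.

    Arm means are mixtures over strata with the arm-specific stratum weights
    implied by the allocation; the QALY difference equals the configured
    additive effect exactly because the utility shift is uniform across
    strata.
    """
    arm_sizes = {g: ab for g, ab in design.arm_sizes().items() if sum(ab) > 0}
    n_by_arm = {
        "intervention": sum(a for a, _ in arm_sizes.values()),
        "control": sum(b for _, b in arm_sizes.values()),
    }
    weights = {
        "intervention": {g: a / n_by_arm["intervention"] for g, (a, b) in arm_sizes.items()},
        "control": {g: b / n_by_arm["control"] for g, (a, b) in arm_sizes.items()},
    }

    def hs_total(g, arm, horizon):
        iv = truth.intervention_component[g] if arm == "intervention" else 0.0
        total = iv + truth.health_cost_mean(g, arm, "w1")
        if horizon == "12m":
            total += truth.health_cost_mean(g, arm, "w2")
        return total

    def prod_total(g, arm, horizon):
        total = truth.prod_cost_mean(g, arm, "w1")
        if horizon == "12m":
            total += truth.prod_cost_mean(g, arm, "w2")
        return total

    out = {"arm_means": {}, "delta_cost": {}, "delta_qaly": {}}
    for perspective in ("health_sector", "societal"):
        out["delta_cost"][perspective] = {}
        for horizon in schema.HORIZONS:
            means = {}
            for arm in schema.ARMS:
                m = sum(
                    weights[arm][g]
                    * (
                        hs_total(g, arm, horizon)
                        + (prod_total(g, arm, horizon) if perspective == "societal" else 0.0)
                    )
                    for g in arm_sizes
                )
                means[arm] = m
            out["arm_means"][f"{perspective}_{horizon}"] = means
            out["delta_cost"][perspective][horizon] = (
                means["intervention"] - means["control"]
            )
    out["delta_qaly"]["3m"] = truth.true_qaly_diff_3m
    out["delta_qaly"]["12m"] = truth.true_qaly_diff
    return out


# ---------------------------------------------------------------------------
# serialization


def save_dataset(
    df: pd.DataFrame, design: TrialDesign, truth: GeneratorTruth, seed: int, outdir
) -> None:
    """Write the canonical CSV (missing values as empty fields) plus a JSON
    sidecar recording design, truth and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "trial_data.csv", index=False)
    sidecar = {
        "design": dataclasses.asdict(design),
        "truth": dataclasses.asdict(truth),
        "seed": int(seed),
    }
    (outdir / "trial_data.json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
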