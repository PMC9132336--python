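"""Decision-analytic layer: bootstrap ICERs, dominance, CEACs.

Uncertainty is propagated by *single imputation nested in bootstrapping*:
each bootstrap resample (stratified by trial arm) receives one chained-
equation imputation, the cost and QALY GLMs are refitted, and the pair
(delta-cost, delta-QALY) of adjusted-mean contrasts is recorded.  The
point ICER is classified by quadrant (dominant / dominated / a ratio in
A$ per QALY); 95% confidence bounds come from the bootstrap percentile
method applied to the draws ordered by angle on the cost-effectiveness
plane, which stays meaningful when draws straddle delta-QALY = 0.  The
CEAC reports, for each willingness-to-pay threshold, the fraction of
draws with positive net monetary benefit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .costing import InterventionCostSchedule
from .dataset import derive_outcomes
from .estimation import GlmSpec, fit_glm
from .imputation import ImputationSpec, single_impute

DOMINANT = "Dominant"
DOMINATED = "Dominated"
DEFAULT_WTP = 50_000.0
DEFAULT_LAMBDA_GRID = np.arange(0.0, 150_001.0, 1_000.0)


# ---------------------------------------------------------------------------
# ICER arithmetic


def icer(delta_cost: float, delta_qaly: float):
    """Point ICER or dominance label.

    Cheaper and more effective -> ``Dominant``; costlier and less effective
    -> ``Dominated``; otherwise the ratio in A$/QALY (signed infinity when
    delta_qaly is exactly zero).
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("ICER inputs must be finite")
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    if delta_qaly == 0:
        if delta_cost == 0:
            return 0.0
        return np.inf if delta_cost > 0 else -np.inf
    return float(delta_cost / delta_qaly)


def quadrant_counts(delta_cost: np.ndarray, delta_qaly: np.ndarray) -> dict[str, int]:
    """Draws per cost-effectiveness-plane quadrant (boundaries go east)."""
    dc, de = np.asarray(delta_cost), np.asarray(delta_qaly)
    ne = (de > 0) & (dc >= 0)
    se = (de > 0) & (dc < 0)
    nw = (de <= 0) & (dc >= 0)
    sw = (de <= 0) & (dc < 0)
    return {"NE": int(ne.sum()), "SE": int(se.sum()), "NW": int(nw.sum()), "SW": int(sw.sum())}


def _angles(delta_cost: np.ndarray, delta_qaly: np.ndarray) -> np.ndarray:
    """Angle on the CE plane, counter-clockwise from the ray pointing into
    pure cost saving (delta_qaly = 0, delta_cost < 0).

    Sweeping order: dominant (SE) -> NE with ICER rising from 0 to +inf ->
    dominated (NW) -> SW — i.e., from most to least favourable.
    """
    theta = np.arctan2(delta_cost, delta_qaly)
    return np.mod(theta + np.pi / 2.0, 2.0 * np.pi)


def icer_percentile_ci(
    delta_cost: np.ndarray, delta_qaly: np.ndarray, level: float = 0.95, mode: str = "angular"
):
    """Bootstrap percentile CI for the ICER as (low, high) values-or-labels.

    ``angular`` (default) orders draws by CE-plane angle and maps the 2.5th
    and 97.5th angular order statistics back to ICER values or dominance
    labels; ``raw`` takes plain quantiles of the numeric ICER draws (only
    meaningful when no draw crosses delta_qaly = 0).
    """
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_qaly, dtype=float)
    B = len(dc)
    if B < 40:
        raise ValueError("at least 40 bootstrap draws required for a 95% CI")
    alpha = (1.0 - level) / 2.0
    if mode == "raw":
        vals = dc / np.where(de == 0, np.nan, de)
        return (
            float(np.nanquantile(vals, alpha)),
            float(np.nanquantile(vals, 1 - alpha)),
        )
    if mode != "angular":
        raise ValueError(f"unknown CI mode {mode!r}")
    order = np.argsort(_angles(dc, de), kind="stable")
    lo_ix = order[int(np.floor(alpha * (B - 1)))]
    hi_ix = order[int(np.ceil((1 - alpha) * (B - 1)))]
    return icer(dc[lo_ix], de[lo_ix]), icer(dc[hi_ix], de[hi_ix])


def ceac(
    delta_cost: np.ndarray, delta_qaly: np.ndarray, lambda_grid=DEFAULT_LAMBDA_GRID
) -> pd.DataFrame:
    """Acceptability curve: P(lambda * dE - dC > 0) per threshold.

    Ties at zero net monetary benefit count as not cost-effective.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any(lam < 0) or np.any(np.diff(lam) < 0):
        raise ValueError("lambda grid must be nonnegative and sorted")
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_qaly, dtype=float)
    nmb = lam[:, None] * de[None, :] - dc[None, :]
    return pd.DataFrame({"lambda": lam, "probability": (nmb > 0).mean(axis=1)})


# ---------------------------------------------------------------------------
# bootstrap with nested single imputation


@dataclass
class BootstrapDraws:
    """B (delta-cost, delta-QALY) pairs per perspective x horizon."""

    draws: pd.DataFrame  # replicate, perspective, horizon, subgroup, delta_cost, delta_qaly
    B: int
    seed: int
    n_redraws: int
    stratify: str

    def cell(self, perspective: str, horizon: str, subgroup: str = "all"):
        d = self.draws
        d = d[
            (d["perspective"] == perspective)
            & (d["horizon"] == horizon)
            & (d["subgroup"] == subgroup)
        ]
        return d["delta_cost"].to_numpy(), d["delta_qaly"].to_numpy()


def _resample_indices(df: pd.DataFrame, stratify: str, rng: np.random.Generator) -> np.ndarray:
    if stratify == "none":
        return rng.integers(0, len(df), size=len(df))
    if stratify == "arm":
        keys = df["arm"].astype(str)
    elif stratify == "arm_x_group":
        keys = df["arm"].astype(str) + "|" + df["group"].astype(str)
    else:
        raise ValueError(f"unknown stratification {stratify!r}")
    parts = []
    for _, idx in df.groupby(keys.to_numpy(), sort=True).indices.items():
        parts.append(rng.choice(idx, size=len(idx), replace=True))
    return np.concatenate(parts)


def bootstrap_cea(
    analysis: pd.DataFrame,
    imputation_spec: ImputationSpec,
    schedule: InterventionCostSchedule,
    B: int = 1000,
    seed: int = 0,
    covariates: str = "protocol",
    perspectives=("health_sector", "societal"),
    horizons=schema.HORIZONS,
    subgroups=("all",),
    stratify: str = "arm",
    resample: bool = True,
) -> BootstrapDraws:
    """Resample -> single-impute -> refit, B times; deterministic given seed.

    A replicate whose fit fails (e.g. a resample losing a covariate level)
    is redrawn from a fresh substream; more than 5% redraws aborts.
    ``resample=False`` is a diagnostic mode that analyses the original
    sample in every replicate (so B=1 on complete data reproduces the
    m=1 point estimates).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    master = np.random.SeedSequence(seed)
    outcome_map = {"health_sector": "health_sector_cost", "societal": "societal_cost"}
    rows = []
    n_redraws = 0
    max_redraws = max(5, int(0.05 * B))
    stream = iter(master.spawn(B + max_redraws))
    b = 0
    while b < B:
        child = next(stream)
        sub = child.spawn(2)
        rng_resample = np.random.Generator(np.random.PCG64(sub[0]))
        ss_impute = sub[1]
        try:
            if resample:
                idx = _resample_indices(analysis, stratify, rng_resample)
                boot = analysis.iloc[idx].reset_index(drop=True)
                boot["id"] = np.arange(1, len(boot) + 1)
            else:
                boot = analysis
            completed = single_impute(boot, imputation_spec, ss_impute)
            derived = derive_outcomes(completed, schedule)
            for subgroup in subgroups:
                for horizon in horizons:
                    qfit = fit_glm(
                        derived,
                        GlmSpec(
                            outcome="qaly",
                            horizon=horizon,
                            covariates=covariates,
                            subgroup=subgroup,
                        ),
                    )
                    de = qfit.adj_mean_intervention - qfit.adj_mean_control
                    for perspective in perspectives:
                        cfit = fit_glm(
                            derived,
                            GlmSpec(
                                outcome=outcome_map[perspective],
                                horizon=horizon,
                                covariates=covariates,
                                subgroup=subgroup,
                            ),
                        )
                        rows.append(
                            {
                                "replicate": b,
                                "perspective": perspective,
                                "horizon": horizon,
                                "subgroup": subgroup,
                                "delta_cost": cfit.adj_mean_intervention
                                - cfit.adj_mean_control,
                                "delta_qaly": de,
                            }
                        )
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} bootstrap replicates failed; aborting"
                )
            continue
        b += 1
    return BootstrapDraws(
        draws=pd.DataFrame(rows), B=B, seed=seed, n_redraws=n_redraws, stratify=stratify
    )


# ---------------------------------------------------------------------------
# summary and export


@dataclass
class CeaResult:
    icer_point: float | str
    delta_cost_point: float
    delta_qaly_point: float
    quadrant_counts: dict[str, int]
    ci_95: tuple
    ceac: pd.DataFrame
    p_ce_at_threshold: float
    wtp: float
    B: int


def summarize_cell(
    delta_cost_point: float,
    delta_qaly_point: float,
    draws_dc: np.ndarray,
    draws_de: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    wtp: float = DEFAULT_WTP,
    ci_mode: str = "angular",
) -> CeaResult:
    curve = ceac(draws_dc, draws_de, lambda_grid)
    at = float(
        np.mean(wtp * np.asarray(draws_de) - np.asarray(draws_dc) > 0)
    )
    return CeaResult(
        icer_point=icer(delta_cost_point, delta_qaly_point),
        delta_cost_point=float(delta_cost_point),
        delta_qaly_point=float(delta_qaly_point),
        quadrant_counts=quadrant_counts(draws_dc, draws_de),
        ci_95=icer_percentile_ci(draws_dc, draws_de, mode=ci_mode),
        ceac=curve,
        p_ce_at_threshold=at,
        wtp=wtp,
        B=len(np.asarray(draws_dc)),
    )


def _fmt_bound(b) -> str:
    return b if isinstance(b, str) else f"{b:,.0f}"


def export_decision_outputs(
    result: CeaResult, draws_dc: np.ndarray, draws_de: np.ndarray, outdir, prefix: str = "cea"
) -> dict[str, Path]:
    """Write draws/CEAC CSVs, a summary JSON and CE-plane + CEAC figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    plane = pd.DataFrame({"delta_qaly": draws_de, "delta_cost": draws_dc})
    paths["plane_csv"] = outdir / f"{prefix}_plane.csv"
    plane.to_csv(paths["plane_csv"], index=False)
    paths["ceac_csv"] = outdir / f"{prefix}_ceac.csv"
    result.ceac.to_csv(paths["ceac_csv"], index=False)
    summary = {
        "icer_point": result.icer_point
        if isinstance(result.icer_point, str)
        else float(result.icer_point),
        "delta_cost_point": result.delta_cost_point,
        "delta_qaly_point": result.delta_qaly_point,
        "ci_95": [
            b if isinstance(b, str) else float(b) for b in result.ci_95
        ],
        "quadrant_counts": result.quadrant_counts,
        "p_ce_at_threshold": result.p_ce_at_threshold,
        "wtp": result.wtp,
        "B": result.B,
    }
    paths["summary_json"] = outdir / f"{prefix}_summary.json"
    paths["summary_json"].write_text(json.dumps(summary, indent=2))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(draws_de, draws_dc, s=6, alpha=0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    lim = max(1e-9, np.abs(draws_de).max())
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, result.wtp * xs, "r--", lw=1, label=f"WTP A${result.wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (A$)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    paths["plane_png"] = outdir / f"{prefix}_plane.png"
    fig.savefig(paths["plane_png"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.ceac["lambda"], result.ceac["probability"])
    ax.axvline(result.wtp, color="r", ls="--", lw=1, label=f"WTP A${result.wtp:,.0f}")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (A$/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    paths["ceac_png"] = outdir / f"{prefix}_ceac.png"
    fig.savefig(paths["ceac_png"], dpi=120)
    plt.close(fig)
    return paths
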