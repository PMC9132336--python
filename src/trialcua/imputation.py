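"""Multiple imputation by chained equations with predictive mean matching.

Two modes serve two estimators: :func:`mice_pmm` produces the m completed
datasets over which Rubin's rules pool point estimates, and
:func:`single_impute` produces one completed dataset per bootstrap
resample (single imputation nested in bootstrapping).

Each incomplete variable is visited in order of increasing missingness.
Per visit a linear model is fitted to the currently-complete data, the
coefficients are perturbed by a draw from their approximate posterior
(normal around the fit, residual variance from a scaled chi-square draw),
and each missing row is matched to the ``k_donors`` observed rows with the
nearest predicted values; one donor is copied uniformly at random
(type-1 PMM).  Imputed values are therefore always observed donor values,
which preserves the support of skewed cost variables.

A master seed spawns independent substreams per imputation, so changing m
never correlates draws between imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from ._design import encode_columns
from .dataset import IMPUTABLE_COLUMNS, INSTRUMENT_COLUMNS

DEFAULT_PREDICTORS = ("arm", "clinic", "age", "gender", "education", "past_psych_visits")

#: named predictor sets; the extended set mirrors the covariates associated
#: with non-response to the trial's primary outcome
PREDICTOR_PRESETS = {
    "default": DEFAULT_PREDICTORS,
    "nonresponse_extended": (
        "arm",
        "clinic",
        "age",
        "gender",
        "education",
        "employment",
        "health_care_card",
        "long_term_illness",
        "lives_alone",
        "past_psych_visits",
        "antidepressant_use",
    ),
}

_POST_BASELINE = set(IMPUTABLE_COLUMNS) | {
    "qaly_3m",
    "qaly_12m",
    "hs_cost_3m",
    "hs_cost_12m",
    "soc_cost_3m",
    "soc_cost_12m",
}


@dataclass(frozen=True)
class ImputationSpec:
    variables_to_impute: tuple[str, ...] = IMPUTABLE_COLUMNS
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    m: int = 100
    k_donors: int = 5
    n_iterations: int = 10
    seed: int = 0
    #: post-baseline columns explicitly allowed as predictors
    allow_post_baseline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.m < 1 or self.k_donors < 1 or self.n_iterations < 1:
            raise ValueError("m, k_donors and n_iterations must all be >= 1")
        bad = (set(self.predictors) & _POST_BASELINE) - set(self.allow_post_baseline)
        if bad:
            raise ValueError(
                f"post-baseline predictors {sorted(bad)} not whitelisted "
                "(set allow_post_baseline)"
            )


@dataclass
class ImputedStack:
    """m completed copies of the analysis dataset plus provenance."""

    datasets: list[pd.DataFrame]
    traces: pd.DataFrame  # columns: variable, imputation, sweep, mean_imputed
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.datasets)


def _collinear_names(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in piv[d < tol]]


def _pmm_draw(
    y: np.ndarray,
    obs: np.ndarray,
    X: np.ndarray,
    names: list[str],
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Imputed values for the missing entries of y (observed donors only)."""
    Xo, yo, Xm = X[obs], y[obs], X[~obs]
    n_obs, p = Xo.shape
    beta, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    if rank < p:
        raise ValueError(
            f"perfect collinearity among imputation predictors: "
            f"{_collinear_names(Xo, names)}"
        )
    dof = n_obs - rank
    if dof <= 0:
        raise ValueError("too few observed rows to fit the imputation model")
    resid = yo - Xo @ beta
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    XtX = Xo.T @ Xo
    L = np.linalg.cholesky(XtX)
    w = linalg.solve_triangular(L, rng.standard_normal(p), trans="T", lower=True)
    beta_draw = beta + np.sqrt(sigma2) * w

    pred_obs = Xo @ beta  # type-1 PMM: donors ranked under the ML fit
    pred_mis = Xm @ beta_draw
    k_eff = min(k, n_obs)
    order = np.argsort(pred_obs, kind="stable")
    sp = pred_obs[order]
    pos = np.searchsorted(sp, pred_mis)
    offsets = np.arange(-k_eff, k_eff)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n_obs - 1)
    dist = np.abs(sp[cand] - pred_mis[:, None])
    top = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    rows = np.arange(len(pred_mis))
    pick = top[rows, rng.integers(0, k_eff, size=len(pred_mis))]
    donors = order[cand[rows, pick]]
    return yo[donors]


def _validate(dataset: pd.DataFrame, spec: ImputationSpec) -> None:
    missing_preds = [c for c in spec.predictors if dataset[c].isna().any()]
    if len(missing_preds) == len(spec.predictors):
        raise ValueError("no fully observed predictor available")
    if missing_preds:
        raise ValueError(f"predictors with missing values: {missing_preds}")
    extra = [
        c
        for c in dataset.columns
        if dataset[c].isna().any() and c not in spec.variables_to_impute
    ]
    if extra:
        raise ValueError(
            f"missingness outside variables_to_impute: {extra}"
        )
    for v in spec.variables_to_impute:
        if dataset[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values (no donors)")


def _one_imputation(
    dataset: pd.DataFrame, spec: ImputationSpec, ss: np.random.SeedSequence
):
    rng = np.random.Generator(np.random.PCG64(ss))
    work = dataset.copy()
    fractions = {v: work[v].isna().mean() for v in spec.variables_to_impute}
    visit = sorted((v for v in fractions if fractions[v] > 0), key=lambda v: fractions[v])
    obs_masks = {v: work[v].notna().to_numpy() for v in visit}
    # working numeric copies; the predictor block is constant across sweeps
    pred_block, pred_names = encode_columns(work, list(spec.predictors))
    values = {v: work[v].to_numpy(dtype=float).copy() for v in spec.variables_to_impute}
    # initial fill: random draws from the observed values
    for v in visit:
        obs_vals = values[v][obs_masks[v]]
        values[v][~obs_masks[v]] = rng.choice(obs_vals, size=int((~obs_masks[v]).sum()))
    trace_rows = []
    for sweep in range(spec.n_iterations):
        for v in visit:
            other = [u for u in spec.variables_to_impute if u != v]
            X = np.column_stack([pred_block] + [values[u] for u in other])
            names = pred_names + other
            imputed = _pmm_draw(values[v], obs_masks[v], X, names, spec.k_donors, rng)
            values[v][~obs_masks[v]] = imputed
            trace_rows.append(
                {"variable": v, "sweep": sweep, "mean_imputed": float(np.mean(imputed))}
            )
    for v in visit:
        work[v] = values[v]
    return work, pd.DataFrame(trace_rows)


def mice_pmm(dataset: pd.DataFrame, spec: ImputationSpec) -> ImputedStack:
    """m-fold chained-equation imputation; observed entries are never altered."""
    _validate(dataset, spec)
    children = np.random.SeedSequence(spec.seed).spawn(spec.m)
    datasets, traces = [], []
    for j, child in enumerate(children):
        completed, trace = _one_imputation(dataset, spec, child)
        trace["imputation"] = j
        datasets.append(completed)
        traces.append(trace)
    trace_df = (
        pd.concat(traces, ignore_index=True)
        if traces and len(traces[0])
        else pd.DataFrame(columns=["variable", "sweep", "mean_imputed", "imputation"])
    )
    return ImputedStack(datasets=datasets, traces=trace_df, spec=spec)


def single_impute(
    dataset: pd.DataFrame, spec: ImputationSpec, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """One completed dataset (the bootstrap-nested mode); deterministic given seed."""
    _validate(dataset, spec)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    completed, _ = _one_imputation(dataset, replace(spec, m=1), ss)
    return completed


def missingness_report(
    dataset: pd.DataFrame, instruments: dict | None = None
) -> pd.DataFrame:
    """Missing counts/fractions per variable, plus instrument-level rows.

    ``instruments`` maps instrument name -> wave -> column list; a wave is
    missing when any of its columns is missing, and a ``union`` row counts
    participants missing the instrument at either wave.  Defaults to the
    analysis-dataset layout (RUQ cost components, AQoL utilities).
    """
    if instruments is None:
        instruments = {
            k: {w: [c for c in cols if c in dataset.columns] for w, cols in waves.items()}
            for k, waves in INSTRUMENT_COLUMNS.items()
        }
    rows = []
    n = len(dataset)
    for col in dataset.columns:
        miss = int(dataset[col].isna().sum())
        rows.append(
            {"variable": col, "horizon": "", "n_missing": miss, "fraction": miss / n}
        )
    for name, waves in instruments.items():
        union = np.zeros(n, dtype=bool)
        for wave, cols in waves.items():
            if not cols:
                continue
            miss = dataset[cols].isna().any(axis=1).to_numpy()
            union |= miss
            rows.append(
                {
                    "variable": name,
                    "horizon": wave,
                    "n_missing": int(miss.sum()),
                    "fraction": miss.mean(),
                }
            )
        rows.append(
            {
                "variable": name,
                "horizon": "union",
                "n_missing": int(union.sum()),
                "fraction": union.mean(),
            }
        )
    return pd.DataFrame(rows)
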