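"""QALYs from utility weights by the area-under-the-curve method.

Utility weights at 0, 3 and 12 months are joined by straight lines and the
area under the utility-time curve gives QALYs (trapezoidal rule):

    qaly_3m  = 0.25 * (u0 + u3) / 2
    qaly_12m = qaly_3m + 0.75 * (u3 + u12) / 2

Any required utility missing makes that horizon's QALY missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema


def _check_range(u: pd.Series, name: str) -> None:
    bad = u.dropna()
    bad = bad[(bad < schema.UTILITY_MIN - 1e-12) | (bad > schema.UTILITY_MAX + 1e-12)]
    if len(bad):
        raise ValueError(
            f"{name} outside instrument range [{schema.UTILITY_MIN}, "
            f"{schema.UTILITY_MAX}]: e.g. {bad.iloc[0]!r}"
        )


def qaly_auc(df: pd.DataFrame) -> pd.DataFrame:
    """Trapezoidal QALYs per participant.

    Expects columns ``utility_0m``, ``utility_3m``, ``utility_12m`` (baseline
    must be fully observed) and ``id``; returns ``id``, ``qaly_3m``,
    ``qaly_12m``.
    """
    for col in schema.UTILITY_COLUMNS:
        _check_range(df[col], col)
    if df["utility_0m"].isna().any():
        raise ValueError("baseline utility must be present for every participant")
    u0 = df["utility_0m"].astype(float)
    u3 = df["utility_3m"].astype(float)
    u12 = df["utility_12m"].astype(float)
    q3 = 0.25 * (u0 + u3) / 2.0
    q12 = q3 + 0.75 * (u3 + u12) / 2.0
    return pd.DataFrame({"id": df["id"].to_numpy(), "qaly_3m": q3, "qaly_12m": q12})


def mean_qalys_by_cell(qalys: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Mean QALYs (SE) by arm x prognostic group x horizon, plus an
    all-participants row per arm.  Empty cells are flagged, not dropped."""
    merged = qalys.merge(records[["id", "arm", "group"]], on="id", validate="1:1")
    rows = []
    cells = [("all", merged)] + [
        (g, merged[merged["group"] == g]) for g in schema.GROUPS
    ]
    for group_label, cell in cells:
        for arm in schema.ARMS:
            sub = cell[cell["arm"] == arm]
            for horizon, col in (("3m", "qaly_3m"), ("12m", "qaly_12m")):
                vals = sub[col].dropna()
                n = len(vals)
                rows.append(
                    {
                        "group": group_label,
                        "arm": arm,
                        "horizon": horizon,
                        "n": n,
                        "mean": vals.mean() if n else np.nan,
                        "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                        "empty": n == 0,
                    }
                )
    return pd.DataFrame(rows)
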