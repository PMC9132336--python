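"""Design-matrix encoding shared by the imputation and estimation modules.

Categorical and boolean columns become drop-first indicator columns;
numeric columns enter as-is.  Column naming is stable so coefficients can
be addressed by name.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_CATEGORICAL = ("arm", "group", "gender", "employment", "clinic")


def encode_columns(df: pd.DataFrame, columns, intercept: bool = True):
    """Return (matrix, names) for the requested columns.

    ``clinic`` is always treated as categorical (fixed indicators) even
    though it is stored as an integer code.
    """
    parts: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        parts.append(np.ones(len(df)))
        names.append("intercept")
    for col in columns:
        s = df[col]
        if col in _CATEGORICAL or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            levels = sorted(pd.unique(s.dropna()), key=str)
            for lev in levels[1:]:  # drop first level as reference
                parts.append((s == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
        elif s.dtype == bool:
            parts.append(s.to_numpy(dtype=float))
            names.append(col)
        else:
            parts.append(s.to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(parts), names


def arm_indicator(df: pd.DataFrame) -> np.ndarray:
    return (df["arm"] == "intervention").to_numpy(dtype=float)
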