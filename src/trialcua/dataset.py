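"""Analysis-dataset assembly shared by estimation and the decision layer.

The analysis dataset is the imputation substrate: baselines plus the
missable follow-up components (utility weights at 3/12 months, valued
health-care use and productivity cost per recall window).  Cost totals and
QALYs are *derived* from completed components, so imputation happens on the
measured quantities and transformation afterwards.
"""

from __future__ import annotations

import pandas as pd

from . import costing, outcomes, schema

#: follow-up components carrying missingness, in default imputation order
IMPUTABLE_COLUMNS = (
    "utility_3m",
    "utility_12m",
    "hs_util_w1",
    "hs_util_w2",
    "prod_w1",
    "prod_w2",
)

#: instrument -> wave -> analysis columns, for missingness reporting
INSTRUMENT_COLUMNS = {
    "ruq": {"3m": ["hs_util_w1", "prod_w1"], "12m": ["hs_util_w2", "prod_w2"]},
    "aqol": {"3m": ["utility_3m"], "12m": ["utility_12m"]},
}


def build_analysis_dataset(
    records: pd.DataFrame, unit_costs: costing.UnitCostTable
) -> pd.DataFrame:
    """Baselines plus valued per-window components, one row per participant.

    RUQ missingness propagates into missing valued components; nothing is
    imputed here.
    """
    comp = costing.window_components(records, unit_costs)
    keep = ["id", *schema.BASELINE_COLUMNS, "utility_3m", "utility_12m"]
    out = records[keep].merge(comp, on="id", validate="1:1")
    return out


def derive_outcomes(
    analysis: pd.DataFrame, schedule: costing.InterventionCostSchedule
) -> pd.DataFrame:
    """Attach cost totals per perspective/horizon and AUC QALYs.

    Applied per completed dataset; the intervention component is recomputed
    from the schedule in force so costing sensitivity variants propagate.
    """
    out = analysis.copy()
    iv = costing.intervention_cost_vector(out, schedule)
    out["hs_cost_3m"] = iv + out["hs_util_w1"]
    out["hs_cost_12m"] = iv + out["hs_util_w1"] + out["hs_util_w2"]
    out["soc_cost_3m"] = out["hs_cost_3m"] + out["prod_w1"]
    out["soc_cost_12m"] = out["hs_cost_12m"] + out["prod_w1"] + out["prod_w2"]
    if "qaly_3m" not in out.columns:
        # impute-then-transform default; when QALYs were imputed directly
        # the columns are already present and are left untouched
        q = outcomes.qaly_auc(out)
        out["qaly_3m"] = q["qaly_3m"].to_numpy()
        out["qaly_12m"] = q["qaly_12m"].to_numpy()
    return out


#: estimation outcome name -> analysis column per horizon
OUTCOME_COLUMNS = {
    ("health_sector_cost", "3m"): "hs_cost_3m",
    ("health_sector_cost", "12m"): "hs_cost_12m",
    ("societal_cost", "3m"): "soc_cost_3m",
    ("societal_cost", "12m"): "soc_cost_12m",
    ("qaly", "3m"): "qaly_3m",
    ("qaly", "12m"): "qaly_12m",
}
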