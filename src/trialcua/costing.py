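"""Micro-costing: value intervention delivery and self-reported resource use.

Two perspectives are supported.  The *health sector* perspective covers the
per-person intervention cost (screening plus prognosis-matched treatment)
and valued health-care use from the resource-use questionnaire.  The
*societal* perspective adds productivity losses from days off paid and
unpaid work, valued by the human-capital approach.

Costs are cumulative: the 12-month total is the 0-3 month window plus the
3-12 month window.  Missing quantities propagate as missing components —
valuation never invents zeros.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import schema


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs in A$ for a single currency year.

    The currency year is metadata and immutable within a run; combining
    tables from different currency years is an error (see
    :func:`ensure_same_currency_year`).
    """

    unit_costs: dict[str, float]
    wage_rate_paid: float
    wage_rate_unpaid: float
    currency_year: str = "2018-19"

    def __post_init__(self) -> None:
        for cat, cost in self.unit_costs.items():
            if cost < 0:
                raise ValueError(f"unit cost for {cat!r} is negative: {cost}")
        if self.wage_rate_paid < 0 or self.wage_rate_unpaid < 0:
            raise ValueError("wage rates must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            unit_costs={k: float(v) for k, v in raw["unit_costs"].items()},
            wage_rate_paid=float(raw["wage_rate_paid"]),
            wage_rate_unpaid=float(raw["wage_rate_unpaid"]),
            currency_year=str(raw["currency_year"]),
        )

    @classmethod
    def default(cls) -> "UnitCostTable":
        ref = importlib.resources.files("trialcua.data") / "unit_costs.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


def ensure_same_currency_year(*tables: UnitCostTable) -> None:
    years = {t.currency_year for t in tables}
    if len(years) > 1:
        raise ValueError(
            f"unit-cost tables mix currency years {sorted(years)}; "
            "a run must use a single currency year"
        )


#: named intervention-cost variants; mutually exclusive per run
SCHEDULE_VARIANTS = ("base", "icbt_high", "sunk_cost")


@dataclass(frozen=True)
class InterventionCostSchedule:
    """Per-person intervention cost components (A$).

    Screening is applied to everyone in the intervention arm; the treatment
    component depends on the prognostic group.  The attention-control phone
    call in the control arm defaults to zero cost.
    """

    screening_per_person: float = 0.96
    treatment_per_person: dict[str, float] = field(
        default_factory=lambda: {"minimal_mild": 14.0, "moderate": 132.0, "severe": 676.0}
    )
    control_contact_cost: float = 0.0
    variant: str = "base"

    def __post_init__(self) -> None:
        if self.screening_per_person < 0 or self.control_contact_cost < 0:
            raise ValueError("intervention cost components must be nonnegative")
        for g, c in self.treatment_per_person.items():
            if c < 0:
                raise ValueError(f"treatment cost for {g!r} is negative: {c}")
        if self.variant not in SCHEDULE_VARIANTS:
            raise ValueError(f"unknown schedule variant {self.variant!r}")

    @classmethod
    def for_variant(cls, variant: str = "base") -> "InterventionCostSchedule":
        """Base schedule or one of the costing sensitivity variants.

        ``icbt_high`` raises the moderate-group treatment cost from $132 to
        $222 (highest of the two clinician-guided iCBT programs);
        ``sunk_cost`` raises screening from $0.96 to $2.30 (includes
        screening-tool research and development).
        """
        base = cls()
        if variant == "base":
            return base
        if variant == "icbt_high":
            treat = dict(base.treatment_per_person, moderate=222.0)
            return replace(base, treatment_per_person=treat, variant=variant)
        if variant == "sunk_cost":
            return replace(base, screening_per_person=2.30, variant=variant)
        raise ValueError(f"unknown schedule variant {variant!r}")

    def per_person(self, arm: str, group: str) -> float:
        if arm == "intervention":
            if group not in self.treatment_per_person:
                raise ValueError(f"unknown prognostic group {group!r}")
            return self.screening_per_person + self.treatment_per_person[group]
        if arm == "control":
            return self.control_contact_cost
        raise ValueError(f"unknown arm {arm!r}")


def intervention_cost(record, schedule: InterventionCostSchedule) -> float:
    """Intervention delivery cost for one participant (mapping with arm/group)."""
    return schedule.per_person(record["arm"], record["group"])


def intervention_cost_vector(df: pd.DataFrame, schedule: InterventionCostSchedule) -> pd.Series:
    unknown = set(df["group"].unique()) - set(schedule.treatment_per_person)
    if unknown:
        raise ValueError(f"unknown prognostic group(s) {sorted(unknown)}")
    treat = df["group"].astype(str).map(schedule.treatment_per_person).astype(float)
    iv = schedule.screening_per_person + treat
    out = np.where(df["arm"] == "intervention", iv, schedule.control_contact_cost)
    return pd.Series(out, index=df.index, name="intervention_component")


def value_resource_use(
    df: pd.DataFrame, unit_costs: UnitCostTable, window: str
) -> pd.DataFrame:
    """Value RUQ quantities for one recall window.

    Returns a frame with one valued column per category plus the summed
    health-care component ``hc_component``; a missing quantity makes the
    participant's component missing for that window.
    """
    cols = [c for c in df.columns if c.startswith("ru_") and c.endswith(f"_{window}")]
    out = pd.DataFrame(index=df.index)
    total = pd.Series(0.0, index=df.index)
    for col in cols:
        cat = col[len("ru_") : -len(f"_{window}")]
        if cat not in unit_costs.unit_costs:
            raise KeyError(f"resource category {cat!r} has no unit cost in the table")
        q = df[col].astype(float)
        if (q.dropna() < 0).any():
            raise ValueError(f"negative quantity in {col}")
        valued = q * unit_costs.unit_costs[cat]
        out[f"cost_{cat}_{window}"] = valued
        total = total + valued  # NaN propagates
    out[f"hc_component_{window}"] = total
    return out


def productivity_cost(df: pd.DataFrame, unit_costs: UnitCostTable, window: str) -> pd.Series:
    """Human-capital valuation of days off paid/unpaid work for a window."""
    paid = df[f"days_off_paid_{window}"].astype(float)
    unpaid = df[f"days_off_unpaid_{window}"].astype(float)
    for name, s in (("paid", paid), ("unpaid", unpaid)):
        if (s.dropna() < 0).any():
            raise ValueError(f"negative days off ({name}) in window {window}")
    out = paid * unit_costs.wage_rate_paid + unpaid * unit_costs.wage_rate_unpaid
    out.name = f"prod_{window}"
    return out


def window_components(df: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Per-window valued components keyed by participant id.

    Columns: ``hs_util_w1/w2`` (health-care use, excluding the intervention
    component) and ``prod_w1/w2`` (productivity losses).
    """
    out = pd.DataFrame({"id": df["id"].to_numpy()}, index=df.index)
    for w in schema.WINDOWS:
        out[f"hs_util_{w}"] = value_resource_use(df, unit_costs, w)[f"hc_component_{w}"]
        out[f"prod_{w}"] = productivity_cost(df, unit_costs, w)
    return out


def assemble_costs(
    df: pd.DataFrame,
    unit_costs: UnitCostTable,
    schedule: InterventionCostSchedule,
) -> pd.DataFrame:
    """One cost summary per participant x horizon.

    The 12-month totals are cumulative (w1 + w2); the intervention component
    is incurred in the first window and therefore appears at both horizons.
    ``societal_cost = health_sector_cost + productivity_cost`` exactly.
    """
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        raise ValueError(f"duplicate participant ids: {list(dups)}")
    iv = intervention_cost_vector(df, schedule)
    rows = []
    valued = {w: value_resource_use(df, unit_costs, w) for w in schema.WINDOWS}
    prod = {w: productivity_cost(df, unit_costs, w) for w in schema.WINDOWS}
    for horizon, windows in (("3m", ("w1",)), ("12m", ("w1", "w2"))):
        hc = sum(valued[w][f"hc_component_{w}"] for w in windows)
        pc = sum(prod[w] for w in windows)
        block = pd.DataFrame(
            {
                "id": df["id"].to_numpy(),
                "horizon": horizon,
                "intervention_component": iv.to_numpy(),
                "health_care_component": np.asarray(hc, dtype=float),
                "productivity_cost": np.asarray(pc, dtype=float),
            }
        )
        for cat in schema.RU_CATEGORIES:
            block[f"cost_{cat}"] = sum(
                valued[w][f"cost_{cat}_{w}"].to_numpy() for w in windows
            )
        block["health_sector_cost"] = (
            block["intervention_component"] + block["health_care_component"]
        )
        block["societal_cost"] = block["health_sector_cost"] + block["productivity_cost"]
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
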