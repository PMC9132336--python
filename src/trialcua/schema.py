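"""Column conventions shared across the pipeline.

One row per participant. Follow-up is split into two recall windows:
``w1`` covers 0-3 months, ``w2`` covers 3-12 months; reported horizons
(3 m, 12 m) are cumulative over windows.
"""

from __future__ import annotations

ARMS = ("intervention", "control")
GROUPS = ("minimal_mild", "moderate", "severe")
WINDOWS = ("w1", "w2")
HORIZONS = ("3m", "12m")

#: resource-use questionnaire categories (quantities per window)
RU_CATEGORIES = (
    "gp",
    "psychologist",
    "psychiatrist",
    "diagnostic_test",
    "medication_script",
    "hospital_day",
    "ed_visit",
    "community_mh",
)

BASELINE_COLUMNS = (
    "arm",
    "group",
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
    "phq9_baseline",
    "utility_0m",
)

UTILITY_COLUMNS = ("utility_0m", "utility_3m", "utility_12m")

#: AQoL-8D instrument range for utility weights
UTILITY_MIN = -0.04
UTILITY_MAX = 1.0


def ru_column(category: str, window: str) -> str:
    return f"ru_{category}_{window}"


def ru_columns(window: str) -> list[str]:
    return [ru_column(c, window) for c in RU_CATEGORIES]


def days_off_columns(window: str) -> list[str]:
    return [f"days_off_paid_{window}", f"days_off_unpaid_{window}"]


def ruq_columns(window: str) -> list[str]:
    """All columns collected by the resource-use questionnaire for a window."""
    return ru_columns(window) + days_off_columns(window)
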