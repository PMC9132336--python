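import numpy as np
import pandas as pd
import pytest

from trialcua import (
    GeneratorTruth,
    InterventionCostSchedule,
    TrialDesign,
    UnitCostTable,
    apply_missingness,
    generate_trial,
    target_d_design,
    target_d_truth,
)
from trialcua.dataset import build_analysis_dataset


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def schedule():
    return InterventionCostSchedule.for_variant("base")


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down trial keeping the three-stratum structure."""
    return TrialDesign(n_total=400, group_props=(0.726, 0.155, 0.119), n_clinics=6)


@pytest.fixture(scope="session")
def truth():
    return target_d_truth()


@pytest.fixture(scope="session")
def preset_records(unit_costs):
    """One complete preset-sized trial, shared across read-only tests."""
    return generate_trial(target_d_design(), target_d_truth(), seed=42, unit_costs=unit_costs)


@pytest.fixture(scope="session")
def preset_records_mar(preset_records, truth):
    return apply_missingness(preset_records, truth, "MAR", seed=43)


@pytest.fixture(scope="session")
def small_records(small_design, truth, unit_costs):
    return generate_trial(small_design, truth, seed=7, unit_costs=unit_costs)


@pytest.fixture(scope="session")
def small_analysis(small_records, truth, unit_costs):
    miss = apply_missingness(small_records, truth, "MAR", seed=8)
    return build_analysis_dataset(miss, unit_costs)


def random_cost_dataset(rng, n=120):
    """Arm-labelled positive skewed outcomes for GLM oracle checks."""
    arm = rng.random(n) < 0.5
    y = rng.gamma(shape=0.8, scale=800.0, size=n) + 1.0
    y[arm] *= rng.uniform(0.5, 1.8)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": np.where(arm, "intervention", "control"),
            "group": "minimal_mild",
            "hs_cost_12m": y,
        }
    )
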