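# trialcua

A within-trial cost-utility analysis toolkit for two-arm randomised trials,
built around the design of a primary-care depression trial in which
participants are stratified into three prognostic groups (minimal/mild,
moderate, severe) and followed for 12 months. It takes participant-level
resource use and utility weights through micro-costing, QALY construction,
missing-data handling and bootstrap decision analytics, and ships a
synthetic trial generator with known ground truth so every stage can be
validated by parameter recovery.

## What it computes

For intervention (T) vs control (C), with cumulative costs over 3- and
12-month horizons under a health-sector or societal perspective:

- **Micro-costing** — per-person intervention cost (screening $0.96 +
  treatment $14/$132/$676 by prognostic group) plus valued resource-use
  quantities (unit-cost table in A$ 2018–19); societal costs add
  productivity losses valued by the human-capital approach.
- **QALYs** — area under the utility–time curve from AQoL-8D-range utility
  weights u at 0, 3, 12 months (trapezoidal):
  `QALY_12m = 0.25·(u0+u3)/2 + 0.75·(u3+u12)/2`.
- **Missing data** — multiple imputation by chained equations with
  predictive mean matching (type-1 PMM, k = 5 donors); m-fold MI with
  Rubin's rules for point estimation, and single imputation nested inside
  each bootstrap resample for uncertainty.
- **Incremental estimation** — cost ratios from gamma GLMs with log link,
  QALY differences from Gaussian GLMs, adjusted for baseline PHQ-9,
  general practice and prognostic group (plus baseline utility for QALY
  models); adjusted per-arm means by marginal standardization.
- **Decision analytics** — ICER = ΔC/ΔE with dominance classification,
  bootstrap percentile CIs ordered by angle on the cost-effectiveness
  plane, and CEACs via the net-monetary-benefit rule
  `P(λ·ΔE − ΔC > 0)` with the willingness-to-pay reference λ = A$50,000/QALY.

## Worked example

```python
from trialcua import (
    target_d_design, target_d_truth, generate_trial, apply_missingness,
    UnitCostTable, InterventionCostSchedule, GlmSpec, estimate_contrast,
)
from trialcua.dataset import build_analysis_dataset, derive_outcomes
from trialcua.imputation import ImputationSpec, mice_pmm

design, truth = target_d_design(), target_d_truth()
unit_costs = UnitCostTable.default()
schedule = InterventionCostSchedule.for_variant("base")

records = generate_trial(design, truth, seed=2, unit_costs=unit_costs)
observed = apply_missingness(records, truth, "MAR", seed=3)
analysis = build_analysis_dataset(observed, unit_costs)
stack = mice_pmm(analysis, ImputationSpec(m=5, seed=11))
derived = [derive_outcomes(d, schedule) for d in stack.datasets]

cost = estimate_contrast(derived, GlmSpec("health_sector_cost", "12m"))
qaly = estimate_contrast(derived, GlmSpec("qaly", "12m"))
print(f"cost ratio 12m: {cost.point:.3f} "
      f"({cost.ci_95[0]:.3f}, {cost.ci_95[1]:.3f})")
print(f"qaly diff 12m: {qaly.point:.4f} "
      f"({qaly.ci_95[0]:.4f}, {qaly.ci_95[1]:.4f})")
```

prints

```
cost ratio 12m: 0.869 (0.679, 1.112)
qaly diff 12m: 0.0104 (-0.0080, 0.0289)
```

i.e. on this simulated trial (true ratio 0.91, true QALY difference 0.011)
the intervention arm's adjusted mean 12-month health-sector cost is 13%
lower than control (not significant) and gains 0.0104 QALYs. The full
pipeline — including the bootstrap cost-effectiveness plane, CEAC and
paper-shaped report tables — runs from one config:

```bash
trialcua simulate --preset target_d --seed 1 --out runs/sim
trialcua run --config config.yaml --out runs/full
```

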