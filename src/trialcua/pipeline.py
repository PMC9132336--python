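"""End-to-end orchestration: simulate -> cost -> QALY -> impute -> estimate
-> decision analysis -> report, reproducible from a persisted config.

A run directory contains the simulated trial data, cost summaries, QALY
results, the tidy estimation table, paper-shaped report tables, decision
outputs (CE plane, CEAC) and a manifest with the config, all seeds and
SHA-256 hashes of every CSV/JSON output.  Rerunning from the persisted
config reproduces the manifest hashes exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cea, costing, dataset, estimation, imputation, outcomes, schema, synthetic


@dataclass
class RunConfig:
    preset: str = "target_d"  # target_d | null
    design_overrides: dict = field(default_factory=dict)
    truth_overrides: dict = field(default_factory=dict)
    mechanism: str = "MAR"  # MCAR | MAR | none
    m: int = 100
    k_donors: int = 5
    n_iterations: int = 10
    B: int = 1000
    schedule_variant: str = "base"
    covariates: str = "protocol"  # protocol | nonresponse_extended
    predictors: str = "default"  # default | nonresponse_extended
    complete_case: bool = False
    impute_on: str = "utilities"  # utilities | qalys
    lambda_max: float = 150_000.0
    lambda_step: float = 1_000.0
    wtp: float = 50_000.0
    ci_mode: str = "angular"
    stratify: str = "arm"
    cea_subgroups: tuple[str, ...] = ("all",)
    estimation_subgroups: tuple[str, ...] = ("all",) + schema.GROUPS
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("cea_subgroups", "estimation_subgroups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def make_design(self) -> synthetic.TrialDesign:
        if self.preset not in ("target_d", "null"):
            raise ValueError(f"unknown preset {self.preset!r}")
        base = dataclasses.asdict(synthetic.target_d_design())
        base.update(self.design_overrides)
        if base.get("arm_counts") and self.design_overrides.get("n_total"):
            base["arm_counts"] = None  # explicit splits only valid at preset size
        if base.get("arm_counts"):
            base["arm_counts"] = {g: tuple(v) for g, v in base["arm_counts"].items()}
        base["group_props"] = tuple(base["group_props"])
        base["horizons"] = tuple(base["horizons"])
        base["allocation_ratio"] = tuple(base["allocation_ratio"])
        return synthetic.TrialDesign(**base)

    def make_truth(self) -> synthetic.GeneratorTruth:
        maker = synthetic.null_truth if self.preset == "null" else synthetic.target_d_truth
        return maker(**self.truth_overrides)

    def lambda_grid(self) -> np.ndarray:
        return np.arange(0.0, self.lambda_max + self.lambda_step / 2, self.lambda_step)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "missingness", "impute", "bootstrap")
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# report rendering


def _fmt_money(x) -> str:
    return "--" if pd.isna(x) else f"{x:,.0f}"


def _fmt_ratio_ci(row) -> str:
    return f"{row['contrast']:.2f} ({row['ci_low']:.2f} to {row['ci_high']:.2f})"


def _fmt_qaly_ci(row) -> str:
    return (
        f"{row['contrast']:.3f} ({row['ci_low']:.3f} to {row['ci_high']:.3f})"
    )


def render_tables(results: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    """Paper-shaped cost and QALY tables from the tidy estimation results.

    Columns: all participants plus the three prognostic strata; rows:
    adjusted arm means (SE), contrast with 95% CI, p-value.  Money to whole
    A$, ratios to 2 decimals, QALYs to 3 decimals; missing cells rendered
    as explicit placeholders.
    """
    paths = {}
    tables = {
        "table1_health_sector_costs": ("health_sector", _fmt_money, _fmt_ratio_ci, 2),
        "table2_societal_costs": ("societal", _fmt_money, _fmt_ratio_ci, 2),
        "table3_qalys": ("qaly", lambda x: "--" if pd.isna(x) else f"{x:.3f}", _fmt_qaly_ci, 3),
    }
    subgroup_cols = ["all", *schema.GROUPS]
    for fname, (outcome, fmt_mean, fmt_ci, _nd) in tables.items():
        block = results[results["outcome"] == outcome]
        rows = []
        for horizon in schema.HORIZONS:
            for label, getter in (
                (
                    "intervention_mean_se",
                    lambda r: f"{fmt_mean(r['adj_mean_intervention'])} ({fmt_mean(r['adj_se_intervention'])})",
                ),
                (
                    "control_mean_se",
                    lambda r: f"{fmt_mean(r['adj_mean_control'])} ({fmt_mean(r['adj_se_control'])})",
                ),
                ("contrast_ci", fmt_ci),
                ("p_value", lambda r: f"{r['p_value']:.2f}"),
            ):
                row = {"horizon": horizon, "quantity": label}
                for sg in subgroup_cols:
                    cell = block[(block["horizon"] == horizon) & (block["subgroup"] == sg)]
                    row[sg] = getter(cell.iloc[0]) if len(cell) else "--"
                rows.append(row)
        table = pd.DataFrame(rows)
        path = outdir / f"{fname}.csv"
        table.to_csv(path, index=False)
        paths[fname] = path
    return paths


def render_icer_table(
    summaries: dict[tuple[str, str, str], cea.CeaResult], outdir: Path
) -> Path:
    """Table of ICER (95% CI) cells, e.g. ``Dominant (Dominant to 87,636)``."""

    def fmt(res: cea.CeaResult) -> str:
        pt = res.icer_point if isinstance(res.icer_point, str) else f"{res.icer_point:,.0f}"
        lo, hi = (
            b if isinstance(b, str) else f"{b:,.0f}" for b in res.ci_95
        )
        return f"{pt} ({lo} to {hi})"

    subgroups = ["all", *schema.GROUPS]
    rows = []
    for perspective in ("health_sector", "societal"):
        for horizon in schema.HORIZONS:
            row = {"perspective": perspective, "horizon": horizon}
            for sg in subgroups:
                res = summaries.get((perspective, horizon, sg))
                row[sg] = fmt(res) if res is not None else "--"
            rows.append(row)
    path = outdir / "table4_icers.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# full run


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage and return the manifest (also persisted)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    unit_costs = costing.UnitCostTable.default()
    schedule = costing.InterventionCostSchedule.for_variant(config.schedule_variant)
    stage = "simulate"
    try:
        design = config.make_design()
        truth = config.make_truth()
        records = synthetic.generate_trial(design, truth, seeds["simulate"], unit_costs)
        if config.mechanism in ("MCAR", "MAR"):
            records = synthetic.apply_missingness(
                records, truth, config.mechanism, seeds["missingness"]
            )
        synthetic.save_dataset(records, design, truth, config.seed, outdir)

        stage = "cost"
        costs = costing.assemble_costs(records, unit_costs, schedule)
        costs.to_csv(outdir / "cost_summaries.csv", index=False)
        analysis = dataset.build_analysis_dataset(records, unit_costs)

        stage = "qaly"
        qalys = outcomes.qaly_auc(records)
        qalys.to_csv(outdir / "qaly_results.csv", index=False)

        stage = "impute"
        if config.impute_on == "qalys":
            # sensitivity order: impute QALYs directly instead of utilities
            analysis = analysis.copy()
            analysis[["qaly_3m", "qaly_12m"]] = qalys[["qaly_3m", "qaly_12m"]].to_numpy()
            variables = ("qaly_3m", "qaly_12m", "hs_util_w1", "hs_util_w2", "prod_w1", "prod_w2")
            analysis = analysis.drop(columns=["utility_3m", "utility_12m"])
        elif config.impute_on == "utilities":
            variables = dataset.IMPUTABLE_COLUMNS
        else:
            raise ValueError(f"unknown impute_on {config.impute_on!r}")
        spec = imputation.ImputationSpec(
            variables_to_impute=variables,
            predictors=imputation.PREDICTOR_PRESETS[config.predictors],
            m=config.m,
            k_donors=config.k_donors,
            n_iterations=config.n_iterations,
            seed=seeds["impute"],
        )
        if config.complete_case or not analysis.isna().any().any():
            completed = [analysis.dropna(subset=list(variables))]
        else:
            stack = imputation.mice_pmm(analysis, spec)
            stack.traces.to_csv(outdir / "imputation_traces.csv", index=False)
            completed = stack.datasets
        derived = [dataset.derive_outcomes(d, schedule) for d in completed]

        stage = "estimate"
        results = estimation.run_estimation_suite(
            derived,
            covariates=config.covariates,
            variant=config.schedule_variant
            if not config.complete_case
            else "complete_case",
            subgroups=config.estimation_subgroups,
        )
        results.to_csv(outdir / "estimation_results.csv", index=False)

        stage = "cea"
        draws = cea.bootstrap_cea(
            analysis,
            spec,
            schedule,
            B=config.B,
            seed=seeds["bootstrap"],
            covariates=config.covariates,
            subgroups=config.cea_subgroups,
            stratify=config.stratify,
        )
        draws.draws.to_csv(outdir / "bootstrap_draws.csv", index=False)
        summaries = {}
        for subgroup in config.cea_subgroups:
            for perspective in ("health_sector", "societal"):
                label = "health_sector" if perspective == "health_sector" else "societal"
                for horizon in schema.HORIZONS:
                    point = results[
                        (results["outcome"] == label)
                        & (results["horizon"] == horizon)
                        & (results["subgroup"] == subgroup)
                    ].iloc[0]
                    qpoint = results[
                        (results["outcome"] == "qaly")
                        & (results["horizon"] == horizon)
                        & (results["subgroup"] == subgroup)
                    ].iloc[0]
                    dc, de = draws.cell(perspective, horizon, subgroup)
                    res = cea.summarize_cell(
                        point["adj_mean_intervention"] - point["adj_mean_control"],
                        qpoint["contrast"],
                        dc,
                        de,
                        lambda_grid=config.lambda_grid(),
                        wtp=config.wtp,
                        ci_mode=config.ci_mode,
                    )
                    summaries[(perspective, horizon, subgroup)] = res
                    cea.export_decision_outputs(
                        res, dc, de, outdir, prefix=f"cea_{perspective}_{horizon}_{subgroup}"
                    )

        stage = "report"
        render_tables(results, outdir)
        render_icer_table(summaries, outdir)
        config.to_yaml(outdir / "config.yaml")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import matplotlib

    manifest = {
        "package_version": __version__,
        "matplotlib_version": matplotlib.__version__,
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "bootstrap_redraws": draws.n_redraws,
        "hashes": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".csv", ".json", ".yaml") and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
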