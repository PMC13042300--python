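"""End-to-end analysis orchestration and calibration experiments.

``analyze`` reproduces the two-track workflow on one dataset: (1) factorial
ANOVA on the raw per-plate scores with post hoc comparisons, and (2) the
bootstrapped effect of food deprivation per strain, whose (mean, SD,
pseudo-N) summaries feed a second ANOVA and post hoc layer.  All artifacts
are written as plain CSV/JSON with the seed and configuration echoed, so a
report regenerates bit-identically.

The calibration experiments measure what the procedure actually delivers on
data from the synthetic generator: CI coverage of the true effect, type-I
error of the ANOVA terms and post hoc families, and bias/RMSE of the effect
estimator.  Inside simulations the bootstrap runs at a reduced replicate
count (recorded in every report) to keep each experiment to a few minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_data import (
    Condition,
    ExperimentTable,
    GroupSample,
    Score,
    group_samples,
    read_plates,
    write_plates,
)
from .bootstrap_effect import BootstrapConfig, BootstrapResult, bootstrap_difference
from .factorial_stats import (
    AdjustMethod,
    AnovaTable,
    ComparisonResult,
    FactorialDesign,
    anova_raw,
    bootstrap_effect_anova,
    posthoc_sidak,
    report_hierarchy,
)
from .synthetic_data import GeneratorConfig, generate_dataset, true_effect

__all__ = [
    "AnalysisPlan",
    "AnalysisReport",
    "CalibrationReport",
    "analyze",
    "coverage_experiment",
    "type1_experiment",
    "recovery_experiment",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-simulation seeds derived from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def mc_se(rate: float, n: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(r(1-r)/n)."""
    return float(np.sqrt(rate * (1.0 - rate) / n))


@dataclass
class AnalysisPlan:
    """What to analyze and how: exactly one input source, a score, a
    bootstrap configuration, and the post hoc method for the summary track."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    score: Score = Score.PERCENT_EXITING
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    posthoc: AdjustMethod = AdjustMethod.SIDAK
    wildtype: str = "WT"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")

    def to_dict(self) -> dict:
        gen = None
        if self.generator is not None:
            gen = dataclasses.asdict(self.generator)
            gen["assay"] = self.generator.assay.value
        return {
            "input_path": self.input_path,
            "generator": gen,
            "score": self.score.value,
            "bootstrap": dataclasses.asdict(self.bootstrap),
            "posthoc": self.posthoc.value,
            "wildtype": self.wildtype,
            "alpha": self.alpha,
        }


@dataclass
class AnalysisReport:
    raw_anova: AnovaTable
    raw_comparisons: list[ComparisonResult]
    bootstrap_results: dict[str, BootstrapResult]
    summary_anova: AnovaTable | None
    summary_comparisons: list[ComparisonResult]
    findings: list[tuple[str, float]]
    seed: int
    plan: AnalysisPlan


def _fed_fd(groups_by_strain: dict, strain: str):
    cells = groups_by_strain[strain]
    if Condition.FED not in cells or Condition.FOOD_DEPRIVED not in cells:
        raise ValueError(f"strain {strain!r} lacks a fed or food-deprived cell")
    return cells[Condition.FED], cells[Condition.FOOD_DEPRIVED]


def _collapse(table: ExperimentTable, score: Score) -> dict[str, dict[Condition, np.ndarray]]:
    """Per-strain, per-condition score vectors (assay parameters pooled)."""
    out: dict[str, dict[Condition, list[float]]] = {}
    for key, sample in group_samples(table, score).items():
        bucket = out.setdefault(key.strain, {}).setdefault(key.condition, [])
        bucket.extend(sample.values.tolist())
    return {
        s: {c: np.asarray(v, dtype=float) for c, v in cells.items()}
        for s, cells in out.items()
    }


def analyze(plan: AnalysisPlan, outdir, seed: int = 0) -> AnalysisReport:
    """Run the full two-track analysis and write every artifact to ``outdir``.

    The seed drives dataset generation (when the plan uses the generator) and
    one bootstrap stream per strain, derived in sorted-strain order, so the
    whole report is reproducible from (plan, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    gen_seed, boot_root = (int(s.generate_state(1)[0]) for s in root.spawn(2))

    if plan.generator is not None:
        dataset = generate_dataset(replace(plan.generator, seed=gen_seed))
        table = dataset.table
        write_plates(table, outdir / "plates.csv")
        dataset.truth.to_csv(outdir / "truth.csv", index=False)
        # I/O transparency: analysis proceeds from the written file
        table = read_plates(outdir / "plates.csv")
    else:
        table = read_plates(plan.input_path)
    table.validate_controls(plan.wildtype)

    by_strain = _collapse(table, plan.score)
    strains = sorted(by_strain)
    conditions = [Condition.FED.value, Condition.FOOD_DEPRIVED.value]

    # Track 1: raw factorial ANOVA (strain × condition) + Šidák post hoc
    cells = {}
    for s in strains:
        fed, fd = _fed_fd(by_strain, s)
        cells[(s, Condition.FED.value)] = fed
        cells[(s, Condition.FOOD_DEPRIVED.value)] = fd
    design = FactorialDesign(
        factors={"strain": strains, "condition": conditions}, cells=cells
    )
    raw_table = anova_raw(design)
    raw_comparisons: list[ComparisonResult] = []
    mutants = [s for s in strains if s != plan.wildtype]
    if mutants and plan.wildtype in strains:
        sidak_plan = [
            (f"{m} vs {plan.wildtype}, {c}", (m, c), (plan.wildtype, c))
            for m in mutants
            for c in conditions
        ]
        raw_comparisons = posthoc_sidak(design, sidak_plan)

    # Track 2: per-strain bootstrapped effect of food deprivation
    boot_seeds = _child_seeds(boot_root, len(strains))
    boot_results: dict[str, BootstrapResult] = {}
    for s, child in zip(strains, boot_seeds):
        fed, fd = _fed_fd(by_strain, s)
        cfg = replace(plan.bootstrap, seed=int(child))
        boot_results[s] = bootstrap_difference(fed, fd, cfg)

    summary_table, summary_comparisons = None, []
    if len(strains) >= 2:
        keyed = {(s,): r for s, r in boot_results.items()}
        if plan.posthoc is AdjustMethod.DUNNETT and plan.wildtype in strains:
            summary_table, summary_comparisons = bootstrap_effect_anova(
                keyed, {"strain": strains},
                posthoc=AdjustMethod.DUNNETT, control_key=(plan.wildtype,),
            )
        else:
            plan_pairs = [
                (f"effect: {m} vs {plan.wildtype}", (m,), (plan.wildtype,))
                for m in mutants
            ] if plan.wildtype in strains else []
            summary_table, summary_comparisons = bootstrap_effect_anova(
                keyed, {"strain": strains},
                posthoc=AdjustMethod.SIDAK, plan=plan_pairs,
            )

    findings = report_hierarchy(raw_table, plan.alpha)
    report = AnalysisReport(
        raw_anova=raw_table,
        raw_comparisons=raw_comparisons,
        bootstrap_results=boot_results,
        summary_anova=summary_table,
        summary_comparisons=summary_comparisons,
        findings=findings,
        seed=seed,
        plan=plan,
    )
    _write_report(report, outdir)
    return report


def _comparisons_frame(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    report.raw_anova.to_csv(outdir / "anova_raw.csv")
    if report.raw_comparisons:
        _comparisons_frame(report.raw_comparisons).to_csv(
            outdir / "posthoc_raw.csv", index=False
        )
    if report.summary_anova is not None:
        report.summary_anova.to_csv(outdir / "anova_bootstrap.csv")
    if report.summary_comparisons:
        _comparisons_frame(report.summary_comparisons).to_csv(
            outdir / "posthoc_bootstrap.csv", index=False
        )
    with open(outdir / "hierarchy.txt", "w", encoding="utf-8") as fh:
        fh.write(report.raw_anova.to_text() + "\n\nReported findings:\n")
        if report.findings:
            for term, p in report.findings:
                fh.write(f"  {term}: P = {p:.4g}\n")
        else:
            fh.write("  no significant terms\n")
    payload = {
        "seed": report.seed,
        "plan": report.plan.to_dict(),
        "findings": [[t, p] for t, p in report.findings],
        "effects": {s: r.to_dict() for s, r in report.bootstrap_results.items()},
    }
    with open(outdir / "analysis.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Calibration experiments
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    """Outcome of a simulation experiment, with everything needed to rerun it."""

    experiment: str
    n_sims: int
    seed: int
    config: dict
    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_echo(config: GeneratorConfig, bootstrap: BootstrapConfig) -> dict:
    gen = dataclasses.asdict(config)
    gen["assay"] = config.assay.value
    return {"generator": gen, "bootstrap": dataclasses.asdict(bootstrap)}


def _sim_effect(
    config: GeneratorConfig, strain: str, gen_seed: int,
    bootstrap: BootstrapConfig, boot_seed: int,
) -> BootstrapResult:
    dataset = generate_dataset(replace(config, seed=gen_seed))
    by_strain = _collapse(dataset.table, Score.PERCENT_EXITING)
    fed, fd = _fed_fd(by_strain, strain)
    return bootstrap_difference(fed, fd, replace(bootstrap, seed=boot_seed))


def coverage_experiment(
    config: GeneratorConfig,
    n_sims: int,
    bootstrap: BootstrapConfig | None = None,
    strain: str = "WT",
    seed: int = 0,
) -> CalibrationReport:
    """Fraction of simulations whose trimmed percentile CI contains the true
    effect of food deprivation, with its Monte-Carlo standard error.

    The percentile bootstrap is approximately — not exactly — nominal, and
    small per-cell plate counts push coverage below the nominal level.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    bootstrap = bootstrap or BootstrapConfig(n_reps=2000)
    te = true_effect(config, strain)
    seeds = _child_seeds(seed, 2 * n_sims)
    hits = 0
    for i in range(n_sims):
        res = _sim_effect(
            config, strain, int(seeds[2 * i]), bootstrap, int(seeds[2 * i + 1])
        )
        if res.ci_low <= te <= res.ci_high:
            hits += 1
    rate = hits / n_sims
    return CalibrationReport(
        experiment="coverage",
        n_sims=n_sims,
        seed=seed,
        config=_config_echo(config, bootstrap),
        rows=[
            {
                "strain": strain,
                "true_effect": te,
                "nominal": 1.0 - bootstrap.alpha,
                "observed": rate,
                "mc_se": mc_se(rate, n_sims),
                "plates_per_cell": config.plates_per_cell,
            }
        ],
    )


def _require_null(config: GeneratorConfig) -> None:
    for s in config.strains:
        if s.strain_logit != 0.0 or s.interaction_logit != 0.0:
            raise ValueError(
                "type-I experiment requires a null config "
                "(zero strain and interaction effects)"
            )


def type1_experiment(
    config: GeneratorConfig,
    n_sims: int,
    procedure: str = "raw_interaction",
    alpha: float = 0.05,
    bootstrap: BootstrapConfig | None = None,
    seed: int = 0,
) -> CalibrationReport:
    """Null rejection rate of one stage of the pipeline.

    Procedures: ``raw_interaction`` (strain × condition F-test on raw
    percent exiting; expected to hold its nominal level, and the report flags
    rates outside [0.035, 0.065] as miscalibrated), ``summary_effect`` (the
    strain term of the ANOVA on bootstrapped-difference summaries with
    pseudo-N — the rule under study; its rate is reported without a pass
    band), and ``sidak_family`` (familywise rate of the Šidák-corrected
    mutant-vs-WT comparisons on raw data).
    """
    if procedure not in ("raw_interaction", "summary_effect", "sidak_family"):
        raise ValueError(f"unknown procedure {procedure!r}")
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha outside [0, 1]")
    _require_null(config)
    if len(config.strains) < 2:
        raise ValueError("need >= 2 strains for a between-strain null")
    bootstrap = bootstrap or BootstrapConfig(n_reps=2000)
    strains = sorted(s.name for s in config.strains)
    conditions = [Condition.FED.value, Condition.FOOD_DEPRIVED.value]
    seeds = _child_seeds(seed, 2 * n_sims)
    rejections = 0
    for i in range(n_sims):
        dataset = generate_dataset(replace(config, seed=int(seeds[2 * i])))
        by_strain = _collapse(dataset.table, Score.PERCENT_EXITING)
        if procedure == "summary_effect":
            boot_seeds = _child_seeds(int(seeds[2 * i + 1]), len(strains))
            keyed = {}
            for s, bs in zip(strains, boot_seeds):
                fed, fd = _fed_fd(by_strain, s)
                keyed[(s,)] = bootstrap_difference(
                    fed, fd, replace(bootstrap, seed=int(bs))
                )
            table, _ = bootstrap_effect_anova(keyed, {"strain": strains})
            p = table.term_p("strain")
            rejections += bool(p < alpha)
            continue
        cells = {}
        for s in strains:
            fed, fd = _fed_fd(by_strain, s)
            cells[(s, conditions[0])] = fed
            cells[(s, conditions[1])] = fd
        design = FactorialDesign(
            factors={"strain": strains, "condition": conditions}, cells=cells
        )
        if procedure == "raw_interaction":
            table = anova_raw(design)
            rejections += bool(table.term_p("strain:condition") < alpha)
        else:  # sidak_family
            wt = strains[0]
            plan = [
                (f"{m} vs {wt}, {c}", (m, c), (wt, c))
                for m in strains[1:]
                for c in conditions
            ]
            comps = posthoc_sidak(design, plan)
            rejections += any(c.adjusted_p < alpha for c in comps)
    rate = rejections / n_sims if alpha > 0 else 0.0
    row = {
        "procedure": procedure,
        "nominal": alpha,
        "observed": rate,
        "mc_se": mc_se(rate, n_sims),
    }
    if procedure in ("raw_interaction", "sidak_family"):
        row["miscalibrated"] = not (0.035 <= rate <= 0.065) if alpha == 0.05 else None
    return CalibrationReport(
        experiment="type1",
        n_sims=n_sims,
        seed=seed,
        config=_config_echo(config, bootstrap),
        rows=[row],
    )


def recovery_experiment(
    configs: list[GeneratorConfig],
    n_sims: int,
    bootstrap: BootstrapConfig | None = None,
    strain: str = "WT",
    seed: int = 0,
) -> CalibrationReport:
    """Bias and RMSE of the bootstrapped effect estimator (mean of replicate
    means) against the generator's true effect, per configuration."""
    if not configs:
        raise ValueError("empty configuration grid")
    bootstrap = bootstrap or BootstrapConfig(n_reps=2000)
    rows = []
    for j, config in enumerate(configs):
        te = true_effect(config, strain)
        seeds = _child_seeds(seed + j, 2 * n_sims)
        estimates = np.empty(n_sims)
        for i in range(n_sims):
            res = _sim_effect(
                config, strain, int(seeds[2 * i]), bootstrap, int(seeds[2 * i + 1])
            )
            estimates[i] = res.mean_of_means
        err = estimates - te
        rows.append(
            {
                "true_effect": te,
                "plates_per_cell": config.plates_per_cell,
                "rho": config.rho,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "bias_mc_se": float(err.std(ddof=1) / np.sqrt(n_sims)),
                "n_sims": n_sims,
            }
        )
    return CalibrationReport(
        experiment="recovery",
        n_sims=n_sims,
        seed=seed,
        config=_config_echo(configs[0], bootstrap),
        rows=rows,
    )
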