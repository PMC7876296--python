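"""End-to-end orchestration: cohort -> adjustment -> indicators -> batteries
-> grades -> report files."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

import carproc
from carproc.adjustment import (
    DEFAULT_ADJUST_VARS,
    AdjustmentModel,
    adjust,
    aprt,
    assign_bmi_group,
    fit_adjustment,
)
from carproc.factors import (
    FactorModel,
    compute_ansi,
    factor_scores,
    fit_retained_efa,
    indicators_from_scores,
    label_factors,
)
from carproc.grading import EvidenceGrade, grade_evidence, synoptic_table
from carproc.nptests import (
    BatteryConfig,
    TestBattery,
    bootstrap_median_ci,
    correlation_screen,
    notch_interval,
    proxy_group_screen,
    run_battery,
)
from carproc.proxies import INDICATOR_TREND_DIRECTION, PROXY_NAMES
from carproc.reference import BMI_GROUPS
from carproc.synthetic import GeneratorConfig, default_config, generate_cohort, read_cohort

#: Indicators submitted to the test battery (BMI_aPRT is the grouping proxy
#: and only enters the correlation table).
BATTERY_INDICATORS: tuple[str, ...] = (
    "OSC_ind",
    "AMP_ind",
    "PRESS_ind",
    "PUL_ind",
    "alpha_aPRT",
    "ANSI",
)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    source: str = "simulate"  # 'simulate' or a cohort CSV path
    generator: GeneratorConfig | None = None
    n_total: int = 756
    seed: int = 0
    log_transform: bool = True
    max_factors: int = 4
    score_method: str = "regression"
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    direction_policy: str = "configured"  # or 'auto'
    out_dir: str | None = None
    make_figures: bool = False

    def config_hash(self) -> str:
        gen = self.generator.to_dict() if self.generator is not None else None
        payload = {
            "source": self.source,
            "generator": gen,
            "n_total": self.n_total,
            "seed": self.seed,
            "log_transform": self.log_transform,
            "max_factors": self.max_factors,
            "score_method": self.score_method,
            "battery": vars(self.battery),
            "direction_policy": self.direction_policy,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All stage outputs of one pipeline run."""

    cohort: pd.DataFrame
    group_labels: np.ndarray
    adjustment_model: AdjustmentModel
    factor_model: FactorModel
    factor_labels: dict
    indicator_table: pd.DataFrame
    proxy_screen: pd.DataFrame
    proxy_correlations: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]
    indicator_correlations: tuple[pd.DataFrame, pd.DataFrame]
    notches: pd.DataFrame
    median_cis: pd.DataFrame
    batteries: dict[str, TestBattery]
    grades: dict[str, EvidenceGrade]
    synoptic: pd.DataFrame
    provenance: dict


def build_indicator_table(
    cohort: pd.DataFrame,
    adjustment_model: AdjustmentModel,
    factor_model: FactorModel,
    factor_labels: dict,
) -> pd.DataFrame:
    """Assemble the seven percentile indicator columns for ``cohort``."""
    adjusted = adjust(cohort, adjustment_model, variables=tuple(factor_model.variable_names))
    scores = factor_scores(factor_model, adjusted)
    table = indicators_from_scores(scores, factor_labels)
    table.index = cohort.index
    table["alpha_aPRT"] = aprt(cohort, "α index", adjustment_model)
    table["BMI_aPRT"] = aprt(cohort, "bmi", adjustment_model)
    table["ANSI"] = compute_ansi(cohort, adjustment_model)
    return table


def indicator_correlations(indicator_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (with p-values) among the indicator columns."""
    r, p, _ = correlation_screen(indicator_table)
    return r, p


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order: ingest/simulate, proxy screens,
    adjustment, factor indicators, per-group medians, batteries, grading."""
    # -- stage: cohort ------------------------------------------------------
    if config.source == "simulate":
        gen = config.generator
        if gen is None:
            gen = default_config(seed=config.seed, n_total=config.n_total)
        cohort, _ = generate_cohort(gen)
    else:
        cohort = read_cohort(config.source)
    groups = assign_bmi_group(cohort["bmi"].to_numpy())

    # -- stage: exploratory screens ----------------------------------------
    proxy_screen = proxy_group_screen(cohort, group_labels=groups)
    screen_cols = cohort[["bmi", *PROXY_NAMES]].rename(columns={"bmi": "BMI"})
    proxy_corr = correlation_screen(screen_cols)

    # -- stage: adjustment and factor indicators ---------------------------
    adj_model = fit_adjustment(
        cohort, variables=DEFAULT_ADJUST_VARS, log_transform=config.log_transform
    )
    adjusted = adjust(cohort, adj_model, variables=PROXY_NAMES)
    factor_model = fit_retained_efa(
        adjusted, max_factors=config.max_factors, score_method=config.score_method
    )
    labels = label_factors(factor_model)
    indicator_table = build_indicator_table(cohort, adj_model, factor_model, labels)
    ind_corr = indicator_correlations(indicator_table)

    # -- stage: per-group medians (notches and bootstrap CIs) ---------------
    seed_root = np.random.SeedSequence(config.seed)
    ci_seeds = seed_root.spawn(len(BATTERY_INDICATORS) * len(BMI_GROUPS))
    notch_rows = []
    ci_rows = []
    idx = 0
    for name in BATTERY_INDICATORS:
        for g in BMI_GROUPS:
            vals = indicator_table.loc[np.asarray(groups) == g, name].to_numpy()
            notch = notch_interval(vals)
            notch_rows.append(
                {
                    "indicator": name,
                    "group": g,
                    "median": notch.median,
                    "q1": notch.q1,
                    "q3": notch.q3,
                    "n": notch.n,
                    "lower": notch.lower,
                    "upper": notch.upper,
                }
            )
            ci = bootstrap_median_ci(
                vals,
                replicates=config.battery.median_replicates,
                level=config.battery.median_level,
                seed=ci_seeds[idx],
            )
            ci_rows.append(
                {
                    "indicator": name,
                    "group": g,
                    "median": float(np.median(vals)),
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "replicates": ci.replicates,
                }
            )
            idx += 1
    notches = pd.DataFrame(notch_rows)
    median_cis = pd.DataFrame(ci_rows)

    # -- stage: batteries and grading ---------------------------------------
    battery_seeds = seed_root.spawn(len(BATTERY_INDICATORS))
    batteries: dict[str, TestBattery] = {}
    grades: dict[str, EvidenceGrade] = {}
    for name, bseed in zip(BATTERY_INDICATORS, battery_seeds):
        bcfg = replace(config.battery, seed=int(bseed.generate_state(1)[0]))
        if config.direction_policy == "configured":
            bcfg = replace(bcfg, direction=INDICATOR_TREND_DIRECTION[name])
        batteries[name] = run_battery(
            indicator_table[name].to_numpy(), groups, config=bcfg, indicator=name
        )
        grades[name] = grade_evidence(batteries[name])
    synoptic = synoptic_table(batteries)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(len(cohort)),
        "carproc_version": carproc.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }

    report = RunReport(
        cohort=cohort,
        group_labels=np.asarray(groups),
        adjustment_model=adj_model,
        factor_model=factor_model,
        factor_labels=labels,
        indicator_table=indicator_table,
        proxy_screen=proxy_screen,
        proxy_correlations=proxy_corr,
        indicator_correlations=ind_corr,
        notches=notches,
        median_cis=median_cis,
        batteries=batteries,
        grades=grades,
        synoptic=synoptic,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(report, config)
    return report


def write_report(report: RunReport, config: PipelineConfig) -> None:
    """Persist stage outputs as CSV/JSON (and figures when requested)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cohort.to_csv(out / "cohort.csv", index=False)
    table = report.indicator_table.copy()
    table.insert(0, "id", report.cohort["id"].to_numpy())
    table.insert(1, "group", report.group_labels)
    table.to_csv(out / "indicators.csv", index=False)
    report.proxy_screen.to_csv(out / "proxy_screen.csv")
    r, p, codes = report.proxy_correlations
    r.to_csv(out / "proxy_correlations_r.csv")
    p.to_csv(out / "proxy_correlations_p.csv")
    codes.to_csv(out / "proxy_correlations_codes.csv")
    ir, ip = report.indicator_correlations
    ir.to_csv(out / "indicator_correlations_r.csv")
    ip.to_csv(out / "indicator_correlations_p.csv")
    report.notches.to_csv(out / "notches.csv", index=False)
    report.median_cis.to_csv(out / "median_cis.csv", index=False)
    pd.concat([b.to_frame() for b in report.batteries.values()]).to_csv(
        out / "battery.csv", index=False
    )
    report.synoptic.to_csv(out / "synoptic.csv")
    report.adjustment_model.to_json(out / "adjustment_model.json")
    report.factor_model.to_json(out / "factor_model.json")
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(report.provenance, fh, indent=1)
    if config.make_figures:
        from carproc import plots

        plots.notched_box_panels(
            report.indicator_table, report.group_labels, out / "notched_boxes.png"
        )
        plots.density_panels(
            report.indicator_table, report.group_labels, out / "densities.png"
        )
        plots.correlation_plot(r, codes, out / "proxy_correlations.png")
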