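"""End-to-end study analysis: no-choice ANOVA, choice preference, and
functional-response fits assembled into one structured report.

The reporter only collects module outputs — every number in a
:class:`StudyReport` is traceable to exactly one module call, nothing is
recomputed here. Missing experiment sections are skipped with a logged
notice rather than an error, so partial datasets still analyse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .art import AlignedRankANOVA
from .functional_response import (
    FlexibleTypeII,
    RogersTypeII,
    compare_models,
    determine_type,
)
from .io import Experiment, TrialDataset
from .preference import MANLY_VARIANT, summarize_preference

logger = logging.getLogger("predfr")


@dataclass
class AnalysisConfig:
    """Settings for a full study analysis run."""

    duration_T: float = 1.0
    significance_level: float = 0.05
    posthoc_adjustment: str = "tukey"
    manly_variant: str = MANLY_VARIANT
    bootstrap: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance level must be in (0, 1)")
        if not self.duration_T > 0:
            raise ValueError("duration must be > 0")


@dataclass
class StudyReport:
    """Structured result bundle for the three analysis stages.

    Sections for experiments absent from the input are ``None`` and
    serialise as explicit nulls.
    """

    no_choice: dict | None
    choice: dict | None
    functional_response: dict | None
    provenance: dict = field(default_factory=dict)


def _treatment_means(dataset: TrialDataset) -> list[dict]:
    """Mean +/- SEM consumption per (species, stage) treatment.

    SEM is the sample SD over replicates divided by sqrt(n). Zero-consumption
    treatments are flagged so renderers can apply the "/" convention.
    """
    rows: dict[tuple, list[int]] = {}
    for t in dataset:
        (stage,) = t.stages
        rows.setdefault((t.predator_species, stage), []).append(t.consumed[stage])
    out = []
    for (species, stage), values in sorted(rows.items()):
        arr = np.asarray(values, dtype=float)
        n = len(arr)
        sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            {
                "species": species,
                "stage": stage,
                "n": n,
                "mean": float(arr.mean()),
                "sem": sem,
                "all_zero": bool(np.all(arr == 0)),
            }
        )
    return out


def _nochoice_section(dataset: TrialDataset, config: AnalysisConfig) -> dict:
    frame = pd.DataFrame(
        {
            "factor_A": [t.predator_species for t in dataset],
            "factor_B": [t.stages[0] for t in dataset],
            "response": [t.consumed[t.stages[0]] for t in dataset],
        }
    )
    model = AlignedRankANOVA(frame)
    art = model.fit()
    posthoc = model.posthoc("A", adjustment=config.posthoc_adjustment)
    logger.info("no-choice: %d rows, posthoc adjustment=%s",
                len(frame), config.posthoc_adjustment)
    return {
        "anova": {
            name: {"F": t.F, "df_num": t.df_num, "df_den": t.df_den, "p": t.p}
            for name, t in art.effects.items()
        },
        "diagnostics": art.diagnostics,
        "posthoc": posthoc.to_dict(orient="records"),
        "posthoc_adjustment": config.posthoc_adjustment,
        "treatment_means": _treatment_means(dataset),
    }


def _choice_section(dataset: TrialDataset, config: AnalysisConfig) -> dict:
    result = summarize_preference(dataset)
    logger.info("choice: %d rows, Manly variant=%s", len(dataset), result.variant)
    return {
        "alphas": [list(pair) for pair in result.alphas],
        "mean_alpha_I": result.mean_alpha_I,
        "mean_alpha_II": result.mean_alpha_II,
        "sem_alpha_I": result.sem_alpha_I,
        "n_defined": result.n_defined,
        "n_undefined": result.n_undefined,
        "variant": result.variant,
    }


def _fr_section(dataset: TrialDataset, config: AnalysisConfig) -> dict:
    tdet = determine_type(dataset, T=config.duration_T,
                          alpha=config.significance_level)
    rogers = RogersTypeII.from_dataset(dataset, T=config.duration_T).fit()
    flex_model = FlexibleTypeII(rogers.model.N0, rogers.model.consumed,
                                T=config.duration_T)
    free = flex_model.fit()
    fixed = flex_model.fit(fix_q=0.0)
    comparison = compare_models(free, fixed)
    densities = sorted(set(rogers.model.N0.astype(int).tolist()))
    curve = (
        [
            {"N0": float(n), "expected_consumed": float(v)}
            for n, v in zip(densities, rogers.predict(densities))
        ]
        if rogers.converged
        else []
    )
    logger.info("functional response: %d rows, delta AIC rule: deviation iff < -2",
                len(dataset))

    def _fit_dict(fit):
        return {
            "params": fit.params.to_dict(),
            "bse": {k: (None if not np.isfinite(v) else float(v))
                    for k, v in fit.bse.items()},
            "logL": fit.llf,
            "aic": fit.aic,
            "converged": fit.converged,
            "fixed": fit.fixed,
        }

    return {
        "type_determination": {
            "b1": tdet.b1, "b1_se": tdet.b1_se, "b1_z": tdet.b1_z, "b1_p": tdet.b1_p,
            "b2": tdet.b2, "b2_se": tdet.b2_se, "b2_z": tdet.b2_z, "b2_p": tdet.b2_p,
            "response_type": tdet.response_type,
            "converged": tdet.converged,
            "linear_only": tdet.linear_only,
        },
        "rogers_fit": _fit_dict(rogers),
        "flexible_fit_free": _fit_dict(free),
        "flexible_fit_q0": _fit_dict(fixed),
        "delta_aic": comparison.delta_aic,
        "conclusion": comparison.conclusion,
        "curve": curve,
    }


def run_study(dataset: TrialDataset, config: AnalysisConfig | None = None) -> StudyReport:
    """Run every applicable analysis stage on a mixed trial dataset."""
    config = config or AnalysisConfig()
    sections: dict[str, dict | None] = {}
    stage_fns = {
        "no_choice": (Experiment.NO_CHOICE, _nochoice_section),
        "choice": (Experiment.CHOICE, _choice_section),
        "functional_response": (Experiment.FUNCTIONAL_RESPONSE, _fr_section),
    }
    any_rows = False
    for name, (experiment, fn) in stage_fns.items():
        subset = dataset.filter(experiment)
        if len(subset) == 0:
            logger.info("no %s rows; section skipped", name)
            sections[name] = None
            continue
        any_rows = True
        sections[name] = fn(subset, config)
    if not any_rows:
        raise ValueError("no recognizable experiment rows in the dataset")
    return StudyReport(
        no_choice=sections["no_choice"],
        choice=sections["choice"],
        functional_response=sections["functional_response"],
        provenance={
            "package_version": __version__,
            "config": {
                "duration_T": config.duration_T,
                "significance_level": config.significance_level,
                "posthoc_adjustment": config.posthoc_adjustment,
                "manly_variant": config.manly_variant,
                "bootstrap": config.bootstrap,
                "seed": config.seed,
            },
            "dataset_metadata": dict(dataset.metadata),
            "n_trials": len(dataset),
        },
    )


def _mean_sem_cell(row: dict) -> str:
    if row["all_zero"]:
        return "/"
    return f"{row['mean']:.2f} ± {row['sem']:.2f}"


def render_report(report: StudyReport, format: str = "json") -> str:
    """Serialise a report deterministically as JSON or markdown.

    JSON round-trips losslessly (absent sections are explicit nulls);
    markdown includes the treatment-means table (with the "/" convention
    for zero-consumption treatments) and the predicted-curve table.
    """
    if format == "json":
        payload = {
            "no_choice": report.no_choice,
            "choice": report.choice,
            "functional_response": report.functional_response,
            "provenance": report.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=False,
                          default=_json_default)
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown format {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _render_markdown(report: StudyReport) -> str:
    lines = ["# Predation study report", ""]
    if report.no_choice is not None:
        lines += ["## No-choice test", "", "| species | stage | n | consumed |",
                  "|---|---|---|---|"]
        for row in report.no_choice["treatment_means"]:
            lines.append(
                f"| {row['species']} | {row['stage']} | {row['n']} | "
                f"{_mean_sem_cell(row)} |"
            )
        lines.append("")
        lines.append("| effect | F | df | p |")
        lines.append("|---|---|---|---|")
        for name, t in report.no_choice["anova"].items():
            lines.append(
                f"| {name} | {t['F']:.2f} | {t['df_num']},{t['df_den']} | "
                f"{t['p']:.3g} |"
            )
        lines.append("")
    else:
        lines += ["## No-choice test", "", "_section absent_", ""]
    if report.choice is not None:
        c = report.choice
        lines += [
            "## Choice test",
            "",
            f"Manly's alpha_I = {c['mean_alpha_I']:.2f} ± "
            f"{c['sem_alpha_I']:.2f} SEM; alpha_II = {c['mean_alpha_II']:.2f} "
            f"({c['n_defined']} defined replicates; variant: {c['variant']})",
            "",
        ]
    else:
        lines += ["## Choice test", "", "_section absent_", ""]
    if report.functional_response is not None:
        fr = report.functional_response
        p = fr["rogers_fit"]["params"]
        lines += [
            "## Functional response",
            "",
            f"Type determination: {fr['type_determination']['response_type']}",
            f"Rogers fit: a = {p.get('a', float('nan')):.3g} per day, "
            f"h = {p.get('h', float('nan')):.3g} days",
            f"delta AIC (q free - q0) = {fr['delta_aic']:.3f} -> {fr['conclusion']}",
            "",
            "| N0 | expected consumed |",
            "|---|---|",
        ]
        for row in fr["curve"]:
            lines.append(f"| {row['N0']:.0f} | {row['expected_consumed']:.3f} |")
        lines.append("")
    else:
        lines += ["## Functional response", "", "_section absent_", ""]
    return "\n".join(lines)
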