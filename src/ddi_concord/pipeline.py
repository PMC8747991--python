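"""End-to-end analysis pipeline and report emission.

Runs standardization, scope, completeness, consistency and agreement
analyses over an evidence matrix and writes the five report tables
(scope, completeness, consistency, pairwise tests, kappa) as TSV and JSON,
plus a run log with the configuration hash.  Output is deterministic:
identical inputs yield byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import (
    DegenerateAgreementError,
    KappaResult,
    RatingsTable,
    fleiss_kappa,
)
from .consistency import COMPONENTS, ConsistencyResult, consistency_scores
from .core import (
    ActionCategory,
    EvidenceMatrix,
    SeverityCategory,
    SeverityMap,
    validate_matrix,
)
from .formatting import format_percent
from .scope_completeness import (
    CompletenessResult,
    PairwiseTestResult,
    ScopeResult,
    assign_tiers,
    compare_completeness,
    compare_scope,
    completeness_summary,
    scope_scores,
)
from .standardize import apply_standardization

__all__ = [
    "PipelineOptions",
    "PipelineReport",
    "KAPPA_COMPONENTS",
    "ratings_table_from_matrix",
    "kappa_by_component",
    "run_pipeline",
    "write_report",
    "holm_adjust",
]

#: Components scored for inter-resource agreement.  The three flag
#: components are binary (documented / not documented among covering
#: resources); severity and course of action use the harmonized ratings;
#: overall completeness treats the 0-5 score as a categorical rating.
KAPPA_COMPONENTS = (
    "clinical_effects",
    "severity",
    "mechanism",
    "level_of_documentation",
    "course_of_action",
    "overall_completeness",
)

_FLAG_FOR_COMPONENT = {
    "mechanism": "has_mechanism",
    "clinical_effects": "has_clinical_effects",
    "level_of_documentation": "has_documentation_level",
}


def ratings_table_from_matrix(matrix: EvidenceMatrix, component: str) -> RatingsTable:
    """Per-pair categorical ratings cast by the covering resources."""
    ratings: list[list] = []
    for p in matrix.pairs:
        row: list = []
        for e in matrix.entries_for_pair(p.pair_id):
            if not e.present:
                continue
            if component in _FLAG_FOR_COMPONENT:
                row.append("documented" if getattr(e, _FLAG_FOR_COMPONENT[component]) else "absent")
            elif component == "severity":
                if e.severity_std is not SeverityCategory.UNRATED:
                    row.append(e.severity_std.value)
            elif component == "course_of_action":
                if e.action_std is not ActionCategory.UNRATED:
                    row.append(e.action_std.value)
            elif component == "overall_completeness":
                row.append(e.completeness_score)
            else:
                raise ValueError(f"unknown component '{component}'")
        ratings.append(row)
    ratings = [r for r in ratings if r]
    return RatingsTable.from_ratings(ratings)


def kappa_by_component(
    matrix: EvidenceMatrix, mode: str = "variable_raters"
) -> dict[str, KappaResult]:
    return {
        comp: fleiss_kappa(ratings_table_from_matrix(matrix, comp), mode=mode)
        for comp in KAPPA_COMPONENTS
    }


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted


@dataclass
class PipelineOptions:
    min_raters: int = 3
    alpha: float = 0.05
    kappa_mode: str = "variable_raters"
    percent_decimals: int = 2
    holm: bool = False


@dataclass
class PipelineReport:
    scope: list[ScopeResult]
    completeness: list[CompletenessResult]
    consistency: dict[str, list[ConsistencyResult]]
    pairwise: list[PairwiseTestResult]
    kappa: dict[str, KappaResult]
    tiers: list[list[str]]
    options: PipelineOptions
    violations: list[str] = field(default_factory=list)


def run_pipeline(
    matrix: EvidenceMatrix,
    smap: SeverityMap | None = None,
    options: PipelineOptions | None = None,
) -> PipelineReport:
    """Standardize then score the matrix through every analysis stage.

    ``smap=None`` skips re-standardization (the matrix must already carry
    harmonized ratings, e.g. straight from the synthetic generator).
    """
    options = options or PipelineOptions()
    violations = validate_matrix(matrix)
    if violations:
        raise ValueError(
            "matrix fails validation: " + "; ".join(violations[:5])
            + ("..." if len(violations) > 5 else "")
        )
    if smap is not None:
        matrix = apply_standardization(matrix, smap)

    scope = scope_scores(matrix, decimals=options.percent_decimals)
    completeness = completeness_summary(matrix, decimals=options.percent_decimals)

    pairwise: list[PairwiseTestResult] = []
    for a, b in itertools.combinations(matrix.resources, 2):
        pairwise.append(compare_scope(matrix, a, b))
        try:
            pairwise.append(compare_completeness(matrix, a, b))
        except ValueError:
            pass  # no commonly covered pair: comparison undefined, omitted
    if options.holm:
        for name in ("mcnemar", "wilcoxon"):
            subset = [t for t in pairwise if t.test_name == name]
            for t, p_adj in zip(subset, holm_adjust([t.p_value for t in subset])):
                t.p_value = p_adj

    consistency = {
        comp: consistency_scores(matrix, comp, min_raters=options.min_raters)
        for comp in COMPONENTS
    }
    kappa = kappa_by_component(matrix, mode=options.kappa_mode)
    tiers = assign_tiers(completeness, pairwise, alpha=options.alpha)
    return PipelineReport(
        scope=scope,
        completeness=completeness,
        consistency=consistency,
        pairwise=pairwise,
        kappa=kappa,
        tiers=tiers,
        options=options,
    )


# ---------------------------------------------------------------- reporting


def _scope_frame(report: PipelineReport) -> pd.DataFrame:
    d = report.options.percent_decimals
    return pd.DataFrame(
        [
            {
                "resource": s.resource_id,
                "n": s.n_present,
                "n_total": s.n_total,
                "percent": format_percent(s.n_present, s.n_total, d),
            }
            for s in report.scope
        ]
    )


def _completeness_frame(report: PipelineReport) -> pd.DataFrame:
    d = report.options.percent_decimals
    rows = []
    for c in report.completeness:
        row: dict = {"resource": c.resource_id, "n": c.n_present}
        if c.undefined:
            row.update({"median": "", "iqr": "undefined"})
        else:
            for flag, count in c.component_counts.items():
                row[flag.removeprefix("has_")] = (
                    f"{count} ({format_percent(count, c.n_present, d)})"
                )
            row["median"] = c.median
            row["iqr"] = f"{c.q1} to {c.q3}"
        rows.append(row)
    return pd.DataFrame(rows)


def _consistency_frame(report: PipelineReport) -> pd.DataFrame:
    d = report.options.percent_decimals
    by_resource: dict[str, dict] = {}
    for comp, results in report.consistency.items():
        for r in results:
            row = by_resource.setdefault(r.resource_id, {"resource": r.resource_id})
            row[f"{comp}_score"] = f"{r.n_consistent}/{r.n_eligible}"
            row[f"{comp}_pct"] = (
                format_percent(r.n_consistent, r.n_eligible, d) if r.n_eligible else ""
            )
    return pd.DataFrame(list(by_resource.values()))


def _pairwise_frame(report: PipelineReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "resource_a": t.resource_a,
                "resource_b": t.resource_b,
                "test": t.test_name,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n_effective": t.n_effective,
                "degenerate": t.degenerate,
            }
            for t in report.pairwise
        ]
    )


def _kappa_frame(report: PipelineReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": comp,
                "kappa": round(k.kappa, 4),
                "ci_low": round(k.ci_low, 4),
                "ci_high": round(k.ci_high, 4),
                "p_value": k.p_value,
                "band": k.band,
                "n_subjects": k.n_subjects,
            }
            for comp, k in report.kappa.items()
        ]
    )


def write_report(report: PipelineReport, outdir, run_info: dict | None = None) -> dict:
    """Write all report tables (TSV + JSON) plus a run log; atomic-ish:
    everything is rendered in memory before any file is opened."""
    frames = {
        "scope": _scope_frame(report),
        "completeness": _completeness_frame(report),
        "consistency": _consistency_frame(report),
        "pairwise_tests": _pairwise_frame(report),
        "kappa": _kappa_frame(report),
    }
    payload = {name: df.to_dict(orient="records") for name, df in frames.items()}
    payload["tiers"] = report.tiers
    options_dict = vars(report.options)
    log = {
        "package_version": __version__,
        "options": options_dict,
        "config_hash": hashlib.sha256(
            json.dumps(options_dict, sort_keys=True).encode()
        ).hexdigest(),
        **(run_info or {}),
    }

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in frames.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
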