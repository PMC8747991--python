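"""Scope and completeness scoring with paired significance tests.

*Scope* is the fraction of evaluated drug pairs for which a resource has any
interaction entry.  *Completeness* counts, per entry, how many of the five
documentation components (mechanism, clinical effects, severity, level of
documentation, course of action) the resource covers, giving a 0-5 score
summarized by median and interquartile range over the resource's present
entries.  Scope is compared between resources with McNemar's paired test,
completeness with the Wilcoxon signed-rank test, and resources are grouped
into completeness tiers by a greedy rule over the pairwise Wilcoxon results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import mcnemar_test, wilcoxon_signed_rank
from .core import COMPONENT_FLAGS, EvidenceMatrix
from .formatting import truncate_percent

__all__ = [
    "ScopeResult",
    "CompletenessResult",
    "PairwiseTestResult",
    "scope_scores",
    "completeness_summary",
    "compare_scope",
    "compare_completeness",
    "assign_tiers",
    "tukey_quartiles",
]


@dataclass
class ScopeResult:
    resource_id: str
    n_present: int
    n_total: int
    percent: float  # truncated to `decimals`


@dataclass
class CompletenessResult:
    resource_id: str
    n_present: int
    component_counts: dict[str, int]
    component_percents: dict[str, float]  # denominator = n_present, truncated
    scores: list[int]  # per-entry 0-5 overall scores, present entries only
    median: float | None
    q1: float | None
    q3: float | None
    undefined: bool = False  # True when the resource covers no pairs


@dataclass
class PairwiseTestResult:
    resource_a: str
    resource_b: str
    test_name: str  # 'mcnemar' or 'wilcoxon'
    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


def scope_scores(matrix: EvidenceMatrix, decimals: int = 2) -> list[ScopeResult]:
    """Per-resource scope: share of drug pairs with any entry."""
    if matrix.n_pairs == 0:
        raise ValueError("matrix has no drug pairs")
    results = []
    for rid in matrix.resources:
        entries = matrix.entries_for_resource(rid)
        n_present = sum(e.present for e in entries)
        results.append(
            ScopeResult(
                resource_id=rid,
                n_present=n_present,
                n_total=matrix.n_pairs,
                percent=truncate_percent(n_present, matrix.n_pairs, decimals),
            )
        )
    return results


def tukey_quartiles(values) -> tuple[float, float, float]:
    """Median and Tukey hinges (inclusive median-of-halves quartiles).

    For odd n the median element belongs to both halves.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if n % 2 == 0:
        lower, upper = x[: n // 2], x[n // 2 :]
    else:
        lower, upper = x[: n // 2 + 1], x[n // 2 :]
    return float(np.median(lower)), med, float(np.median(upper))


def completeness_summary(
    matrix: EvidenceMatrix, decimals: int = 1
) -> list[CompletenessResult]:
    """Per-resource component coverage and overall 0-5 score summary.

    Component percentages are computed over *present* entries only; a
    resource covering zero pairs yields an explicitly flagged undefined
    result rather than silent NaNs.
    """
    results = []
    for rid in matrix.resources:
        present = [e for e in matrix.entries_for_resource(rid) if e.present]
        n = len(present)
        if n == 0:
            results.append(
                CompletenessResult(
                    resource_id=rid,
                    n_present=0,
                    component_counts={flag: 0 for flag in COMPONENT_FLAGS},
                    component_percents={},
                    scores=[],
                    median=None,
                    q1=None,
                    q3=None,
                    undefined=True,
                )
            )
            continue
        counts = {
            flag: sum(getattr(e, flag) for e in present) for flag in COMPONENT_FLAGS
        }
        percents = {
            flag: truncate_percent(c, n, decimals) for flag, c in counts.items()
        }
        scores = [e.completeness_score for e in present]
        q1, med, q3 = tukey_quartiles(scores)
        results.append(
            CompletenessResult(
                resource_id=rid,
                n_present=n,
                component_counts=counts,
                component_percents=percents,
                scores=scores,
                median=med,
                q1=q1,
                q3=q3,
            )
        )
    return results


def _presence_vectors(matrix: EvidenceMatrix, rid_a: str, rid_b: str):
    pa, pb = [], []
    for p in matrix.pairs:
        pa.append(matrix.entry(p.pair_id, rid_a).present)
        pb.append(matrix.entry(p.pair_id, rid_b).present)
    return np.asarray(pa), np.asarray(pb)


def compare_scope(
    matrix: EvidenceMatrix, resource_a: str, resource_b: str, method: str = "auto"
) -> PairwiseTestResult:
    """McNemar's paired test of two resources' presence/absence patterns."""
    for rid in (resource_a, resource_b):
        if rid not in matrix.resources:
            raise ValueError(f"resource '{rid}' not in matrix")
    pa, pb = _presence_vectors(matrix, resource_a, resource_b)
    b = int(np.sum(pa & ~pb))
    c = int(np.sum(~pa & pb))
    res = mcnemar_test(b, c, method=method)
    return PairwiseTestResult(
        resource_a=resource_a,
        resource_b=resource_b,
        test_name="mcnemar",
        statistic=res.statistic,
        p_value=res.p_value,
        n_effective=b + c,
        degenerate=res.degenerate,
    )


def compare_completeness(
    matrix: EvidenceMatrix, resource_a: str, resource_b: str, method: str = "auto"
) -> PairwiseTestResult:
    """Wilcoxon signed-rank test of paired overall-completeness scores.

    Pairing is restricted to drug pairs present in *both* resources: an
    absent entry has no completeness score, and imputing one would
    manufacture data.
    """
    for rid in (resource_a, resource_b):
        if rid not in matrix.resources:
            raise ValueError(f"resource '{rid}' not in matrix")
    diffs = []
    for p in matrix.pairs:
        ea = matrix.entry(p.pair_id, resource_a)
        eb = matrix.entry(p.pair_id, resource_b)
        if ea.present and eb.present:
            diffs.append(ea.completeness_score - eb.completeness_score)
    if not diffs:
        raise ValueError(
            f"no drug pair is covered by both '{resource_a}' and '{resource_b}'"
        )
    res = wilcoxon_signed_rank(diffs, method=method)
    return PairwiseTestResult(
        resource_a=resource_a,
        resource_b=resource_b,
        test_name="wilcoxon",
        statistic=res.statistic,
        p_value=res.p_value,
        n_effective=res.n_effective,
        degenerate=res.degenerate,
    )


def assign_tiers(
    completeness: list[CompletenessResult],
    pairwise: list[PairwiseTestResult],
    alpha: float = 0.05,
) -> list[list[str]]:
    """Group resources into completeness tiers.

    Resources are ordered by (median desc, Q1 desc, Q3 desc, name asc); a
    resource joins the current tier iff its Wilcoxon p-value against every
    current member is >= ``alpha``, otherwise it starts a new tier.  This
    greedy grouping is a reporting convention, not a formal inference.
    """
    p_lookup: dict[frozenset, float] = {}
    for t in pairwise:
        if t.test_name == "wilcoxon":
            p_lookup[frozenset((t.resource_a, t.resource_b))] = t.p_value

    defined = [c for c in completeness if not c.undefined]
    ordered = sorted(
        defined, key=lambda c: (-c.median, -c.q1, -c.q3, c.resource_id)
    )
    tiers: list[list[str]] = []
    for c in ordered:
        if tiers:
            current = tiers[-1]
            try:
                joins = all(
                    p_lookup[frozenset((c.resource_id, member))] >= alpha
                    for member in current
                )
            except KeyError as exc:
                raise ValueError(f"missing pairwise Wilcoxon result: {exc}") from None
            if joins:
                current.append(c.resource_id)
                continue
        tiers.append([c.resource_id])
    return tiers
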