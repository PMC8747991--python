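"""Majority-vote consistency scoring.

For each drug pair and component (severity or course of action), the
reference standard is the *plurality* rating among the resources that cast a
non-unrated rating.  A pair contributes to scoring only when at least
``min_raters`` resources rate it (sparse coverage carries no reference) and
the plurality is untied.  A resource's consistency score for a component is
the share of its eligible ratings that match the plurality.

A ``minor`` severity rating is a special case: the evaluated sample contains
only moderate-or-worse interactions, so a resource rating a sampled pair
*minor* is never scored consistent, even when minor wins the vote.  The
minor rating still participates in the tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core import ActionCategory, EvidenceMatrix, ResourceEntry, SeverityCategory

__all__ = [
    "ConsistencyResult",
    "majority_rating",
    "consistency_scores",
    "COMPONENTS",
]

COMPONENTS = ("severity", "course_of_action")


@dataclass
class ConsistencyResult:
    resource_id: str
    component: str
    n_consistent: int
    n_eligible: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_consistent / self.n_eligible if self.n_eligible else float("nan")


def _rating(entry: ResourceEntry, component: str):
    if component == "severity":
        r = entry.severity_std
        return None if r is SeverityCategory.UNRATED else r
    if component == "course_of_action":
        r = entry.action_std
        return None if r is ActionCategory.UNRATED else r
    raise ValueError(f"unknown component '{component}'")


def majority_rating(
    matrix: EvidenceMatrix,
    pair_id: str,
    component: str,
    min_raters: int = 3,
):
    """Plurality rating for one pair, or ``None`` when no reference exists.

    Returns ``None`` when fewer than ``min_raters`` resources rate the pair
    (default 3: pairs covered by two or fewer resources are excluded) or
    when the top vote count is tied — a tie defines no reference standard.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component '{component}'")
    ratings = [
        r
        for e in matrix.entries_for_pair(pair_id)
        if (r := _rating(e, component)) is not None
    ]
    if len(ratings) < min_raters:
        return None
    tally = Counter(ratings).most_common()
    if len(tally) > 1 and tally[0][1] == tally[1][1]:
        return None
    return tally[0][0]


def consistency_scores(
    matrix: EvidenceMatrix,
    component: str,
    min_raters: int = 3,
    minor_always_inconsistent: bool = True,
) -> list[ConsistencyResult]:
    """Per-resource majority-vote consistency for one component.

    A pair is *eligible* for a resource when the resource casts a rating and
    a plurality reference exists; the rating is *consistent* when it equals
    the reference (and, for severity, is not ``minor`` — see module notes;
    set ``minor_always_inconsistent=False`` to lift that rule).
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component '{component}'")
    majorities = {
        p.pair_id: majority_rating(matrix, p.pair_id, component, min_raters)
        for p in matrix.pairs
    }
    results = []
    for rid in matrix.resources:
        n_eligible = 0
        n_consistent = 0
        for e in matrix.entries_for_resource(rid):
            rating = _rating(e, component)
            if rating is None:
                continue
            majority = majorities[e.pair_id]
            if majority is None:
                continue
            n_eligible += 1
            if rating != majority:
                continue
            if (
                minor_always_inconsistent
                and component == "severity"
                and rating is SeverityCategory.MINOR
            ):
                continue  # minor can win the vote but never scores consistent
            n_consistent += 1
        results.append(
            ConsistencyResult(
                resource_id=rid,
                component=component,
                n_consistent=n_consistent,
                n_eligible=n_eligible,
            )
        )
    return results
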