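"""Shared fixture builders.

All evidence matrices used in tests are constructed programmatically, either
through the synthetic generator or through the small builders below, which
draw drug pairs from the package's drug universe so that every fixture
passes structural validation.
"""

from __future__ import annotations

import pytest

from ddi_concord.core import (
    COMPONENT_FLAGS,
    COVID_DRUGS,
    ActionCategory,
    DrugPair,
    EvidenceMatrix,
    PSYCHOTROPIC_DRUGS,
    ResourceEntry,
    SeverityCategory,
)

_UNIVERSE = [
    (drug, cls, covid)
    for cls, drugs in PSYCHOTROPIC_DRUGS.items()
    for drug in drugs
    for covid in COVID_DRUGS
]


def make_pairs(n: int) -> list[DrugPair]:
    """First ``n`` pairs of the drug universe with stable ids."""
    assert n <= len(_UNIVERSE)
    return [
        DrugPair(f"P{i + 1:03d}", psy, covid_drug=covid, psychotropic_class=cls)
        for i, (psy, cls, covid) in enumerate(_UNIVERSE[:n])
    ]


def matrix_from_presence(presence: dict[str, list[bool]]) -> EvidenceMatrix:
    """Matrix where entry presence per resource follows the given boolean
    vectors (all five components documented for present entries)."""
    n = len(next(iter(presence.values())))
    pairs = make_pairs(n)
    entries = []
    for rid, vec in presence.items():
        assert len(vec) == n
        for pair, present in zip(pairs, vec):
            entries.append(
                ResourceEntry(
                    pair.pair_id,
                    rid,
                    present=present,
                    **{flag: present for flag in COMPONENT_FLAGS},
                )
            )
    return EvidenceMatrix(pairs, list(presence), entries)


def matrix_from_counts(n_pairs: int, counts: dict[str, int]) -> EvidenceMatrix:
    """Matrix where each resource covers its first ``counts[rid]`` pairs."""
    return matrix_from_presence(
        {rid: [i < k for i in range(n_pairs)] for rid, k in counts.items()}
    )


def matrix_from_ratings(
    severity: dict[str, list[SeverityCategory | None]],
    action: dict[str, list[ActionCategory | None]] | None = None,
) -> EvidenceMatrix:
    """Matrix with explicit harmonized ratings; ``None`` = resource does not
    cover the pair at all."""
    n = len(next(iter(severity.values())))
    pairs = make_pairs(n)
    action = action or {rid: [None] * n for rid in severity}
    entries = []
    for rid in severity:
        for i, pair in enumerate(pairs):
            sev, act = severity[rid][i], action[rid][i]
            if sev is None and act is None:
                entries.append(ResourceEntry(pair.pair_id, rid, present=False))
                continue
            entries.append(
                ResourceEntry(
                    pair.pair_id,
                    rid,
                    present=True,
                    has_severity=sev is not None,
                    has_course_of_action=act is not None,
                    severity_std=sev or SeverityCategory.UNRATED,
                    action_std=act or ActionCategory.UNRATED,
                )
            )
    return EvidenceMatrix(pairs, list(severity), entries)


@pytest.fixture
def study_matrix():
    """A standardized 181 x 6 synthetic matrix at the study marginals."""
    from ddi_concord.synthetic import generate_matrix, study_marginal_config

    return generate_matrix(study_marginal_config(seed=11))
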