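"""Scope and completeness scoring, paired tests and tier assignment."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_pairs, matrix_from_counts, matrix_from_presence
from ddi_concord.core import (
    COMPONENT_FLAGS,
    EvidenceMatrix,
    ResourceEntry,
    entry_with,
)
from ddi_concord.scope_completeness import (
    CompletenessResult,
    PairwiseTestResult,
    assign_tiers,
    compare_completeness,
    compare_scope,
    completeness_summary,
    scope_scores,
    tukey_quartiles,
)
from ddi_concord.synthetic import ResourceSpec, SyntheticConfig, generate_matrix


def _random_matrix(seed, n_pairs=20, resources=("a", "b", "c"), coverage=0.6):
    rng = np.random.default_rng(seed)
    return matrix_from_presence(
        {rid: list(rng.random(n_pairs) < coverage) for rid in resources}
    )


# -------------------------------------------------------------------- scope


def test_scope_equals_brute_force_count():
    matrix = _random_matrix(seed=1)
    results = {s.resource_id: s for s in scope_scores(matrix)}
    for rid in matrix.resources:
        expected = sum(1 for e in matrix.entries if e.resource_id == rid and e.present)
        assert results[rid].n_present == expected
        assert results[rid].n_total == 20
        assert results[rid].percent == (expected * 100 * 100 // 20) / 100


def test_scope_all_present_is_100_percent():
    matrix = matrix_from_counts(10, {"a": 10, "b": 10})
    assert all(s.percent == 100.0 for s in scope_scores(matrix))


def test_scope_percent_is_truncated():
    matrix = matrix_from_counts(181, {"pepid": 143, "drugscom": 115})
    by = {s.resource_id: s.percent for s in scope_scores(matrix, decimals=2)}
    assert by["pepid"] == 79.00
    assert by["drugscom"] == 63.53  # 63.535... truncates, never rounds up


def test_scope_invariant_under_pair_reordering():
    matrix = _random_matrix(seed=2)
    reordered = EvidenceMatrix(
        list(reversed(matrix.pairs)), matrix.resources, list(reversed(matrix.entries))
    )
    assert {(s.resource_id, s.n_present) for s in scope_scores(matrix)} == {
        (s.resource_id, s.n_present) for s in scope_scores(reordered)
    }


def test_scope_empty_matrix_rejected():
    with pytest.raises(ValueError):
        scope_scores(EvidenceMatrix([], ["a", "b"], []))


# ------------------------------------------------------------- completeness


def _matrix_with_scores(scores_by_resource: dict[str, list[int]]) -> EvidenceMatrix:
    """Each present entry documents its first `score` components."""
    n = max(len(v) for v in scores_by_resource.values())
    pairs = make_pairs(n)
    entries = []
    for rid, scores in scores_by_resource.items():
        for pair, score in zip(pairs, scores):
            flags = {flag: i < score for i, flag in enumerate(COMPONENT_FLAGS)}
            entries.append(ResourceEntry(pair.pair_id, rid, present=True, **flags))
        for pair in pairs[len(scores):]:
            entries.append(ResourceEntry(pair.pair_id, rid, present=False))
    return EvidenceMatrix(pairs, list(scores_by_resource), entries)


def test_overall_score_sums_flags_and_is_monotone():
    matrix = _matrix_with_scores({"a": [5, 3, 0], "b": [2, 2, 2]})
    entry = matrix.entry("P001", "a")
    assert entry.completeness_score == 5
    dropped = entry_with(entry, has_severity=False)
    assert dropped.completeness_score == 4


def test_median_iqr_match_sort_based_oracle():
    rng = np.random.default_rng(8)
    scores = list(rng.integers(0, 6, size=10))
    matrix = _matrix_with_scores({"a": scores, "b": [5] * 10})
    res = {c.resource_id: c for c in completeness_summary(matrix)}["a"]
    # oracle: sort, take median, Tukey hinges by explicit indexing
    x = sorted(scores)
    med = (x[4] + x[5]) / 2
    lower, upper = x[:5], x[5:]
    assert res.median == med
    assert res.q1 == lower[2]
    assert res.q3 == upper[2]
    assert sorted(res.scores) == x


def test_component_percent_denominator_is_present_entries():
    # 85 present entries, clinical effects documented for 81 of them
    pairs = make_pairs(85)
    entries = []
    for i, p in enumerate(pairs):
        flags = {flag: True for flag in COMPONENT_FLAGS}
        if i >= 81:
            flags["has_clinical_effects"] = False
        entries.append(ResourceEntry(p.pair_id, "micromedex", present=True, **flags))
        entries.append(ResourceEntry(p.pair_id, "other", present=False))
    matrix = EvidenceMatrix(pairs, ["micromedex", "other"], entries)
    res = {c.resource_id: c for c in completeness_summary(matrix, decimals=1)}
    assert res["micromedex"].component_counts["has_clinical_effects"] == 81
    assert res["micromedex"].component_percents["has_clinical_effects"] == 95.2
    assert res["other"].undefined and res["other"].median is None


def test_tukey_quartiles_odd_includes_median_in_both_halves():
    q1, med, q3 = tukey_quartiles([1, 2, 3, 4, 5])
    assert (q1, med, q3) == (2.0, 3.0, 4.0)
    q1, med, q3 = tukey_quartiles([1, 2, 3, 4, 5, 6, 7])
    assert (q1, med, q3) == (2.5, 4.0, 5.5)


# ------------------------------------------------------------- paired tests


def test_compare_scope_identical_vectors_degenerate():
    matrix = matrix_from_counts(12, {"a": 7, "b": 7})
    res = compare_scope(matrix, "a", "b")
    assert res.p_value == 1.0 and res.degenerate


def test_compare_scope_one_sided_discordance():
    # a covers 10 pairs b misses; b covers nothing a misses
    matrix = matrix_from_counts(15, {"a": 15, "b": 5})
    res = compare_scope(matrix, "a", "b")
    assert res.n_effective == 10
    assert res.p_value == pytest.approx(2 * 0.5**10)


def test_compare_scope_is_symmetric():
    matrix = _random_matrix(seed=3)
    ab = compare_scope(matrix, "a", "b")
    ba = compare_scope(matrix, "b", "a")
    assert ab.p_value == pytest.approx(ba.p_value)


def test_compare_scope_null_simulation_keeps_size():
    """Equal coverage probabilities: McNemar rejects at ~alpha rate."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_reps = 200
    for _ in range(n_reps):
        presence = {rid: list(rng.random(60) < 0.5) for rid in ("a", "b")}
        res = compare_scope(matrix_from_presence(presence), "a", "b")
        rejections += res.p_value < 0.05
    assert rejections / n_reps <= 0.10


def test_compare_completeness_identical_scores():
    matrix = _matrix_with_scores({"a": [4, 4, 5], "b": [4, 4, 5]})
    res = compare_completeness(matrix, "a", "b")
    assert res.p_value == 1.0 and res.n_effective == 0 and res.degenerate


def test_compare_completeness_exact_small_sample():
    # differences (2, 2, 2, 0): three tied positive ranks, p = 2/8
    matrix = _matrix_with_scores({"a": [5, 5, 5, 4], "b": [3, 3, 3, 4]})
    res = compare_completeness(matrix, "a", "b")
    assert res.n_effective == 3
    assert res.p_value == pytest.approx(0.25)


def test_compare_completeness_pairs_restricted_to_joint_coverage():
    matrix = _matrix_with_scores({"a": [5, 5], "b": [3, 3, 3, 3]})
    res = compare_completeness(matrix, "a", "b")
    assert res.n_effective == 2


def test_compare_completeness_no_common_pairs_is_an_error():
    pairs = make_pairs(2)
    entries = [
        ResourceEntry(pairs[0].pair_id, "a", True, has_mechanism=True),
        ResourceEntry(pairs[1].pair_id, "a", False),
        ResourceEntry(pairs[0].pair_id, "b", False),
        ResourceEntry(pairs[1].pair_id, "b", True, has_mechanism=True),
    ]
    matrix = EvidenceMatrix(pairs, ["a", "b"], entries)
    with pytest.raises(ValueError, match="covered by both"):
        compare_completeness(matrix, "a", "b")


def test_compare_completeness_detects_dominant_resource():
    """Power: strictly higher documentation probabilities are detected."""
    rng = np.random.default_rng(7)
    high = {f: 0.95 for f in COMPONENT_FLAGS}
    low = {f: 0.55 for f in COMPONENT_FLAGS}
    rejections = 0
    n_reps = 50
    for seed in range(n_reps):
        config = SyntheticConfig(
            n_pairs=181,
            resources=[
                ResourceSpec("a", 1.0, dict(high)),
                ResourceSpec("b", 1.0, dict(low)),
            ],
            seed=seed,
        )
        res = compare_completeness(generate_matrix(config), "a", "b")
        rejections += res.p_value < 0.05
    assert rejections / n_reps >= 0.9


# -------------------------------------------------------------------- tiers


def _completeness(rid, median, q1, q3):
    return CompletenessResult(
        resource_id=rid,
        n_present=10,
        component_counts={},
        component_percents={},
        scores=[],
        median=median,
        q1=q1,
        q3=q3,
    )


def _wilcoxon(a, b, p):
    return PairwiseTestResult(a, b, "wilcoxon", 0.0, p, 5)


def test_all_significant_pairs_make_singleton_tiers():
    comp = [_completeness(r, m, m, m) for r, m in [("a", 5), ("b", 4), ("c", 3)]]
    pw = [_wilcoxon(a, b, 0.001) for a, b in [("a", "b"), ("a", "c"), ("b", "c")]]
    assert assign_tiers(comp, pw) == [["a"], ["b"], ["c"]]


def test_non_significant_pair_shares_a_tier():
    comp = [_completeness(r, m, m, m) for r, m in [("a", 5), ("b", 5), ("c", 3)]]
    pw = [
        _wilcoxon("a", "b", 0.8),
        _wilcoxon("a", "c", 0.001),
        _wilcoxon("b", "c", 0.001),
    ]
    assert assign_tiers(comp, pw) == [["a", "b"], ["c"]]


def test_six_resources_with_three_median_levels_form_three_tiers():
    levels = {"a": 5, "b": 5, "c": 4, "d": 4, "e": 3, "f": 3}
    comp = [_completeness(r, m, m, m) for r, m in levels.items()]
    pw = []
    names = list(levels)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            p = 0.5 if levels[x] == levels[y] else 0.001
            pw.append(_wilcoxon(x, y, p))
    assert assign_tiers(comp, pw) == [["a", "b"], ["c", "d"], ["e", "f"]]
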