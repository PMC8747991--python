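"""Inter-rater agreement statistics.

Self-contained implementations of the three paired/multi-rater procedures
the concordance analysis rests on:

* **Fleiss kappa** for m raters assigning categorical ratings, with the
  fixed-marginal large-sample null variance (Fleiss 1971), a Wald 95% CI,
  a two-sided z-test of H0: kappa = 0, and the Landis-Koch verbal band.
* **McNemar's test** for paired binary outcomes (exact binomial and
  continuity-corrected chi-square forms).
* **Wilcoxon signed-rank test** with exact enumeration for small samples
  and a tie-corrected, continuity-corrected normal approximation otherwise.

The kappa estimator accepts per-subject rater counts, because different
compendia cover different drug pairs: subjects (pairs) rated by fewer than
two resources carry no agreement information and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RatingsTable",
    "KappaResult",
    "McNemarResult",
    "WilcoxonResult",
    "DegenerateAgreementError",
    "fleiss_kappa",
    "interpret_kappa",
    "mcnemar_test",
    "wilcoxon_signed_rank",
]


class DegenerateAgreementError(ValueError):
    """All ratings fall in a single category: chance agreement is 1."""


@dataclass
class RatingsTable:
    """Subjects x categories matrix of assignment counts.

    ``counts[i, j]`` is the number of raters assigning subject ``i`` to
    category ``j``; row sums give the per-subject rater counts ``n_i``.
    """

    counts: np.ndarray
    categories: tuple | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D subjects x categories array")
        if (self.counts < 0).any():
            raise ValueError("assignment counts must be non-negative")

    @classmethod
    def from_ratings(cls, ratings: list[list]) -> "RatingsTable":
        """Build a table from per-subject lists of categorical ratings."""
        categories = sorted({r for subject in ratings for r in subject}, key=str)
        index = {c: j for j, c in enumerate(categories)}
        counts = np.zeros((len(ratings), len(categories)))
        for i, subject in enumerate(ratings):
            for r in subject:
                counts[i, index[r]] += 1
        return cls(counts, tuple(categories))

    @property
    def rater_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    band: str
    n_subjects: int
    n_excluded: int
    mode: str


def fleiss_kappa(
    table: RatingsTable, mode: str = "variable_raters", ci_level: float = 0.95
) -> KappaResult:
    """Fleiss' chance-corrected multi-rater agreement coefficient.

    kappa = (P-bar - Pe) / (1 - Pe), where the per-subject observed
    agreement is P_i = [sum_j n_ij (n_ij - 1)] / [n_i (n_i - 1)] and the
    chance agreement Pe = sum_j p_j^2 uses the pooled category proportions
    p_j.  ``variable_raters`` evaluates P_i with each subject's own rater
    count; ``complete_case`` first restricts to subjects rated by the
    maximal rater count so all n_i are equal (the classical setting).

    The standard error is the fixed-marginal null-hypothesis form
    (evaluated at the mean rater count when counts vary), so the z-test is
    exact in spirit for H0: kappa = 0 and the CI is a Wald interval on the
    same scale.
    """
    if mode not in ("variable_raters", "complete_case"):
        raise ValueError(f"unknown mode '{mode}'")
    counts = table.counts
    n_i = counts.sum(axis=1)
    if mode == "complete_case":
        keep = n_i == n_i.max()
    else:
        keep = n_i >= 2
    n_excluded = int((~keep).sum())
    counts = counts[keep]
    n_i = n_i[keep]
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 subjects with >= 2 raters")

    p_j = counts.sum(axis=0) / n_i.sum()
    pe = float(np.sum(p_j**2))
    if pe >= 1.0:
        raise DegenerateAgreementError(
            "all ratings fall in one category; kappa is undefined"
        )
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (n_i * (n_i - 1))
    p_bar = float(np.mean(p_i))
    kappa = (p_bar - pe) / (1.0 - pe)

    # Fleiss (1971) null variance; n enters as the (mean) rater count.
    n_subj = counts.shape[0]
    n_bar = float(np.mean(n_i))
    num = pe - (2.0 * n_bar - 3.0) * pe**2 + 2.0 * (n_bar - 2.0) * float(np.sum(p_j**3))
    var = 2.0 * num / (n_subj * n_bar * (n_bar - 1.0) * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))

    z_crit = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    if se > 0:
        z = kappa / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p_value = float(kappa == 0.0)
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(kappa - z_crit * se),
        ci_high=float(kappa + z_crit * se),
        p_value=p_value,
        band=interpret_kappa(float(np.clip(kappa, -1.0, 1.0))),
        n_subjects=n_subj,
        n_excluded=n_excluded,
        mode=mode,
    )


def interpret_kappa(k: float) -> str:
    """Landis-Koch verbal agreement band for a kappa value.

    poor (<= 0.20), fair (0.21-0.40), moderate (0.41-0.60),
    substantial (0.61-0.80), almost perfect (0.81-1.00).
    """
    if not -1.0 <= k <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if k <= 0.20:
        return "poor"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def mcnemar_test(b: int, c: int, method: str = "auto") -> McNemarResult:
    """McNemar's test for paired binary outcomes.

    Only the discordant counts enter: ``b`` pairs positive under the first
    condition only, ``c`` under the second only.  ``exact`` doubles the
    binomial(b+c, 1/2) tail of min(b, c), capped at 1; ``asymptotic`` is
    the continuity-corrected chi-square (|b-c|-1)^2/(b+c) on 1 df.
    ``auto`` uses the exact form when b + c < 25.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, method="degenerate", degenerate=True)
    if method == "auto":
        method = "exact" if n < 25 else "asymptotic"
    if method == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return McNemarResult(statistic=float(k), p_value=p, method="exact")
    if method == "asymptotic":
        statistic = (abs(b - c) - 1.0) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        return McNemarResult(statistic=float(statistic), p_value=p, method="asymptotic")
    raise ValueError(f"unknown method '{method}'")


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_effective: int
    method: str
    degenerate: bool = False


def _signed_rank_ranks(abs_d: np.ndarray) -> np.ndarray:
    return stats.rankdata(abs_d, method="average")


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating the 2^n sign-assignment
    distribution of W+ over the observed (possibly tied) ranks."""
    # work on doubled ranks so tied .5 ranks become integers
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_low = float(dist[: w2 + 1].sum())
    p_high = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_signed_rank(
    differences, method: str = "auto"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Zero differences are dropped; ties among |d| share average ranks.
    ``exact`` enumerates all 2^n sign assignments (used automatically when
    n_effective <= 15); ``normal`` applies the tie-corrected normal
    approximation with a 0.5 continuity correction.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise ValueError("differences must be non-empty")
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    ranks = _signed_rank_ranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= 15 else "normal"
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    if method == "normal":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
        delta = w_plus - mu
        cc = 0.5 * np.sign(delta)
        z = (delta - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        return WilcoxonResult(w_plus, p, n, "normal")
    raise ValueError(f"unknown method '{method}'")
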