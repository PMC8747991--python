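# Methods

## The evidence matrix

The unit of analysis is a drug pair (one psychotropic drug, one COVID-19
medication) evaluated against a set of drug-information resources. For each
(pair, resource) combination there is exactly one entry recording

- `present` — whether the resource lists the interaction at all;
- five boolean documentation components: mechanism, clinical effects,
  severity, level of documentation, course of action;
- the resource's native severity and course-of-action labels plus their
  harmonized categories.

A row absent from an input CSV is materialized as `present = false`: a
missing entry is a scope miss by the resource, not missing data. The
default resource set is the six compendia `pepid, micromedex, uptodate,
drugscom, medscape, webmd` (this order fixes report layout); any ≥ 2
resources are accepted. The drug universe is a fixed list of 37
psychotropics (by ATC-style class) × 9 COVID-19 medications.

## Harmonization

Severity scales differ per resource (PEPID numeric levels, UpToDate letter
ratings, verbal labels elsewhere) and are mapped onto three informative
categories {minor, moderate, major_contraindicated}; management advice maps
onto {no_action, monitor, modify_dosage, avoid}. The shipped
`severity_map.yaml` covers the six canonical vocabularies; matching is
exact after trimming and case-folding, and an unmapped label is a hard
error — silent coercion would corrupt every downstream score. Sub-moderate
labels (PEPID 1–2, UpToDate B, verbal "Minor") map to `minor`. The sampled
interactions are moderate-or-worse by design, so `minor` is retained only
as a consistency-breaking category (below), not as part of the two-level
moderate/major risk collapse.

## Endpoints

**Scope** — n_present / n_pairs per resource. Pairwise comparison uses
McNemar's test on the paired presence vectors: with discordant counts b
(first resource only) and c (second only), the exact two-sided p-value is
the doubled binomial(b+c, ½) tail of min(b, c) capped at 1, used whenever
b+c < 25; otherwise the continuity-corrected χ² = (|b−c|−1)²/(b+c) on
1 df. b+c = 0 is reported as a degenerate test with p = 1.

**Completeness** — each present entry scores 0–5 (one point per documented
component). Component percentages use the resource's present entries as
the denominator; a resource covering zero pairs is flagged undefined
rather than emitting NaNs. Overall scores are summarized by median and
Tukey hinges (inclusive median-of-halves quartiles; no universal quartile
convention exists for small ordinal samples, and the hinge rule is the one
the tests' oracles also use). Pairwise comparison uses the Wilcoxon
signed-rank test restricted to pairs present in *both* resources (an
absent entry has no score; imputation is refused): zeros dropped, average
ranks for ties, exact 2^n enumeration for n ≤ 15, otherwise a
tie-corrected normal approximation with 0.5 continuity correction.
Resources are then grouped into completeness tiers: ordered by (median,
Q1, Q3, name) descending, a resource joins the current tier iff its
Wilcoxon p against every member is ≥ α (default 0.05), else it opens a
new tier. This greedy grouping is a reporting convention, not an
inferential procedure, and is sensitive to α. The 15 pairwise p-values
are uncorrected by default; a Holm step-down option exists.

**Consistency** — per pair and component, the reference standard is the
strict plurality of the non-unrated ratings cast by the resources. No
reference exists (pair excluded) when fewer than `min_raters` (default 3)
resources rate the pair or the top vote count is tied — a tie defines no
standard, and scoring all raters inconsistent against a tie would
penalize coverage. Plurality rather than absolute majority is used because
different resources cover different pairs; an absolute-majority reading
is available by raising `min_raters`. A resource's score for a component
is n_consistent / n_eligible over its rated, reference-bearing pairs. A
`minor` severity rating participates in the vote tally but is never scored
consistent (the evaluated sample excludes minor-severity interactions, so
such a rating contradicts the inclusion standard even when other
resources echo it); the rule is switchable
(`minor_always_inconsistent=False`).

**Agreement** — Fleiss' kappa per component: binary documented/absent
ratings for mechanism, clinical effects and level of documentation (cast
by resources with an entry), the harmonized categories for severity and
course of action (cast by resources with a rating), and the 0–5 score
treated as categorical for overall completeness. With per-subject rater
counts nᵢ, Pᵢ = Σⱼ nᵢⱼ(nᵢⱼ−1)/nᵢ(nᵢ−1), P̄ₑ = Σⱼ pⱼ² from the pooled
category proportions, κ = (P̄ − P̄ₑ)/(1 − P̄ₑ). Because resources cover
different pairs, the default `variable_raters` mode keeps every subject
with nᵢ ≥ 2 (singletons are excluded and counted); `complete_case`
restricts to subjects rated by the maximal rater count, the classical
equal-n setting. The standard error is the Fleiss (1971) fixed-marginal
null-hypothesis variance, evaluated at the mean rater count when counts
vary; the 95% CI is Wald (κ ± 1.96·SE) on the same scale and the p-value a
two-sided z-test of κ = 0. This variance is exact only under H₀ and equal
n — adequate for the null test the analysis reports, but the CI should be
read as approximate. Verbal interpretation uses the Landis–Koch bands
with right-closed boundaries: κ ≤ 0.20 poor, (0.20, 0.40] fair,
(0.40, 0.60] moderate, (0.60, 0.80] substantial, (0.80, 1.00] almost
perfect.

## Percentage formatting

Report percentages are truncated, not rounded, to the requested decimals
(115/181 → 63.53, 81/85 → 95.2), implemented in integer arithmetic so the
truncation is exact. This is the formatting convention the comparison
tables follow; it is exposed as `--percent-decimals`.

## Synthetic generator

The generator emulates the study conditions: 181 pairs sampled without
replacement from the 333-pair drug universe, and per resource an
independent Bernoulli coverage draw, per-component documentation draws
conditional on presence, and ratings from a latent-severity confusion
model. Defaults:

- coverage and documentation probabilities equal the observed six-resource
  marginals (`study_marginal_config`), e.g. PEPID coverage 143/181 with
  clinical effects documented at 114/143;
- latent severity distribution (minor, moderate, major) =
  (0.05, 0.55, 0.40) — a convention loosely reflecting a moderate-severe
  sample, not an observed quantity;
- agreement α = 0.8: with probability α a resource reports the latent
  category, otherwise it draws uniformly from the *full* category set, so
  α = 0 yields ratings independent of the latent state (κ ≈ 0), α = 1 the
  noiseless limit (κ = 1), and estimated κ is monotone in α over the whole
  range. Perturbing only to the *other* categories was rejected: it makes
  raters agree on avoiding the latent category, so κ(0) ≈ +0.2 exceeds
  κ(0.3) and the agreement parameter is no longer monotonically
  identifiable. The latent action is the deterministic map minor →
  no_action, moderate → monitor, major → avoid, perturbed with the same α
  over the four actions.

Randomness uses one root `SeedSequence` with spawned substreams for pair
sampling, latent severities, and each resource, so adding a resource does
not perturb the draws of the others and every run is reproducible from one
seed.

What the generator does *not* emulate: between-resource dependence of
coverage (real compendia overlap non-randomly; printed marginals do not
identify the joint distribution, so independence is assumed),
per-resource agreement heterogeneity (one scalar α), drift of vocabularies
over time, and any association between drug classes and severity. Passing
tests therefore demonstrate correctness of the scoring and statistics
under the marginal structure, not fidelity to any real compendium's joint
behavior; with six independent raters at α = 0.8 the plurality reference
is cleaner than real majority votes, so synthetic consistency scores run
higher than observed ones.

## Numerical and degenerate-input choices

- Exact McNemar/Wilcoxon switch points (b+c < 25, n ≤ 15) balance
  exactness against enumeration cost; the Wilcoxon exact distribution is
  built by dynamic programming over doubled ranks so tied (half-integer)
  ranks stay exact.
- Degenerate cases are flagged, not hidden: no discordance → McNemar
  p = 1; all-zero differences → Wilcoxon p = 1 with n_effective = 0; all
  ratings in one category → kappa undefined, raised as an error (CLI exit
  code 4).
- Tier assignment breaks median ties by Q1, then Q3, then name, making
  report order deterministic.
- The analysis sizes used by the test-suite and the reproduction script —
  181 pairs × 6 resources, 20–50 seeds per Monte-Carlo sweep, pooled
  ≥ 5000 draws for marginal-convergence checks — were chosen as the
  smallest sizes at which the binomial standard errors are comfortably
  inside the asserted tolerances.

## Known limitations

- The tier rule and the consistency eligibility rule are declared
  reconstructions of reporting conventions that the comparison literature
  leaves under-specified; exact published denominators are not
  reproduction targets.
- Fleiss' kappa with variable rater counts has no exact small-sample
  variance here; the reported SE/CI are large-sample null-based.
- No weighting of resources, no weighted kappa, no Krippendorff alpha.
- Drug names are opaque labels; no RxNorm/ATC normalization is attempted.
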