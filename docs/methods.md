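# Methods

This note records the statistical definitions the package implements, the
conventions chosen where the field's practice varies, and what the synthetic
cohort generator does and does not emulate.

## Data model

A diet table is one row per fish: group label, total length (cm), body mass
(g), gut-content mass (mg), and biomass (mg) per food category. A fish with
all-zero biomass is *empty*; empty fish stay in the file model but are
excluded from every composition-based statistic (%FO denominators,
compositions, multivariate analyses), following the universal practice of
dropping empty guts before diet analysis. Masses are mg throughout except
body mass (g); the fullness coefficient converts internally.

Diet composition p admits two conventions, both implemented and exposed as
a `basis` parameter everywhere downstream:

* `per_fish` (default): mean over fish of each fish's own biomass
  proportions. This is the convention behind per-fish mean ± SD summary
  tables, so it is the default.
* `pooled`: group-summed biomass, normalised. Ration-heavy fish weigh more.

The two coincide exactly when all fish have proportionally identical diets.

## Importance metrics

%FO_i = 100 × (non-empty fish containing i) / (non-empty fish in group).
%W_i is the composition in percent; the summary also reports the SD and
CV = 100·SD/mean of the per-fish proportions (CV is reported as missing,
not 0 or ∞, when the mean is 0). IRI uses the two-term biomass form
IRI_i = %FO_i × %W_i — numeric prey abundance (%N) is not part of the data
model, so the three-term form is deliberately not implemented — and
%IRI normalises IRI to sum to 100. The %W basis used inside IRI follows the
`basis` parameter; published %IRI values computed with pooled %W can be
reproduced by choosing `pooled`.

Gut-content mass is compared between groups with the Welch
unequal-variance t and Welch–Satterthwaite df (callable on raw vectors or
on printed summary statistics). The pooled-variance form is intentionally
not offered: on the reference study's printed summaries only the Welch form
reproduces the printed statistic.

## Niche breadth, overlap, uncertainty

Breadth indices of a composition: S (count of p_i > 0), D = Σp², B = 1/D,
H′ = −Σ p log p, Ba = (B−1)/(S−1), J′ = H′/log S, with 0·log 0 := 0. Ba and
J′ are undefined (NaN) at S = 1. The Shannon log base is a parameter
defaulting to natural log: base 10 caps H′ at log₁₀ 25 ≈ 1.40 for 25
categories, below published weatherfish values (2.38, 2.52), so those were
evidently natural-log despite the base-10 notation in common formula
listings; J′ is base-invariant either way.

Overlap: Schoener α = 1 − ½Σ|p_ix − p_iy| and Horn
Ro = [Σ(p+q)log(p+q) − Σp log p − Σq log q]/(2 log 2), clipped to [0, 1]
against rounding. Both are 1 for identical and 0 for disjoint diets; Ro is
log-base invariant.

Uncertainty uses the delete-one-fish jackknife — the fish is the only
replicated unit. Pseudovalues θ_i = nθ̂ − (n−1)θ̂₍₋ᵢ₎, estimate = mean(θ_i),
SE = sd(θ_i)/√n. For overlap, deletion runs over the combined two-group
sample with both compositions recomputed. Jackknifed nonlinear statistics
need not satisfy algebraic identities of their plug-in forms (e.g.
jack(B) ≠ 1/jack(D)); this is expected behaviour.

The two-group comparison of a breadth index is a label-permutation test:
observed |Δindex|, null from random reassignment of non-empty fish to
groups with sizes preserved, p = (count ≥ observed + 1)/(n_perm + 1)
(add-one convention, so p > 0 and the test is exact-level). Permutations on
which the index is undefined are redrawn up to a cap, with a warning. The
default n_perm is 9999; the floor is 99.

## Community comparison

Bray–Curtis d(x,y) = Σ|x_c − y_c| / Σ(x_c + y_c) between fish, by default
on per-fish proportions (diet *composition*; a `raw` option compares
absolute ration). ANOSIM uses Clarke's R = (r̄_between − r̄_within) /
(N(N−1)/4) on tie-averaged ranks of the condensed distances; R is invariant
to monotone transforms of d. The permutation p follows the add-one
convention; for two groups with C(N, n₁) ≤ n_perm the null is enumerated
exhaustively and p is the exact tail proportion (identity included). The
permutation RNG is seeded and the seed recorded in the output.

SIMPER averages each category's share |x_c − y_c|/Σ(x+y) of the pairwise
dissimilarity over all between-group pairs; the per-category averages sum
exactly to the mean between-group dissimilarity (internal consistency is
tested at 1e-10), and contributions are reported in percent with a
cumulative column. A helper rebuilds contribution/cumulative percentages
from a published (possibly truncated) average-dissimilarity column given
the overall dissimilarity implied by its printed cumulative endpoint.

## Clustering and discriminant analysis

Guild aggregation sums biomass within habitat guild (BE, EP, EP/BE, PL, DE)
per fish, conserving per-fish totals exactly; categories outside the five
guilds go to an explicit `others` bucket (strict mode refuses unmapped
categories). The packaged weatherfish map assigns 24 categories to the five
guilds and leaves its composite "others" category in the bucket, matching
how the guild-level analyses of the reference study treat it.

Clustering: Ward minimum-variance linkage on Euclidean distances between
per-fish guild percentage profiles (untransformed — the clustering view is
of raw diet amounts), via the Lance–Williams recursion; heights are
reported as within-cluster variance increments ΔESS = h²/2, the convention
that makes them comparable across software. The tree is cut at two
clusters, clusters take the majority maturity label, and misclassified
counts per group are reported. Identical-profile degeneracy yields a
flagged, deterministic split. Empty fish are excluded by default
(`include_empty` adds them as all-zero profiles).

DFA: guild percentages are arcsine-√ transformed (arcsin√(pct/100),
variance-stabilising for proportions), and the two-group canonical
eigenproblem gives the single eigenvalue λ₁ = (n₁n₂/N)·d′W⁻¹d of W⁻¹B,
hence Wilks' Λ = 1/(1+λ₁), F = ((1−Λ)/Λ)(N−p−1)/p on df (p, N−p−1) — for
two groups this F is exactly the Hotelling T² F (tested to 1e-8).
Per-variable F-to-remove = (Λ₋ᵥ/Λ − 1)(N−p−1) on df (1, N−p−1); structure
correlations are Pearson correlations of each transformed variable with the
canonical scores (axis signed so the alphabetically-second group scores
high). Classification is the linear discriminant rule with pooled
covariance and group-size-proportional priors, reported as a resubstitution
table and percent correct. The five named guild variables enter; the
`others` bucket is excluded. A singular within-group scatter (constant or
collinear variable) is rejected with a pointer to remove variables.

## Synthetic cohort generator

Per fish: empty flag ~ Bernoulli(empty_prob); if non-empty, a presence mask
~ Bernoulli(occurrence_prob_c) per category (redrawn if all-absent), a
composition ~ Dirichlet(κ · base weights restricted to present categories),
gut mass ~ lognormal, biomass = composition × gut mass. Presence and
composition are drawn independently and the restricted composition is
renormalised — a deliberate modelling simplification; no within-fish
covariance beyond the Dirichlet and the shared mask is attempted.

Because renormalisation after presence-thinning inflates the marginal mean
share of frequently-present categories, the base weights are calibrated by
a deterministic fixed point (Monte Carlo over presence masks with a fixed
internal seed; the conditional Dirichlet mean is κ-free) so that the
generator's expected per-fish mean composition equals the target
`mean_composition`. Targets below 0.1% with non-zero occurrence are floored
at 0.001 before calibration, and Dirichlet components at α = 0.01 against
gamma underflow; both floors are far below every tested tolerance.

Defaults are the study conditions of the reference weatherfish dataset:
n = 33/26, 25 categories with the published group mean %W (normalised; the
printed juvenile column sums to 99.11%) and %FO/100 occurrence
probabilities, empty-gut probability 5/64, lognormal gut mass
moment-matched to 73.98 ± 67.04 mg (juvenile) and 142.65 ± 100.62 mg
(mature), lengths 11.4 ± 0.71 vs 17.3 ± 1.0 cm. Body mass is dressed with a
cubic length-weight relation W = 0.0042·TL³ g with 10% lognormal scatter,
chosen so the implied fullness coefficients sit near the published group
means (≈1.1% juvenile, ≈0.7% mature); it affects only metadata, not diets.
The Dirichlet concentration defaults to κ = 3, which makes per-category CVs
span the published range (≈55–575%); single-κ matching of every printed CV
is impossible since the implied κ varies by an order of magnitude across
categories. The published sample-size ambiguity in the reference summaries
(juvenile %FO grid implying n = 33 in the category block but 32 in the
guild block) is resolved as 33/26.

What the generator does *not* emulate: fish growth or length-diet
covariance within a group, seasonality, prey-encounter mechanics, and
between-category correlations beyond closure. Passing recovery tests
therefore show the pipeline is consistent for compositional, overdispersed,
presence-thinned data — not that real gut contents follow this generative
model.

## Problem sizes and numerical choices in the test suite

Type-I error of the permutation breadth test is estimated on 500 simulated
null cohorts of 12 + 12 fish with 199 permutations each (the add-one
convention makes the achieved level exactly 0.05 at those counts);
generator recovery is checked at n = 200/group averaged over 50 replicate
cohorts, estimating the expectation to ≈0.3 points so the ±2-point check
is far from its noise floor; ANOSIM's sampled p is compared with the
exhaustive p on a 4+4 set at 4999 draws within binomial error; Ward heights
are compared with a first-principles greedy ESS oracle up to 7 fish.
Composition sums are validated to 1e-9; internal consistency identities to
1e-10. All stochastic tests fix seeds; permutation outputs record theirs.

## Known limitations

* ANOSIM exhaustive enumeration is implemented for two groups only;
  k-group problems always use sampling.
* Only two-group DFA (one canonical axis) is provided — the intended use
  is juvenile vs mature contrasts; no quadratic discriminants, no
  cross-validated error rates (resubstitution matches the convention of
  the reference analyses and is optimistic by construction).
* No Pianka/Morisita overlap variants or Hurlbert standardisation.
* The permutation comparison of breadth indices is a label-permutation
  test; no bootstrap CI variant is offered.
* Numeric prey abundance (%N) data are out of scope by design.
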