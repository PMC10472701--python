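# Methods

This note documents the models, conventions and numerical choices behind
`classnet`, and what the simulation-based tests do and do not establish.

## The data model

The unit of network computation is the classroom: a roster of students and a
directed graph of best-friend nominations (no self-ties, no duplicates, no
cap on nominations, ties only within the roster). Students who made or
received no nominations stay on the roster as isolates; excluding them would
bias density denominators. Attribute values may be missing on input; metric
computation stays total and missingness is resolved by listwise deletion in
each regression model, so bivariate and multivariate sample sizes may differ
(`n_used` is always reported).

## Egocentric metric conventions

Several of the nine variables admit more than one defensible reading; the
package fixes one convention each, exposes alternatives behind flags, and
writes every choice into the run manifest.

- **Friend set** (reciprocity, homophily, friends' AP): the OUT-neighbors —
  the classmates the ego nominated — because all three definitions are
  phrased from the nominator's viewpoint. `friend_set="mutual"` restricts to
  reciprocated ties.
- **Homophily sign**: the statistic is the mean absolute AP difference
  between ego and each nominated friend, *negated*, so that larger values
  mean greater academic similarity and regression coefficients read
  "similarity is associated with …". The raw positive value is also emitted
  (`homophily_raw`). Note the statistic is on the AP scale (typical
  magnitude a few tenths of a grade point for ~N(7.2, 0.7) grades); field
  reports of per-sample homophily an order of magnitude smaller imply an
  additional, usually unstated normalization that this package deliberately
  does not guess at.
- **Density denominator**: roster − 1, i.e. the ego's potential ties to all
  classmates, ×100. This is the reading under which egocentric density at
  mean network size ≈ 12.5 in classrooms of 25–30 lands near 50%.
  Alter–alter density (the classical ego-network density) would not involve
  network size at all.
- **Triangles**: counted on the symmetrized graph (an unordered pair {a, b}
  closes a triangle with the ego if all three dyads carry a tie in at least
  one direction). A directed transitive-triad variant
  (`triangle_variant="directed"`) counts ordered triples (i, j, k) with
  edges i→j, j→k, i→k and the ego in any seat; directed counting triples
  each symmetric closure and is the likelier convention behind published
  triad means near 90 at these densities.
- **Betweenness**: directed, unnormalized, with fractional credit across
  tied geodesics (Freeman/Brandes, the default of classic sociometry
  software). Pairs with no connecting path contribute zero.

Implementation uses networkx (Brandes betweenness, triangle counts); the
test suite verifies both against independent brute-force enumerations —
exhaustively for all digraphs on ≤ 4 nodes and on 500 random digraphs with
≤ 8 nodes.

## The two-step transform

Step 1 replaces observed values by fractional ranks r/(n+1) with mean ranks
for ties (missing values excluded and reinserted); step 2 maps ranks through
Φ⁻¹ and rescales to a target mean/SD, by default the input's own moments
(SD with ddof = 1). The transform is monotone, maps ties to ties, and is
idempotent up to moment matching (ranks are unchanged by a second pass). It
is fit once on the pooled analysis sample, not per classroom or per sex, so
stratified models see a common scale; per-stratum refitting would change
coefficients between strata for reasons unrelated to the association of
interest. The r/(n+1) offset is the published two-step recipe; Blom-type
offsets would differ only in the extreme ranks.

Normality is assessed by the one-sample KS statistic against a normal with
estimated mean/SD — the Lilliefors convention, matching what standard
statistical packages report as a K-S test. At least 8 non-missing values are
required; zero-spread input is rejected as degenerate.

## The regression stage

Descriptives use the equal-variance Student's t (a Welch flag exists) and
Pearson's chi-square without continuity correction. Regressions are OLS with
Wald t-based 95% CIs. Categorical predictors expand to indicator contrasts
with fixed reference levels (rural location, "other" family structure); if a
stratum happens to contain no observation at the reference level, the first
sorted level is substituted with a warning. Cohen's f² = R²/(1−R²) is
computed from the simple model's R² for bivariate rows and from the full
model's R² (against the empty model) for the multivariate model — one f² per
joint model. A perfect fit returns the documented sentinel `F2_CAP = 1e6`.
Screening retains predictors with any contrast's bivariate p strictly below
α = 0.25; multi-level categoricals enter or leave whole, and the screened
set may differ between sexes. No multiple-testing correction is applied, and
classroom clustering is ignored in the default standard errors — both
deliberate mirrors of common practice in this literature and known
limitations; `cov_type="cluster"` provides cluster-robust errors for
sensitivity analyses.

## The synthetic cohort generator

Defaults are the study conditions: 32 classrooms of 20–31 students
(E[n] ≈ 816), 52.7% girls, 79% urban (assigned per classroom, since location
is a school attribute), family structure 66.8/25.3/8.0%
(nuclear/single-parent/other), ages uniform on 12–17, AP truncated-normal
N(7.2, 0.7²) on [1, 10], Apgar ≈ N(14.1, 4.1) rounded and clamped to [0, 25],
FAS ≈ N(1.85, 1.6) rounded and clamped to [0, 8].

**Ties.** Pass 1 assigns each ordered pair an independent tie with
probability logistic(−0.45 − 0.5·|ΔAP| + 0.4·same-sex); pass 2 upgrades each
absent tie whose reverse exists with the same logit plus a reciprocity
offset (default −2.4). The intercept and offset were calibrated once to the
target marginals: mean out-degree ≈ 8.9 and egocentric reciprocity ≈ 0.40.
The offset is *negative* because the upgrade pass acts exactly on asymmetric
dyads, so at offset 0 reciprocity would reach ≈ 0.6 at this density; a
positive offset still increases reciprocation monotonically, which the test
suite checks. Independent dyads keep generation O(n²) and bit-reproducible
for a fixed seed; clustering/transitivity arises only incidentally, which is
the main respect in which these networks are simpler than real classrooms.

**Peer effect.** In a cross-section, peer influence and peer selection are
observationally equivalent; what a pipeline can be validated against is the
*estimand* — the population regression slope of AP on the mean AP of
nominated friends. `influence_mode="environment"` (default) therefore
defines `peer_effect_beta` as that slope and realizes it through fixed
classroom academic environments: classroom c receives the effect
θ_c = √T·z_c, where z_c are evenly spaced standard-normal quantiles
standardized with non-isolate counts as weights, and

  T = β/(1−β) · noise_sd² · E[1/d_i]

with the expectation over realized out-degrees of non-isolates. Each
non-isolate's AP is redrawn as ap_mean + θ_c + e_i with e_i ~ N(0,
noise_sd); isolates keep their attribute-model AP. Since
Cov(AP, friends' mean AP) = T and Var(friends' mean AP) = T + noise_sd²·E[1/d],
the population slope equals β exactly, and because the environments form a
fixed ladder rather than fresh draws, replicate-to-replicate dispersion of
the estimate stays at its nominal OLS level and confidence-interval coverage
is approximately nominal. This is what the parameter-recovery test
demonstrates: 200 replicate cohorts at β = 0.8, noise_sd = 0.5 yield a mean
multivariate friends'-AP coefficient within ±0.05 of 0.8 with ≥ 90% CI
coverage. The small residual downward bias (≈ 0.02) comes from the rank
transform and from co-screened covariates such as homophily that are
themselves functions of AP.

`influence_mode="assimilation"` instead performs a literal one-shot update
AP′ = α + β·(pre-update mean AP of out-neighbors) + e, with α preserving the
marginal mean (overridable). It is mechanistically transparent but the
observable regression uses friends' *post-update* AP, a noisy proxy for the
generation regressor, so the recovered slope is attenuated well below β
(≈ 0.3 at these densities) — classical errors-in-variables. It is retained
for experiments about that very phenomenon, not for recovery testing.

A caveat on realism: in environment mode the final AP is an outcome model
(environment + noise), so AP-homophily written into tie formation acts on
the pre-influence AP draw and is largely invisible in the final data; use
`influence_mode="none"` to study pure selection effects.

**Seeding.** One seed drives three SeedSequence-spawned streams
(attributes, ties, influence); classrooms are processed in sorted order, so
every run is bit-identical given the seed.

## What the simulations do and do not show

Passing tests establish that the pipeline's arithmetic and inference behave
correctly *under the generator's assumptions*: independent dyads, Gaussian
attribute noise, a linear peer-effect estimand, no unmodeled school-level
confounding beyond the classroom environments. They do not establish that
real adolescent grade data satisfy those assumptions, nor do they reproduce
any particular published coefficient — observed cohorts have triadic
closure, measurement error in grades, and informative missingness that this
generator deliberately omits.

## Problem sizes and numerical notes

Acceptance-level experiments use 200 replicate cohorts (~800 students each)
for recovery, 1000 replicates of n = 800 for screening calibration, n = 500
samples for transform normality, exhaustive oracle comparison on all ≤ 4-node
digraphs plus 500 random ≤ 8-node digraphs, and 200 random classrooms for
round-trip identity; the standalone acceptance script uses lighter replicate
counts chosen to keep a full run in the minutes range. Betweenness
comparisons use an absolute tolerance of 1e-9; moment matching in the
transform is exact to 1e-9; f² identities are checked to 1e-12. Degenerate
inputs (constant predictors, zero-spread samples, rosters under 3, rank
deficiency) raise typed errors rather than propagating NaNs.
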