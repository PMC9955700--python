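# Methods

## Scope and data model

The pipeline analyses a cross-sectional twin-family cohort: child/adolescent
twin pairs with known zygosity, the first (oldest) sibling, and both
biological parents. Every questionnaire indicator is tristate —
case / control / missing — and an unanswered item is never coerced to
control; classifiers return missing whenever a required item is absent.
Disease-related or severe-injury-related back pain is *excluded from
analysis* rather than recoded or deleted: the record keeps an
`lbp_excluded` / `tlbp_excluded` flag and drops out of denominators, pair
tallies, and model frames, which keeps every reported N auditable
(loaded = analysed + excluded). Pain attributed to minor injury does not
exclude.

The body map has 21 site codes partitioned into 9 regions (lower limbs,
upper limbs, chest, abdomen, head, neck, lower/middle/upper back).
Thoracolumbar back pain means pain in the lower and/or middle back region.
The lower-limb constituents (foot, ankle, shin, calf, thigh, hip) follow the
published region definition; the remaining site-level allocation is this
package's own fixed, versioned stand-in (`twinpain-sites-1`, exported as a
JSON sidecar), because the source instrument's full 21-site partition is not
enumerated anywhere we can cite. Analyses only consume regions, so any
relabelling of sites within a region is observationally equivalent.

One scale discrepancy is carried as declared rather than resolved: the
sensory-sensitivity scale sums seven 5-point items, which arithmetically
yields 7–35, but its declared range is 5–35; the implementation validates
items per-item (1–5) and the total against the declared range.

## Twin similarity

For a binary trait, complete same-zygosity pairs are tallied as
(Nc, Nd, N00). Three measures are computed:

* **Casewise concordance** `C = 2Nc/(2Nc+Nd)` — the probability that the
  co-twin of an affected twin is affected — with variance
  `4·Nc·Nd·(Nc+Nd)/(2Nc+Nd)^4` and a Wald interval truncated to [0, 1].
* **Phi correlation** and **pairwise odds ratio** on the *double-entered*
  table `(a,b,c,d) = (2Nc, Nd, Nd, 2N00)`; the OR uses a Woolf interval
  (`Var(log OR) = 1/a+1/b+1/c+1/d`). Double entry is the tabulation
  convention precisely because it reproduces the published estimates from
  the published tallies; that back-validation is frozen into the test suite.
* **MZ–DZ difference tests**: z = (g(MZ) − g(DZ)) / √(Var_MZ + Var_DZ) with
  g = identity for C, Fisher z for phi, log for the OR; the one-sided
  p-value is the upper tail (alternative: MZ more similar), the two-sided
  p doubles the smaller tail.

Numerical conventions: report tables round half-up — two decimals for
proportions and correlations, three significant figures for odds ratios —
while internal values keep full precision. A zero discordant or
double-entered cell yields an explicit undefined-estimate error; a
Haldane–Anscombe +0.5 correction is available but off by default, because a
silent correction distorts small simulations. The phi interval uses Fisher z
with n = number of pairs (variance 1/(n−3)).

Two published-value caveats are documented rather than forced: (i) the
source's correlation intervals and correlation-difference p-values follow an
unstated method that Fisher z on pair counts does not reproduce, so no exact
test asserts them; (ii) the variance formula above reproduces every printed
concordance interval except one lower bound (0.13 here vs 0.12 printed,
treated as rounding and tested at ±0.01), and gives a one-sided TLBP
concordance p of 0.0053, consistent with the printed two-sided 0.011 but one
rounding unit below the separately printed one-sided 0.006.

## Family analysis

One twin per complete pair is selected with a seeded generator (the seed is
mandatory and echoed into output metadata). The selected children's trait is
regressed on the same trait in a given relative by ordinary logistic
regression; the analysis is repeated with the co-twins as index children;
and the two log odds ratios are combined by inverse-variance weighting
(weights 1/Var, combined variance 1/Σw). This uses both twins' information
without double-counting families; a single-arm mode is available as a flag
since either reading of the source procedure is defensible. Covariates (age,
sex) follow an adjust-if-significant policy: fit with both, drop those with
Wald p ≥ 0.05, refit, and log the decision. Separation or a constant
predictor produces a flagged non-converged result, never a silent estimate.

## Clustered association models

Offspring (twins + first siblings) analyses use logistic regression with one
Gaussian random intercept per *family* (the source does not state per-pair
vs per-family clustering when twins and siblings are pooled; per-family is
this package's default and only implemented choice). The marginal likelihood
is maximized by adaptive Gauss–Hermite quadrature: each cluster's integrand
is centered at its posterior mode (Newton steps) and scaled by the local
curvature, with 15 nodes by default and an L-BFGS-B tolerance of 1e-6 on the
log-likelihood; Wald covariance comes from the numerical Hessian at the
optimum. At `fix_sigma=0` the model reduces exactly to ordinary logistic
regression. The fitter is cross-checked in the test suite against lme4's
`glmer(nAGQ=15)` on identical data (agreement to ~1e-3) — the R fit is an
independent oracle only, never the implementation.

Parent analyses use ordinary logistic regression and are *not* age-adjusted
by default (the source states age adjustment only for offspring); offspring
models always include age, and sex enters only when significant.

Association tables fit one univariate model per predictor plus one joint
multivariable model containing all listed predictors simultaneously (no
stepwise selection); the retention flag marks multivariate p < 0.05. For
region predictors the outcome's own region(s) are removed — lower back for
`lbp_life`; lower and middle back for `tlbp_current` — both from the
predictor list and from the multiple-sites indicator (≥2 positive
non-outcome regions). Binary predictors with fewer than 10 cases among
analysed rows are dropped with a logged reason. No multiple-testing
correction is applied by default, matching the source presentation; a
Bonferroni switch exists. The lifetime-LBP → current-TLBP fit is exposed as
a positive-control diagnostic of pipeline wiring.

## Synthetic cohort generator

Binary traits follow a liability-threshold model: trait present when a
standard-normal liability exceeds Φ⁻¹(1 − prevalence). Familial structure
uses a single (a², c², e²) decomposition shared across traits: co-twin
liability correlation a²+c² (MZ) or a²/2+c² (DZ), twin–sibling a²/2+c²,
parent–offspring a²/2, parents uncorrelated (no dominance, no assortative
mating). Cross-trait dependence within a person uses one shared factor
(trait s and t correlate γ_s·γ_t) plus optional planted pairwise
correlations; the full family draw is multivariate normal with covariance
kron(R_family, C_traits), eigenvalue-checked and rejected if not PSD.

Age enters through the threshold: the thresholded score is
(L + β·(age − role mean)) / √(1 + β²·sd²) with β = log(OR per year)/1.7
(the standard probit–logit bridge), so the marginal prevalence stays exactly
at target. Because co-twins share their exact age, the shared-age term
β²sd²/(1+β²sd²) adds to the effective co-twin correlation, and the
closed-form oracle `theoretical_similarity` (bivariate-normal orthant
probabilities) accounts for it. Parents get their own higher thresholds
rather than an age extrapolation, since adult prevalences (~40%) far exceed
any age-extrapolated child value.

Defaults are fixed once to the study conditions: 651 families, 42.2% MZ,
sibling present in 64.5% and mother/father in 98.3%/86.9% of families
(participation margins implied by the published table Ns); offspring
prevalences 12.1% (lifetime LBP) and 9.6% (current TLBP), parent prevalences
42.0%/39.9% and 26.6%/23.1%; age effects OR 1.24/yr (LBP) and 1.15/yr
(TLBP) for offspring; ages drawn from the published role-specific
mean/SD/range. Variance shares default to a² = 0.55, c² = 0.10 — a
calibration choice giving MZ/DZ similarity of the observed order; the
generator makes no claim to estimate heritability. The LBP–TLBP within-person
correlation is solved by root finding so the population cross-trait OR
equals the published positive-control magnitude (17.7); condition
prevalences and the γ = 0.45 factor loading (0.20 for iron-deficiency
history, 0.30 for the score latents) are realistic choices producing
cross-trait ORs in the 2–3 range. Scale scores are affine transforms of
their latents, rounded and clipped to the declared ranges. Optional MCAR
missingness (default 0) exercises pair-exclusion logic; a serious-disease
rate (default 0) exercises the exclusion filter.

What the generator does *not* emulate: non-random volunteer participation,
recall bias, shared-environment differences between MZ and DZ pairs
(equal-environments is assumed, as in the twin design itself), dominance,
assortative mating, sex-specific prevalence or sex-limitation, site-level
(sub-region) detail, and item-level questionnaire noise. Passing tests
therefore validate the estimators and their calibration under the stated
model, not the substantive findings of any real cohort.

## Problem sizes and test design

Desk-scale checks (published tallies → printed estimates) are exact and run
in well under a second. Stochastic validation uses sizes chosen to keep the
whole suite around a minute while leaving Monte-Carlo bands informative:
oracle equivalence on a 50,000-pair simulated cohort (3 MC SEs); planted
conditional ORs of 1, 2, 3 recovered by the mixed-logit fitter over 20
replicates of 800 two-child families (ICC 0.2); the null MZ/DZ difference
test calibrated over 200 simulated cohorts of 400 pairs at 30% prevalence
(the higher-than-default prevalence keeps every replicate's concordance
defined); IVW identities checked exactly; and same-seed byte-identical
cohort output.

## Known limitations

* The correlation-interval method of the source tables is unknown; this
  package's Fisher-z convention is documented but intentionally different.
* Only per-family random intercepts are offered for pooled offspring models.
* The simulator's single (a², c², e²) set is shared across traits; traits
  with genuinely different architectures cannot be mixed in one cohort.
* `theoretical_similarity` covers twins (including the shared-age term) but
  not sibling or parent-offspring pairings.
* The family analysis assumes relatives' traits are measured with the same
  instrument and definition as the children's.
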