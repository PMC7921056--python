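# Methods

## The problem

Enhanced-recovery (ERAS-style) perioperative care bundles many individual
interventions — preoperative preparation, intraoperative anesthesia and
fluid management, postoperative mobilization — whose individual effects are
hard to separate: compliance with each item depends on patient
characteristics, the items influence one another along the care pathway,
and the clinical endpoints are composite (complications *and* discharge
timing measure overlapping traits). `causallc` implements a causal
latent-class model for this setting: patients are reweighted so that
treatment receipt is decoupled from observed confounders, the multivariate
binary outcomes are summarized by a discrete latent variable, and the
treatment effects on that latent variable are reported as average causal
effects on the treated (ATET).

## Model

**Treatments and weights.** Treatments are grouped into ordered blocks
v = 1..V (e.g. preoperative, intraoperative, postoperative). Every
treatment in block v is regressed on the confounders available at that
block plus all treatments of earlier blocks: logistic regression for
binary items, linear regression for continuous ones. Identification rests
on conditional exchangeability, positivity and consistency. For a binary
item, p_ij is the fitted probability of the arm patient i actually
received; for a continuous item it is a stabilized generalized propensity
score, the marginal normal density of the observed dose divided by its
conditional normal density given the predictors (an unstabilized inverse
density is numerically explosive). The patient weight combines the blocks
as

    w_i = sum_v 1 / prod_{j in v} p_ij        (default)

with the conventional product over all blocks available as
`mode="product"`. The sum form is the package's primary definition; the
product form is the standard sequential-treatment weight and is the one
with a balancing interpretation, which is why the balance diagnostic uses
per-treatment weights (below). Probabilities are floored at 1e-6 (logged),
weights are winsorized at the (0.01, 0.99) empirical quantiles, and the
likelihood stages consume weights rescaled to mean 1: estimates are
invariant to the scale of the weights, but information-based standard
errors and the log(n) penalty in the BIC are only on the right scale when
the weighted pseudo-sample size equals n.

**Balance diagnostic.** For each binary treatment, standardized mean
differences (weighted-mean difference over pooled unweighted SD,
sqrt((s_t^2+s_c^2)/2)) are reported for the confounders in that
treatment's adjustment set — the confounders available at its block.
Later-entering confounders are downstream of earlier blocks, so balancing
early treatments on them would condition on post-treatment variables. The
weighted SMD uses the treatment's own Hájek-normalized inverse-probability
weight 1/p_ij, the weight relevant to its treated/untreated contrast; the
overall sum-over-blocks weight is not a balancing weight for any single
item.

**Measurement model.** Outcomes Y_ir (r = 1..p) are binary, partitioned
into D latent dimensions (between-item multidimensionality: each item
loads on exactly one dimension). A latent class variable U with k support
points drives them through a two-parameter-logistic response,

    P(Y_r = 1 | U = u) = 1 / (1 + exp[-eta_r (xi_{u,d(r)} - delta_r)]),

with local independence given the class. eta_r is the item's
discrimination, delta_r its difficulty, xi_{u,d} the class-u support point
on dimension d. The weighted log-likelihood l(theta) =
sum_i w_i log sum_u pi_u prod_r P(y_ir | u) is maximized by EM.

*Identifiability.* The 2PL is invariant to a per-dimension affine
rescaling of (xi, eta, delta); the gauge is fixed by the first item of
each dimension (eta = 1, delta = 0), support points free. The free
parameter count is therefore (k-1) + kD + 2(p-D). Warm starts that do not
satisfy the gauge are first mapped into it by the exact affine
transformation, never by truncation.

**Selection, classification, uncertainty.** Models are fitted for k = 1
upward; BIC = -2 l + log(n)·#par, and the chosen k is the one immediately
before the first BIC increase (first local minimum); if BIC falls over the
whole range the largest k is returned with a warning. Classes are
relabeled in increasing order of mean conditional outcome probability, so
class 1 always denotes the best-outcome subpopulation; MAP allocation uses
the posterior argmax with ties to the lower class. Measurement-model
standard errors come from the finite-difference observed information of
the weighted log-likelihood, with delta-method SEs for the conditional
probabilities.

**Structural model.** With k fixed, class membership is parameterized by
adjacent-category logits over the treatments and external covariates,

    log p(U = u) / p(U = u-1) = beta_0u + d' beta_1u,  u = 2..k,

class 1 as reference. Under the weighted likelihood the beta_1u encode the
ATET in the distribution of the latent variable; negative coefficients
favor the lower (better) class. The default fit re-maximizes the full
weighted likelihood jointly (measurement + structural) by bounded L-BFGS
with the analytic gradient (the observed-data score equals the
posterior-weighted complete-data score), warm-started at the
measurement-step estimates so class labels cannot switch; a two-step mode
freezes the measurement parameters and fits the concomitant logit on the
posterior probabilities. An intercept-only structural model exactly
inverts the measurement-step class masses.

*Standard errors.* Structural SEs default to the robust sandwich variance
H^{-1} B H^{-1}, with H the observed information and B the outer product
of per-patient weighted scores. With estimated, non-unit weights the plain
inverse information is anticonservative (in the package's own calibration
study, 95% CI coverage was 82% with unnormalized weights and 92% with
normalized weights under inverse information, against 93% with the
sandwich); `se_method="information"` restores the plain version. Wald
z = estimate/SE with two-sided normal p-values. Significance stars default
to the conventional mapping (*** at 1%, ** at 5%, * at 10%); an inverted
"legend" mapping (* at 1%, *** at 10%) is available for compatibility with
reports that print that legend.

## Numerical choices

- Likelihood evaluation uses the stable log-sigmoid of the linear
  predictor everywhere (E-step, M-step, external calls), so the same
  finite likelihood is seen by all stages even at near-degenerate
  probabilities; log-sum-exp guards the mixture over classes.
- EM: patients are collapsed to unique response patterns, making the
  per-iteration cost independent of n. The item M-step maximizes the
  expected complete-data log-likelihood on the collapsed sufficient
  statistics by a few bounded quasi-Newton steps (generalized EM); if a
  step fails to improve, the previous parameters are kept, so the
  log-likelihood is non-decreasing by construction and the fitter raises
  if it ever decreases beyond rounding.
- Multi-start: one deterministic start (k-quantile split of patient
  outcome sums) plus 20 seeded random starts by default; each start runs a
  40-iteration burn-in and the best is polished to convergence (relative
  tolerance 1e-8, cap 1000 iterations).
- Parameters are box-bounded at ±30 during optimization; near-empty
  classes (mass < 1e-4) are flagged.
- Hessians use symmetric central differences; for the structural model the
  Hessian is differenced from the analytic gradient.

## Synthetic cohorts

The generator draws, in causal order: confounders; treatments block by
block (each depending on the confounders available at its block and all
earlier treatments); external covariates; a latent class from the
adjacent-logit truth given treatments and covariates; outcomes from the
2PL truth given the class. The latent truth is returned with the records.

The shipped scenarios emulate the frequency structure of a multicenter
colorectal-surgery enhanced-recovery registry of 1261 patients: marginal
confounder and treatment frequencies (e.g. 37% epidural anesthesia, 83%
ambulation on the first postoperative day, 9% transfusion), a three-class
structure for the primary outcomes (complications dimension + discharge
dimension, masses 0.47/0.35/0.18) and a two-class structure for the
secondary outcomes (masses 0.78/0.22) including a near-degenerate death
item (~0.6% prevalence) that exercises the numerical guards. Since a
printed class-by-item probability table is only approximately
2PL-consistent, the generator truth is the projection of the target table
onto the 2PL manifold: alternating weighted least squares on the logit
scale with weights p(1-p) — a Pearson-chi-square metric on the probability
scale — initialized from the leading singular vectors of the
column-centered logit table. This keeps informative mid-range entries
(e.g. the 0.65 vs 0.87 discharge contrast between the two slower classes)
close to their targets while letting near-zero entries stay near zero.
Structural intercepts are calibrated by root-finding on a fixed internal
draw (seed 202409, n = 20000) so the population-average class masses hit
their targets given the treatment distribution; the calibration is
independent of user seeds.

Scenario-specific choices: `strong-confounding` doubles the confounder
effects on assignment, chosen so that assignment probabilities stay within
roughly [0.013, 0.99] — confounding is strong but positivity, which the
weighting estimator assumes, still holds. `atet-recovery` uses a single
binary treatment (one mildly confounding risk factor) with a true
adjacent-logit effect of -0.8 and well-separated outcome profiles, the
setting in which CI calibration of the structural estimator is
interpretable. `null` zeroes all treatment effects for type-I-error
studies.

What the generator does **not** emulate: the registry's joint confounder
distribution, center heterogeneity, calendar-time trends, missing data, or
any dependence of outcomes on treatments beyond the latent class. Passing
recovery tests therefore shows the estimator works under the model's own
assumptions at realistic sizes, not that those assumptions hold in real
registries.

## Problem sizes in the test and acceptance suites

Measurement recovery uses 20 replicates at n = 2000; BIC selection 20
replicates over k = 1..5; structural recovery and CI coverage 100
replicates at n = 3000; type-I calibration 100 replicates at n = 1261 (the
registry's scale) with k fixed at the generating value; balance checks one
draw at n = 5000; oracle equivalence 25 random instances at n ≤ 8 with a
dense-grid oracle on unconstrained tiny models.

## Known limitations

- The three-class primary scenario is intentionally faithful to the
  emulated class profiles, in which the two better classes share an almost
  identical complications profile (0.07 vs 0.08). Their split is then
  identified only by the two discharge items — a just-identified corner of
  the model — and the maximum-likelihood class masses have large sampling
  variability at n = 2000 (errors up to ~0.15 on single draws, and the
  global optimum itself can sit at a distant mode). The recovery test for
  class masses documents this honestly; conditional-probability recovery
  is unaffected. Sharper class separation would make recovery look better
  but would no longer emulate the target structure.
- The sum-over-blocks weight is reported as defined; it lacks the joint
  balancing property of the product weight and its pseudo-population
  interpretation is per-block.
- Standard errors ignore the sampling variability of the estimated
  weights (no joint estimating-equation correction); the sandwich form
  absorbs most, but not all, of this in the calibration study.
- No missing-data handling: rows with missing declared values are
  rejected at ingest.
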