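# Methods

## The VGR model

Each grading record is one observer's ordinal judgement of a presented image
pair for one image-quality criterion. The model treats the score as a
censored latent variable: the latent quality difference (right minus left)
is

η = a·(ln mAs_R − ln mAs_L) + b[algo_R] − b[algo_L] + u_patient + v_observer + ε,

with ε standard logistic and nondecreasing thresholds θ cutting the latent
scale into the observed categories — the proportional-odds cumulative-logit
model. Covariates enter as right-minus-left *differences* because the score
itself is relative; this coding makes the likelihood invariant to which side
a condition is hung on (mirroring a pair and negating its score changes
nothing) and identifies `a` and `b` exactly as the dose-reduction equation
requires. Tube load is logged with the natural base throughout; DR
= 1 − e^−(b/a) is only base-consistent if the same base is used here.

Assumptions worth stating: proportional odds (one set of thresholds for all
covariate values — no partial-proportional extension); a latent effect
linear in log tube load, which in practice holds only locally (hence the
`dose_interval` restriction, default analyses use 42–98 mAs); random
*intercepts* only for patients and observers — no random slopes; each
criterion is fitted separately, so intercepts are drawn per
(subject, criterion) in the simulator.

Coefficients for an algorithm pair not involving the reference (e.g. IR5
relative to IR3) are obtained by re-fitting with the other algorithm as
`reference`, not by subtracting coefficients, so that the reported SEs and
p-values are the correct ones for that contrast.

## Estimation

Fixed-effects fits maximize the exact likelihood with BFGS on an analytic
gradient, thresholds parameterized as θ₁ plus log-increments to enforce
monotonicity, initialized from the empirical cumulative score frequencies
(coefficients from 0). If the line search stalls above the gradient
tolerance (1e−6 max-norm), damped Newton steps on a central-difference
Hessian polish the optimum. Responses are mapped onto the categories
actually observed, so small datasets using only part of the −2…+2 scale
remain estimable; with all five categories present the thresholds are the
usual 4-vector.

Crossed patient × observer random intercepts make Gauss–Hermite quadrature
inapplicable (the likelihood does not factor over clusters), so the marginal
likelihood uses a Laplace approximation: for each candidate parameter value
the joint mode over all stacked random effects is found by damped Newton
with the full (dense) curvature matrix — cheap at the tens-of-levels scale
of reading studies — and the approximation adds the usual ½·log-determinant
correction. The outer optimization is L-BFGS-B with finite-difference
gradients (step 1e−6, chosen to dominate inner-solver noise) and bounds
log σ ∈ [−5, 3]; a fit whose log-SD ends below −4 is reported with a
"variance pinned at 0" warning rather than an error, and a factor with fewer
than two levels is dropped from the random part up front with the same
warning. Wald covariance for the fixed effects is the corresponding block of
the inverse central-difference Hessian of the negative marginal
log-likelihood over all non-pinned parameters (this block is invariant to
the smooth reparameterizations used for thresholds and SDs).

Degenerate inputs: a response with fewer than two observed categories and a
rank-deficient model matrix raise immediately with the offending covariate
named; coefficients exceeding |30| on the latent scale are treated as
separation and also raise.

## Dose reduction

DR = 1 − exp(−b/a), defined only for a > 0. Intervals: the delta method
propagates the (a, b) covariance to r = b/a and maps the symmetric interval
through the monotone transform (default — smooth and adequate when a is
precisely estimated, as in these designs); Fieller's interval solves the
ratio quadratic and is reported as unbounded when a is not significantly
positive at the chosen level, never truncated; the parametric bootstrap
resamples (a, b) from the fitted Gaussian (seeded, draws with a ≤ 0
discarded). Reported percentages round to the nearest integer per cent;
full precision is kept on the objects. Following the usual reporting
convention, a DR cell whose b is not significant at 0.05 is rendered "−" in
formatted tables while the numeric estimate remains accessible.

## Reliability

Weighted kappa uses disagreement weights |i−j|/(K−1) (linear, default) or
((i−j)/(K−1))² (quadratic); percent agreement is exact-match only — a
within-one-category rate would be a different statistic and is deliberately
not conflated with it. The CI uses the Fleiss–Cohen–Everitt large-sample
variance. Inter-observer comparisons use original readings only
(replicate_index 0), matched on (patient, pair, criterion) with scores
mapped to a canonical pair orientation; intra-observer comparisons pair each
replicated hanging with its original, pooling criteria within observer.
Kappa is reported as undefined (NaN plus a note) when fewer than two
categories occur, rather than as 0 or 1.

## The simulator

`simulate_study` draws from exactly the generative inverse of the fitted
model, with defaults emulating a realistic reading study: 50 patients,
5 observers, 6 criteria, the 12-pair design over {42, 98, 140} mAs ×
{FBP, IR3, IR5} (six within-algorithm dose steps plus the three algorithm
contrasts at 42 and at 98 mAs), ground truth a = 2.3, b(IR3) = 1.0,
b(IR5) = 1.7, σ_patient = σ_observer = 0.5, symmetric thresholds
(−3, −1, 1, 3) — magnitudes that put most probability mass on scores −1…+1,
as observed gradings tend to — and 5 replicated hangings per observer
(replication per observer rather than once overall is a design choice;
the alternative is configurable via `n_replicates`).

Left/right orientation is randomized per (patient, pair) hanging and shared
by all observers, as in a reading room; replicates reuse the original
hanging's orientation and random intercepts with a fresh residual draw. One
consequence worth knowing: after orientation canonicalization an observer's
constant bias v becomes item-sign-dependent noise whose sign factor is
shared between observers, so inter-observer kappa is *not* monotone
decreasing in σ_observer under this design; agreement is driven by the
components observers share (fixed effects and patient intercepts), and the
tests assert those monotonicities instead.

What the simulator does not emulate: image pixel data and noise texture,
observer search behaviour and learning/fatigue over the session, criterion
correlations within a hanging (criteria are conditionally independent given
the intercepts), and any patient case-mix effects beyond a scalar intercept.
Passing tests therefore demonstrate the statistical pipeline is correct
under its own assumptions, not that those assumptions hold for any
particular scanner or reader population.

## Problem sizes and numerical settings

The test suite and examples fit single criteria of full-size studies
(~2,300 records after the dose-interval restriction, 55 stacked random
effects) and scaled-down calibration studies (15 patients, 3 observers);
parameter-recovery checks use 20 replicates and null calibration 100 —
sizes chosen so the whole suite completes in a couple of minutes while the
Monte-Carlo bands stay informative. Convergence targets: relative
log-likelihood change below 1e−8 or gradient max-norm below 1e−6, iteration
cap 200 (outer); inner Newton runs to 1e−10. The brute-force oracle used in
tests refines a 13-point grid over (a, θ₁, θ₂) for 14 rounds, reaching the
1e−4 log-likelihood agreement it asserts.

## Known limitations

- The Laplace approximation can bias variance components downward when
  cluster counts are very small (5 observers); fixed effects are unaffected
  in our recovery checks, but σ²_observer itself is noisy.
- No partial proportional odds, no random slopes, no Bayesian or GEE
  estimation.
- Published coefficient tables ship only to support DR worked examples;
  real ratings are not distributed, so reliability figures from the
  literature are qualitative context, not reproduction targets.
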