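# Methods

## The model

Each study *i* of design *d* (a design is the unordered set of treatments
compared) contributes a vector **Y**_di of estimated relative effects — log
odds ratios or mean differences of the non-baseline arms against the
design's baseline arm — modelled as

    Y_di = delta_d + B_di + omega_d + eps_di,

where delta_d expresses the design's mean effects in terms of the *basic
parameters* delta^{AJ} (average effect of treatment J relative to the
network reference A, with delta^{AA} = 0), B_di ~ N(0, tau_beta^2 P) is a
study-level heterogeneity effect, omega_d ~ N(0, tau_omega^2 P) is a
design-level inconsistency effect shared by all studies of the design, and
eps_di ~ N(0, S_di) is the within-study error with S_di treated as known.
P is the matrix with unit diagonal and halves off it; it arises because all
contrasts in a multi-arm study share the baseline arm.  Stacking gives

    Y ~ N(X delta, tau_beta^2 M1 + tau_omega^2 M2 + S),

with M1 = 1 on the diagonal, 1/2 between rows of the same study, 0
otherwise; M2 = 1 between rows of the same design and comparison, 1/2
between rows of the same design and different comparisons, 0 otherwise.
Consistency (direct and indirect evidence agreeing) is the special case
tau_omega^2 = 0.  Within a single design the design mean and the
inconsistency effect are aliased, so the full model needs at least two
designs, and identifying tau_beta^2 from the single-design submodels needs
at least one design observed in more than one study.

## Estimation

All three estimators act on quadratic forms

    Q(V) = (Y - Yhat)' V^{-1} (Y - Yhat),

with Yhat the GLS fit under weight V^{-1}; when V is the true covariance
this is chi-square distributed with df = rows minus estimated location
parameters.  Matching the realized quadratic form to its expectation (the
df) gives moment estimators:

* **Paule-Mandel** uses total-precision weights, so each Q is a function of
  the unknown variance.  Full model: solve
  sum_d Q_d_het(tau_beta^2) = sum_d (n_d - 1) c_d over the single-design
  submodels, then with tau_beta^2 fixed solve
  Q_net(tau_beta^2, tau_omega^2) = n - c.  Consistency model: solve
  Q_net(tau_beta^2, 0) = n - c.  Each pivot is continuous, strictly
  decreasing in its variance argument and vanishes at infinity, so the root
  is unique; if the pivot at zero is at or below the target df the estimate
  is truncated to zero (at-boundary counts as truncated).  Because the
  expectation of a quadratic form needs only second moments, the estimator
  is semiparametric.
* **DerSimonian-Laird** uses within-study weights S^{-1}, making both
  expectations linear in (tau_beta^2, tau_omega^2):
  E[Q_net] = (n - c) + tr((W - WH)M1) tau_beta^2 + tr((W - WH)M2)
  tau_omega^2 with W = S^{-1} and H the weighted hat matrix, and the
  analogous per-design equation for tau_beta^2.  The estimates are closed
  form, truncated at zero.
* **REML/ML** maximize -1/2 [log det V + log det(X'V^{-1}X) + r'V^{-1}r]
  (ML drops the middle term and profiles out delta) over the nonnegative
  quadrant.  REML is the gold standard when normality is acceptable; ML is
  provided but biased downwards in small networks and never the default.

Inference for the treatment effects plugs the estimated variances into GLS
and treats the weights as fixed and known: delta_hat is multivariate normal
with covariance (X'V^{-1}X)^{-1}, every pairwise effect is a difference of
basic parameters, and Wald intervals use normal quantiles with no
small-sample df adjustment — deliberately, so that simulated coverage
measures the cost of ignoring variance-estimation uncertainty.

Variance-component intervals: the Q-profile interval for tau_beta^2 under
consistency inverts the chi-square(n - c) distribution of the monotone
network pivot; profile-restricted-likelihood intervals around the REML
estimates profile out the other component and cut at the chi-square(1)
quantile.  Intervals for one component that account for uncertainty in the
other are an open problem and are not attempted.

## Numerical choices

* All V^{-1} products use Cholesky factorizations and triangular solves;
  a factorization failure raises immediately — no ridge is ever added,
  since silent regularization would bias the variance estimates.
* Monotone-pivot roots: truncate when pivot(0) <= df; otherwise bracket by
  doubling from 1 + max diag(S) (the pivot decays to 0, so a bracket always
  exists) and solve with Brent iteration to xtol 1e-13, giving estimating-
  equation residuals well below 1e-10.
* REML/ML: bounded L-BFGS-B with analytic gradients
  (dl/dtheta_k = -1/2 [tr(P M_k) - Y'P M_k P Y], P the REML projection) on
  [0, B]^2 with B = 10 (max moment estimate + 1); starts at the origin and
  at the DL and PM estimates; the best converged start wins and a
  convergence flag is always reported.  A run where no start converges
  raises, carrying the best point found.
* Truncation at the boundary (pivot(0) exactly equal to df) counts as
  truncated to zero.
* Reference treatment defaults to the lexicographically smallest label;
  within each design the baseline is the smallest treatment of the design,
  and user-supplied blocks with another baseline are re-expressed exactly
  by the corresponding linear transform.  Variance estimates are invariant
  to both choices (tested).
* Rows are ordered by design, then study, then comparator; designs are
  identified by treatment set only.  A disconnected treatment graph raises
  an identifiability error naming the components rather than falling back
  to a pseudo-inverse.
* Binary outcomes: if any cell of a study is zero, 0.5 is added to every
  cell of every arm of that study before computing log odds; published
  analyses may use other conventions, so third-party results can differ in
  the last digit.
* Location shifts of the outcomes change the estimates only through ~1-ulp
  round-off in forming Y + X kappa; invariance is asserted at 1e-12.

## The synthetic-data generator

`synthetic_layout` emulates a control-anchored drug network of the kind
found in cognitive-enhancer reviews: 37 two-arm, 3 three-arm and 1 four-arm
study on 9 treatments by default, each study containing the common control
with probability 0.6, redrawn until the treatment graph is connected and
every treatment appears.  Per-arm variances are log-normal with
mu = -2.2699, sigma = 1.3725, calibrated so that a two-arm contrast
variance (the sum of two independent draws) has mean 0.53 and median 0.29 —
a heavy-tailed spread of study sizes matching real mini-mental-state data.
Multi-arm covariances follow the shared-baseline-arm rule (off-diagonals
equal the baseline arm's variance).

`simulate_dataset` draws directly from the model with S fixed at its layout
value, basic parameters zero by default (estimation is location invariant),
and replicate streams keyed by (seed, grid point, replicate) so that all
estimators see identical data.  What the generator does **not** emulate:
uncertainty in the within-study variances, non-normal random effects,
binary outcomes generated at the arm level, and any association between
study size and effect.  Passing Monte-Carlo checks therefore demonstrates
correctness of the estimators *under the model*, not robustness to model
misspecification.

## Problem sizes used in the checks

The Monte-Carlo test suite uses the default 41-study layout with 500
replicates per point on the 15-point grid tau_beta^2 in {0, .25, .5, .75,
1} x tau_omega^2 in {0, .25, .5}; the pivot-calibration check uses 5000
replicates at (0.5, 0.25); property checks use 100-200 small random
networks.  These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands (e.g. ~0.01 for a mean of 500 heterogeneity estimates).
The acceptance script defaults to 200 replicates on a 3-point subgrid.

## What the Monte-Carlo checks show — and do not show

On the default synthetic layout, PM recovers the heterogeneity variance
with small bias at every grid point and pooled Wald coverage stays within a
few points of nominal for all three methods.  Two findings deserve note.
First, REML's heterogeneity estimate acquires a visible downward bias when
the true inconsistency variance is zero and heterogeneity is substantial:
with the fitted model free to assign variation to the inconsistency
component, boundary-adjacent fits leak heterogeneity into it.  We confirmed
this is the estimator, not this implementation, by checking our REML
against an independent implementation (metafor's `rma.mv` with the matching
compound-symmetry structure) replicate by replicate.  Second, the relative
precision of the PM and DL heterogeneity estimates crosses over: with the
calibrated log-normal variance spread, DL is the tighter estimator for
small-to-moderate heterogeneity and PM for large heterogeneity — a pattern
an independent brute-force univariate simulation reproduces.  How these two
moment estimators rank therefore depends on the configuration of
within-study variances, and results obtained on one evidence base (for
example, a published real network) need not transfer to another.

## Known limitations

* Only the two-variance-component inconsistency structure is implemented;
  loop-inconsistency variants of M2, covariates (network meta-regression),
  multiple outcomes and dose-response structures are out of scope.
* No Bayesian estimation, prediction intervals, ranking probabilities or
  I-squared summaries.
* The Q-profile interval is available only under the consistency model;
  full-model variance intervals come from the profile likelihood.
* Normal approximations throughout; very small arms (sparse binary data)
  strain the log-odds approximation.
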