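# Methods

## Endpoint and data model

A patient contributes a baseline tumour size `z0 > 0` (sum of target-lesion
diameters, cm), interim and final sizes `z1`, `z2` where observed, interval
failure indicators `d1`, `d2` (non-shrinkage failure: new lesions,
non-target growth, toxicity, death) and non-failure dropout indicators.
The analysis variable is the log size ratio `y_k = log(z_k / z0)`, which
makes a joint normal model for repeated relative change defensible.
Missingness is monotone and structural: failure or dropout in an interval
censors every later size and status, and the package validates these
invariants on construction and on file read (one error message per offending
row).  An indicator 0 is informative; absence never stands in for 0.

A complete response (`z_k = 0`) has no finite log ratio; the package
substitutes the lowest observed size ratio among the *other* patients at the
same timepoint, and errors if there is none.  This keeps the normal model
usable when complete responses are rare, which is the setting the method is
intended for; trials with many complete responses would need a censored
continuous model instead, which is out of scope.

The composite success label is `s = 1` iff `d1 = 0`, `d2 = 0` and
`y2 < log(c)` for the dichotomisation ratio `c` (0.7 for an ORR-like
endpoint, 1.2 for DCR-like).  An optional interim criterion
(`y1 < log(c_interim)`) supports designs that declare failure on ≥20% interim
growth; it is a second threshold on the same code path, not a separate
variant.  A label is 0 as soon as any observed criterion fails and missing
only when dropout makes it undeterminable.

## Model fits

**Shrinkage.** `(y1, y2)` is bivariate normal with means linear in baseline
size — single-arm `mu1 = alpha + gamma*z0`, `mu2 = beta + gamma*z0`;
comparative adds per-timepoint treatment effects (`mu`, `delta`, `beta1`,
`beta2`, `gamma`) — and unstructured `Sigma`.  The fit maximises the
observed-data likelihood directly (valid under MAR): complete pairs
contribute the bivariate density, interim-only patients the univariate
marginal.  Including the interim-only patients is what lets the method keep
its precision under dropout between interim and final visits.  `Sigma` is
parameterised as `(log sd1, log sd2, atanh rho)` so the optimisation (BFGS
from complete-case moment starts, deterministic) is smooth and
unconstrained.  The parameter covariance is the inverse observed information,
by central finite differences of the likelihood with steps
`1e-5 * max(1, |param|)`, on the same internal scale used later by the delta
method.  We use full ML rather than REML-style fitting so that the
likelihood, the information matrix and the delta method are mutually
consistent; at the sample sizes the method is recommended for (≥50 per arm)
the difference is negligible.

**Failure.** Interval 1: logistic regression of `d1` on baseline size (and
treatment).  Interval 2: logistic regression of `d2` on the most recent
observed size among patients with `d1 = 0` — the interim size in cm by
default (`interval2_covariate="size"`), with the interim log ratio as an
alternative; the two give nearly identical operating characteristics in the
scenarios studied here.  Fits use Newton ML (statsmodels) with the inverse
observed information as covariance.  One-class outcomes and (quasi-)complete
separation raise an explicit error suggesting a simpler model rather than
being silently repaired.

The three fits share no parameters, so the joint parameter vector theta
(length 10 single-arm, 14 comparative) carries a block-diagonal covariance.

## Success probability, CI and two-arm test

The per-patient success probability integrates the failure-weighted
conditional normal law of the final ratio over the interim ratio:

    p(z0, t) = (1 - pi1(z0, t)) * Int phi(y1; mu1, Sigma11)
               (1 - pi2(z0*exp(y1), t)) * Phi((log c - mu_{2|1})/sd_{2|1}) dy1

The `y2` dimension closes analytically through the conditional normal CDF;
the `y1` integral spans ±8 marginal SDs (tail mass < 1e-14), truncated at
`log` of the interim threshold when that criterion is active.  The scalar
entry point uses adaptive quadrature (absolute tolerance 1e-8); estimate and
gradient evaluation use a 48-node Gauss–Legendre rule vectorised over
baselines, which agrees with the adaptive result to ~1e-9 and with a
million-draw Monte-Carlo evaluation to well under 1e-3 (both are tested).

The trial estimate averages `p(z0_i)` over all observed baseline sizes —
including patients with no post-baseline data, who are still part of the
trial population.  The CI is Wald on the logit scale: the gradient of
`logit(mean p)` in theta is taken by central finite differences (steps as
above), `se^2 = grad' V grad`, and the interval is mapped back by expit.
A degenerate estimate (0 or 1) raises rather than returning an infinite
logit.  The two-arm analysis estimates
`m(theta) = mean_i [p(z0_i, 1) - p(z0_i, 0)]` over the pooled baseline sizes
of both arms — adjusting the comparison for chance imbalance in baseline
size (per-arm averaging is an option) — with the analogous delta-method Wald
test on the difference scale.

## Comparators

* **Binary**: complete-case success proportion with a Wilson score interval
  (patients with undeterminable status excluded, no imputation).
* **Logistic**: Wald test of the treatment coefficient in
  `S ~ 1 + z0 + t` on complete cases.
* **Karrison worst-value rank-sum**: Wilcoxon rank-sum on final log ratios
  between arms, with non-shrinkage failures imputed to the worst (largest)
  observed log ratio pooled across arms, and non-failure dropouts excluded.
  Exact null distribution for combined n ≤ 20 without ties, otherwise the
  normal approximation with tie correction and continuity correction.
  Being rank-based, it is invariant to monotone transforms of the ratios.

## Simulator and operating characteristics

The simulator draws `z0 ~ U(5, 10)` cm and `(y1, y2)` bivariate normal with
mean `(delta/2, delta)` and covariance
`Sigma_sim = sigma^2 [[f, rho*sqrt(f)], [rho*sqrt(f), 1]]`.  Defaults
`f = 0.5`, `rho = 1/sqrt(2)` — i.e. `sigma^2 [[0.5, 0.5], [0.5, 1]]` — were
fixed by requiring the generating model to reproduce the published truth of
the size-dependent-failure scenario (0.293), which is sensitive to the
covariance; the flat-failure truths (0.334, 0.241) do not depend on it.
Interval failures are logistic in the previous observed size with intercept
`alpha_D`, size slope `gamma_D` and treatment effect `beta_D`; an analogous
independent process drives dropout (`alpha_O = -inf` disables it), and a
patient simulated to both fail and drop out in one interval is recorded as a
dropout.  Two-arm means are `log(0.7) + psi ± x`: `2x` is the arm contrast
and `psi` shifts both arms relative to the 30%-shrinkage point.  Each trial
is drawn from one seeded generator in a fixed vectorised order, so a seed
reproduces the dataset byte-for-byte.

`true_success_prob` integrates the generating law (uniform baseline × normal
interim marginal × conditional normal CDF) with 64-node quadrature; with no
size effect it collapses to `(1 - expit(a))^2 * Phi((log c - delta)/sigma)`.

The OC runner applies every requested method to the *same* simulated dataset
per replicate (paired comparisons), aggregates bias, coverage against the
generating truth, CI width, the replicate-wise width reduction of the
augmented binary CI relative to the binary CI, and rejection rates.
Replicates where a method errors are counted and reported per method, never
silently dropped; headline runs require a failure rate below 1%.  The
Monte-Carlo standard error of any rate is `sqrt(r(1-r)/n_reps)`.  Default
problem sizes — 2000 replicates at 75 patients per arm — keep a full study
in the minutes range on one CPU while leaving rate SEs near 0.005–0.011.

## What the simulations do and do not show

The generator reproduces the structural features the method relies on:
uniform baselines, correlated normal log ratios, logistic failure/dropout in
the previous size, monotone censoring.  It does not emulate measurement
error in lesion sums, non-normal ratio distributions, failure depending on
the *latent* current size, cause-specific failure mixtures, or more than two
post-baseline visits — so passing simulations demonstrate correctness of the
implementation under its stated model, not robustness to those violations.

## Known limitations and observed behaviour

* The delta-method CI is first-order.  In our runs its SE tracks the
  empirical sd of `logit(p_hat)` to within a few percent at n = 75 and sits
  at the ML information bound; coverage lands near 0.95 across the scenarios
  studied, including low-success ones.  Published results for this class of
  method report noticeably larger CI-width reductions together with
  undercoverage in low-success scenarios, a combination consistent with an
  optimistic SE; a calibrated implementation cannot reproduce both, and this
  package reports the calibrated numbers.
* Bootstrap CIs (preferable below ~50 patients per arm) are not provided;
  a parametric bootstrap is used internally only as a test oracle.
* No sample-size machinery: trials should be sized by conventional methods,
  with the augmented binary analysis supplying the extra precision.
* Lesion-level RECIST bookkeeping is out of scope; only the summed diameter
  is modelled.
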