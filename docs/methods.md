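# Methods

## Model and scope

`ipbkit` analyses collections of randomized trials reporting a binary
adverse event as 2×2 tables, grouped into meta-analyses. The effect measure
is the odds ratio throughout — the standard choice for binary safety
outcomes, and the scale on which Peters' test is defined. All inference is
in the conventional normal-within-study framework: each trial contributes
`y_i = ln(a_i d_i / b_i c_i)` with variance `s_i² = 1/a + 1/b + 1/c + 1/d`,
and the random-effects model is `y_i ~ N(μ, s_i² + τ²)`. Generalized linear
mixed models, exact methods, and selection-model likelihoods are out of
scope.

## Zero events

Zero cells are the norm, not the exception, in rare-event safety data.

- **One arm with zero events** (or, symmetrically, an arm in which every
  participant had the event): 0.5 is added to all four cells, never to a
  subset, so each arm total grows by 1. The corrected cells feed `y` and
  `s`; the *observed* integer counts feed everything that represents a
  measured quantity — total sample size `N_i`, total events `S_i`, total
  non-events `F_i` used by Peters' covariate and weights. Sample sizes are
  facts about the trial; the correction is an estimation device.
- **Zero events in both arms**: the trial is excluded from all IPB
  assessment. The eligibility report accounts for every excluded row.

## Pooling and τ²

Fixed-effect pooling is plain inverse-variance. Random-effects τ² is
estimated by restricted maximum likelihood via Fisher scoring: starting from
the DerSimonian–Laird moment estimate, each step adds (restricted
score)/(expected information) and floors the iterate at 0. Convergence is a
step smaller than 1e-10 within 100 iterations; anything else (including
non-finite iterates or non-positive information) is reported as
non-convergence, and pooling silently falls back to DerSimonian–Laird,
recording which estimator was actually used. Non-convergence is real in
practice — two-study meta-analyses with wildly unequal variances stall the
scoring iteration — so the fallback is part of the contract, not an error
path. The REML estimate matches a bounded maximization of the restricted
likelihood to 8 decimals on fixtures, and an independent R implementation
(metafor) to its looser default tolerance.

## Asymmetry tests and direction

Egger's test is fit as OLS of `z_i = y_i/s_i` on precision `1/s_i`; the
intercept is the asymmetry coefficient, algebraically identical to the slope
on `s_i` in the weighted form of the regression (the test suite checks the
identity to 1e-10). Peters' test is WLS of `y_i` on `1/N_i` with weights
`1/(1/S_i + 1/F_i)`. Both use Student-t inference with `k − 2` degrees of
freedom and a multiplicative dispersion estimate, and both require `k ≥ 3`
and a non-constant regressor.

Direction: harm is coded log OR > 0. IPB suppresses significant harm, so
published small studies sit closer to the null and the IPB alternative is a
**negative** coefficient (`suppress_high`, the default; configurable per
meta-analysis since a dataset may orient outcomes either way). The one-sided
p is `P(T ≤ t)` under that alternative, so `p_one = p_two/2` when the
coefficient has the expected sign and `1 − p_two/2` otherwise — which is
exactly how a one-sided test can overturn a two-sided verdict in both
directions. Significance is called at α = 0.1, the customary level for
asymmetry tests; no multiplicity adjustment is applied across
meta-analyses, matching how such corpora are conventionally reported.

## Trim-and-fill

The Duval–Tweedie iteration with the L0 (default) or R0 estimator. For
missing-on-the-right (the IPB default), effects are sign-flipped so the
observed surplus is positive; ranks of |y − μ̂| use midranks for ties, with
ties identified up to a relative 1e-8 tolerance — mirror-imputed points
reproduce |y − μ̂| only to floating point, and exact-equality ranking would
break those ties arbitrarily. L0 is rounded half away from zero and floored
at 0; trimming removes the k0 most extreme surplus-side studies (ties broken
by input order), and the loop re-pools, re-centres and re-estimates until k0
stabilizes (cap 20 passes, with a `stabilized` flag). Filling mirrors each
trimmed study about the final centre (`y_fill = 2μ̂ − y`, SE unchanged) and
re-pools observed + filled. Within-iteration pooling defaults to random
effects to match the pipeline; fixed-effect pooling is available and is what
the oracle tests use (k0 and the adjusted estimate match metafor's
trim-and-fill exactly on fixtures). No attempt is made to widen the adjusted
confidence interval for imputation uncertainty.

## Funnel geometry

All three funnel variants are computed as plain coordinate arrays first and
rendered second, so every boundary is testable without a plotting backend.
Contour bands at p ∈ {0.1, 0.05, 0.01} (aligned with the α = 0.1 threshold)
satisfy `|x| = z_{1−p/2}·s`. The sample-size funnel needs a
variance-versus-N model to draw contours at all; we calibrate
`Var(y) ≈ c/N` with `c = median(N_i s_i²)` over the plotted studies. This is
a pragmatic stand-in — the construction of published sample-size funnels is
not standardized — and the contours should be read as approximate
significance guides, not exact test boundaries. The x-axis is drawn in
log-OR units with OR tick labels. SVG output pins the hash salt and strips
date metadata, so identical geometry yields byte-identical files.

## Agreement

Cohen's κ is unweighted, for both the 4-level grades (no/mild/moderate/
severe IPB) and the binary collapse (no+mild = absent, moderate+severe =
present). When both raters are constant and identical, κ is defined as 1.
Visual grades are *inputs* read from a labels file — the package quantifies
agreement between human assessments, it does not grade funnels. Venn region
counts over the four significant-sets partition the universe of assessed
meta-analyses; the complement region collects meta-analyses flagged by no
test.

## Pipeline

Eligibility follows: drop rows with missing 2×2 cells, drop double-zero
trials, then require `k ≥ 10` analysable trials (10 being the conventional
floor below which asymmetry tests are considered uninformative). The
ordering matters for meta-analyses straddling the threshold, so the
alternative (threshold before the double-zero drop) is available by option
and the per-meta report accounts for every input row exactly once.
Per-meta-analysis failures (degenerate designs, etc.) are recorded in-row
and never abort a batch; `summarize` is a pure function of the assessment
table.

## Simulation model

Each trial draws total `N` log-uniform on [50, 1000] (equal allocation by
default), a control-arm risk `p₀` (fixed or log-uniform over a range), a
study effect `θ_i ~ N(θ, τ²)`, treatment risk `expit(logit(p₀) + θ_i)`, and
binomial event counts per arm. Selection is significance-based: a study
whose own one-sided Wald p for harm (after zero handling; double-zero counts
as no harm) is below `alpha_sel = 0.05` is published with probability γ,
otherwise always published. Generation repeats until the target number of
published studies is reached, keeping every generated study in the truth
record so the realized suppression fraction is known. All randomness flows
through one seeded `numpy` Generator.

Defaults (k = 13 published trials, control risk 0.1, N ∈ [50, 1000]) mirror
a typical adverse-event meta-analysis: the median meta-analysis size in
large safety corpora is about 13 trials. What the generator does **not**
emulate: correlated outcomes within reviews, non-binomial overdispersion,
dependence of selection on magnitude rather than significance, or the
metadata richness of real trial tables. Passing calibration tests here says
the tests behave as designed under a clean selection mechanism — not that
they will detect IPB reliably in any particular real corpus.

### What the simulations show — including a negative result

With no selection and θ = 0, the one-sided Peters test holds its nominal
0.1 level at moderate event rates, while two-sided Egger runs slightly hot
— the familiar rare-event inflation (the suite asserts Peters' calibration
and records Egger's rate without asserting it). Under strong selection
(γ = 0.1, θ = 0.7) the pooled estimate is biased sharply toward the null
(≈ 0.46 vs 0.7 at control risk 0.1), and the bias grows monotonically as γ
falls.

However, significance-based suppression at these settings produces only
weak *funnel asymmetry*: it removes significant-harm studies of all sizes,
so the funnel shifts toward the null nearly uniformly, and at θ = 0.7 the
intrinsic association between a log OR and its SE actually shifts Egger's
statistic in the *positive* direction. The net result — verified by
Monte Carlo in this package — is that the correctly-directed one-sided test
does **not** reliably out-reject the two-sided test under this mechanism,
even though the one-sided test is the right tool when the asymmetry truly
has the expected sign (as the hand-built fixtures demonstrate). The
acceptance test asserting the one-sided power advantage is left failing
rather than weakened: it is an informative negative finding about
significance-based selection, not a defect of the tests.

## Numerical choices

- REML: tol 1e-10 on τ², 100 iterations, DL start, floor at 0.
- Trim-and-fill: max 20 passes; midrank tie tolerance 1e-8 (relative).
- L0 rounding: half away from zero.
- Degenerate regressions (constant `s_i` or constant `N_i`) raise a typed
  error rather than returning a coefficient from a singular fit.
- Exact-fit regressions (zero residual) report t = 0 when the coefficient
  is 0, ±∞ otherwise.
- Selection acceptance is capped at 10⁶ generated studies per meta-analysis;
  pathological configurations abort with a diagnostic.
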