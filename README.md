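# ipbkit

Tools for assessing **inverse publication bias (IPB)** in meta-analyses of
adverse events.

Classic publication bias favours large, significant *benefits*. Safety
outcomes suffer the mirror-image problem: trials that find **no significant
harm** are the ones more likely to be published, so the published record of a
drug's adverse events is biased toward the null. `ipbkit` is for
biostatisticians and evidence-synthesis researchers who want to detect that
pattern in trial-level 2×2 safety data — and to study how well the standard
detection toolkit works when events are rare and meta-analyses are small.

## What it computes

For each meta-analysis of 2×2 tables (events/total per arm):

- **Effect sizes.** Log odds ratio `y = ln(ad/bc)` with
  `SE = √(1/a + 1/b + 1/c + 1/d)`. Trials with zero events in one arm get a
  0.5 continuity correction added to all four cells; double-zero trials are
  excluded (their OR is undefined).
- **Pooling.** Inverse-variance fixed effect, or random effects
  `yᵢ ~ N(μ, sᵢ² + τ²)` with τ² by Fisher-scoring REML and an automatic
  DerSimonian–Laird fallback when scoring fails to converge.
- **Asymmetry tests, one- and two-sided.** Egger's regression
  (`yᵢ/sᵢ = α + β/sᵢ`; asymmetry coefficient α) and Peters' test (WLS of
  `yᵢ` on `1/Nᵢ` with weights `1/(1/Sᵢ + 1/Fᵢ)`), each with the conventional
  two-sided p and a direction-aware one-sided p. Under IPB the suppressed
  studies sit on the harmful (right) side of the funnel, so the alternative
  is a *negative* coefficient; significance is called at α = 0.1.
- **Trim-and-fill** (Duval–Tweedie, L0 or R0 estimator) oriented to impute
  missing *harmful* studies on the right, with a bias-adjusted pooled
  estimate.
- **Funnel geometry and plots**: contour-enhanced, trim-and-fill and
  sample-size-based funnels, as testable coordinate arrays plus SVG/PNG
  rendering and JSON export.
- **Agreement**: unweighted Cohen's κ between raters or between tests,
  4-level IPB grades collapsed to present/absent, and Venn region counts of
  which meta-analyses each of the four test variants flags.
- **Simulation**: a generator of meta-analyses of binary adverse events with
  known truth (θ, τ², event rates, sample-size distribution) and a
  significance-based selection mechanism — a study whose own one-sided Wald
  test shows significant harm is published only with probability γ — for
  calibration and power studies of all of the above.

## A worked example

```bash
python examples/03_trim_and_fill.py
```

Eight trials form a symmetric funnel around log OR ≈ 0.48; the three with
the largest harm are deleted to mimic suppression, and trim-and-fill is run
on the surviving five:

```
observed pooled log OR = +0.388 over k = 5
estimated missing studies k0 = 3 (estimator L0, side = right, 3 iterations)
  imputed t0+fill: log OR = +1.220 (SE 0.50)
  imputed t1+fill: log OR = +1.020 (SE 0.40)
  imputed t2+fill: log OR = +0.820 (SE 0.30)
adjusted pooled log OR = +0.460 over k = 8
pre-deletion pooled log OR  = +0.483  <- the target the adjustment moves toward
```

The algorithm correctly estimates that three studies are missing on the
harmful side and moves the pooled estimate from 0.39 back toward the
pre-deletion value. The other scripts under `examples/` walk through effect
sizes and pooling, the four test variants, funnel plots, agreement
statistics, and a full simulate-then-assess pipeline run.

For file-based workflows there is a thin CLI:

```bash
ipbkit simulate --seed 7 --n-meta 20 --out sim/
ipbkit assess --input sim/trials.csv --alpha 0.1 --min-k 10 --out results/
```

`assess` writes per-meta-analysis results, an eligibility accounting CSV,
and an aggregate JSON summary (significance counts per test, one- vs
two-sided concordance and κ, change-direction splits, Venn regions,
median k).

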