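# Methods

## The problem

In the ternary-response timing task an observer judges two stimuli *x* and
*y*, physically separated by the stimulus-onset difference `d = t_y − t_x`
(ms), and reports *xy* (*x* first), *si* (simultaneous) or *yx* (*y*
first). The task yields two psychometric functions of `d`:

    F_R(d) = P(xy | d)
    F_L(d) = P(xy | d) + P(si | d) = 1 − P(yx | d)

Independent-channels models assume the central comparator receives the
arrival-time difference `ΔA = ΔL + d`, where `ΔL` is the difference of the
peripheral (sensory) latencies, and compares it to a central threshold
`C`: *xy* if `ΔA ≥ C`, *yx* if `ΔA ≤ −C`, *si* otherwise. Under this
additivity, `E(F_R) = E(C − ΔL)` and `E(F_L) = E(−C − ΔL)` as distributions
over `d`, so

    E(F_R) − E(F_L) = 2·E(C),

independently of the latency distribution. Half the distance between the
two function means therefore isolates the central threshold, free of
peripheral latencies — the quantity this package estimates, and whose
invariance across stimulus conditions it tests.

## Synthetic observer (`simulate`)

The generator draws `ΔL ~ N(mu, sigma²)` per trial and applies the
two-threshold decision rule: *si* if `|ΔA| < c_su`; veridical order
report if `|ΔA| ≥ c_o`; otherwise (successiveness detected, order not)
*xy* with probability `gamma`. Ties are resolved by the weak/strict
inequalities above; `c_su = c_o = C` recovers the single-threshold rule.
A single `gamma` is shared by the positive and negative guess regions —
the simplest parameterization consistent with order guessing; side-specific
guessing biases or trial-variable thresholds are deliberately not modelled.

Built-in designs mirror the two study geometries:

* **exp1** (modality design): 25 `d` values from −200 to +200 ms in steps
  of 16.6̄ ms, 400 trials per `d` per condition, 20 sessions × 20 blocks of
  50 trials, conditions alternating block-wise (20,000 trials total).
* **exp2** (intensity design): 15 `d` values from −350 to +350 ms in steps
  of 50 ms, 180 trials per `d` per condition, 5 sessions × 18 blocks of 60
  trials, conditions interleaved trial-by-trial.

Contamination is applied after response generation, one exclusive channel
per trial: premature RT (< 150 ms), delayed RT (> 5000 ms), double-click
lapse flag, and corrected finger error (flag only — the final response
remains valid). Default rates (0.2%, 0.1%, 0.2%, 1.0%) match the mean
exclusion proportions reported for the modality experiment. RTs otherwise
come from a lognormal body (median 600 ms, log-SD 0.35) clipped inside the
valid window; RT distributions are not a modelling target, they exist only
to exercise the cleaning rules. What the generator does **not** emulate:
criterion drift and practice effects, apparent-motion cues, sequential
dependencies, or hardware timing jitter — so passing tests demonstrate
correctness of the estimators under the stated model, not robustness of
the model to real observers.

## Cleaning and tabulation (`preprocess`)

Practice trials (first two blocks of session 1 for the exp1 layout, first
block of session 1 for exp2 — configurable), listed excluded blocks,
premature (RT < 150 ms, strict), delayed (RT > 5000 ms, strict) and lapse
trials are removed, in that priority order when a trial qualifies for more
than one category; corrected trials are retained. Cleaning is idempotent.
Retained trials are tabulated into per-(condition, `d`) counts
`(n_xy, n_si, n_yx)`; empirical `F_R` and `F_L` follow directly, with
`F_R ≤ F_L` by construction.

## Nonparametric estimator (`nonparametric`)

Each empirical function is monotonized by weighted pool-adjacent-violators
(weights = per-`d` trial totals, giving the binomial maximum-likelihood
monotone fit) and anchored: the function is pinned to 0 and 1 exactly at
configurable anchor points outside the grid (±225 ms for the exp1 grid,
±400 ms for exp2). The anchors are hard constraints, not data points. The
mean of each function is the mean of the discrete distribution of its
increments on the anchor-augmented grid,

    mean = Σ_i (p_{i+1} − p_i) · (d_i + d_{i+1}) / 2,

and the central threshold is `(mean_R − mean_L)/2`, the midpoint (point of
subjective simultaneity) `(mean_R + mean_L)/2`.

Numerical notes:

* PAV blocks carry their weighted mean, so the fit stays in [0, 1] and is
  idempotent; a non-monotone input to the mean formula is an error rather
  than silently fixed.
* Because both functions share the same per-`d` weights and isotonic
  regression is an order-preserving operator, the monotonized functions
  cannot cross; the crossing diagnostic in `sk_threshold` is a safety net
  for hypothetical unequal-weight uses.
* **Anchor truncation bias.** If a function has not effectively reached 0
  or 1 inside the grid, the mass beyond the anchors is relocated to the
  outermost increment midpoint. For an observer with `C = 50` ms,
  `sigma = 40` ms and a latency shift of ±100 ms on the ±200 ms grid this
  biases the threshold by ≈ −0.4 ms (computed at infinite n). This is
  negligible against typical CI widths, but a bootstrap CI from 10,000
  trials per function is narrow enough to occasionally flag it as a
  spurious sub-millisecond "invariance violation". Conclusions should rest
  on effect sizes, not only on CI exclusion of zero, when functions are
  visibly truncated — and anchors should sit where the functions truly
  saturate.

Under the two-threshold generating model with shared `gamma`, the
half-distance estimand equals `c_su` exactly (the `c_o` and `gamma` terms
cancel between the two means); simulation tests use this identity.

## Parametric model (`parametric`)

With `z(c) = Φ((c − mu − d)/sigma)` the trinomial cell probabilities are

    p_si = z(c_su) − z(−c_su)
    p_xy = [1 − z(c_o)] + gamma·([z(c_o) − z(c_su)] + [z(−c_su) − z(−c_o)])
    p_yx = 1 − p_xy − p_si.

The multinomial log-likelihood (probability floor 1e−9) is maximized over
`(mu, log sigma, c_su, δ = c_o − c_su, logit gamma)` by L-BFGS-B with
explicit bounds `c_su ≥ 0`, `δ ≥ 0` — bounds rather than a fully
unconstrained transform because the boundary estimates `c_su = 0` and
`δ = 0` (single-threshold submodel) are legitimate ML solutions that a log
transform could only approach asymptotically. Convergence: relative
log-likelihood tolerance 1e−6.

Multi-start (default 20 restarts): `mu` from the negated SK midpoint,
`c_su` from the SK threshold, `sigma` from the interquartile `d`-spread of
the monotonized `F_R`, `δ ∈ {1, c_su/4 + 5}`, `gamma = 0.5`, plus seeded
lognormal/Gaussian jitter — the trinomial likelihood is multimodal when
the guess region is flat. The single-threshold submodel (`δ` fixed at 0)
is available for likelihood-ratio comparisons. Lapse/finger-error
parameters are intentionally absent from the model: contamination is
handled upstream by cleaning, mirroring the pipeline order.

## Inference (`inference`)

* **Bootstrap**: trials are resampled within each (condition, `d`) cell —
  multinomial with the observed cell proportions, per-cell n fixed, the
  natural scheme for a fixed-design psychophysics experiment. The
  estimator is re-applied to each of B = 1000 (default) resamples;
  the 2.5th/97.5th percentiles (numpy linear interpolation between order
  statistics) bound the 95% CI. Estimator failures trigger a redraw (cap
  5, reported). Everything is deterministic given the seed.
* **Invariance test**: both conditions are resampled on every iteration;
  invariance is violated iff the CI of the difference excludes zero. No
  multiple-testing correction across estimators is applied.
* **Parametric refits** inside the bootstrap warm-start from the full-data
  fit with a single restart; cold multi-start refits changed no CI
  endpoint beyond percentile noise in spot checks but cost 20× the time.
* **Practice curve**: sorted sessions are partitioned into consecutive
  levels (default 5 sessions per level), each estimated with its own CI.
* **Group statistics**: two-sided paired t with `d_z = mean(diff)/sd(diff)`
  (n−1 denominator); zero-variance differences with nonzero mean report a
  signed infinite t.

## Problem sizes in the test and acceptance suites

Unit and property tests run on scaled-down designs (40–240 trials per
`d`). The validation suite uses the full 400-trials-per-`d` geometry:
parameter recovery over 20 replicate datasets; CI coverage over 200
simulate-then-estimate replications at B = 500; the closed-form/Monte-Carlo
oracle at 10⁶ draws per `d`; and the coverage-of-generating-values check
over 5 replicate end-to-end runs per estimator (majority coverage, since
any single 95% CI misses ~5% of the time). `scripts/acceptance.py`
recomputes the group statistics from the packaged tables and the
latency-invariance, recovery and coverage studies at these same sizes.

## Known limitations

* The Gaussian fixed-threshold form of the two-threshold model is the
  minimal reading; parameter-recovery tests define its correctness here.
* The SK anchor positions are part of the estimand definition; thresholds
  near or beyond the grid edge are biased toward the anchors (see above).
* The simulator's stationarity means practice-curve machinery is only
  validated for stability, not for detecting real drift shapes.
* Bootstrap CIs are percentile, not BCa; for strongly skewed bootstrap
  distributions (thresholds near 0) coverage can dip slightly below
  nominal.
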