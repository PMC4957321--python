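# Methods

## Model and assumptions

Enrollment is modeled as a renewal process with i.i.d. exponential waiting
times `w_i ~ Exp(mean θ)` — equivalently, a homogeneous Poisson process with
rate 1/θ. The constant-rate assumption is the model's central simplification:
it is reasonable for single-site studies with stable referral streams, and
the diagnostics module exists precisely to check it (ECDF of the observed
gaps against the fitted exponential, cumulative trajectory against the
planned line).

The prior `θ ~ IG(nP, TP)` is conjugate to the exponential likelihood, so
the posterior after `m` enrollments in elapsed time `Tm` is
`IG(nP + m, TP + Tm)`. The prior is deliberately parameterized by the study
design: it carries the information of `nP` pseudo-subjects over `TP`
pseudo-time, all at the planned rate `n/T`. `P` therefore acts as a prior
sample-size fraction, not a probability of success. As data accumulate, the
prior weight `nP/(nP + m)` decays to zero (verified by a swamping test).

Two closed-form posterior predictives follow:

* **Count**: the number of further enrollments in the remaining window is
  `NB(r, p)`, `r = nP + m`, `p = (TP + Tm)/(TP + T)`. Its mean at the
  prior state is exactly `n` for every valid design — an algebraic identity
  (`r(1−p)/p = nP · T/(TP) = n`) asserted as a property test.
* **Time**: the remaining time to `k` more enrollments satisfies
  `T_rem/(T_rem + s) ~ Beta(k, r)`, `s = TP + Tm`; equivalently
  `T_rem = s·X` with `X` beta prime. Quantiles map through
  `Tm + s·x/(1−x)`.

The two views describe the same event — "recruit the remaining `k` within
the window" versus "total time ≤ T" — and both probabilities reduce to the
regularized incomplete beta `I_{1−p}(k, r)`; the test suite asserts their
equality to 1e−9 on random states.

## Parameters

| Parameter | Meaning | Units | Default / guidance |
|---|---|---|---|
| `n` | target sample size | subjects | required |
| `T` | planned accrual duration | caller's unit (days or months, consistent) | required |
| `P` | prior confidence | fraction in (0, 1] | CLI default 0.1; 0.5 when confidence is genuinely strong |
| `Tm` | elapsed review time | same unit as `T` | last enrollment time if omitted |
| `level` | credible level | probability | 0.95 |

`P = 0` is rejected: IG(0, 0) is improper and every closed form degenerates.
Strong priors (`P ≈ 0.5`) help when accrual is on target; weak priors
(`P ≈ 0.01`) adapt faster when it is not. When in doubt, 0.1 is a sensible
starting point.

### The elapsed-time convention

The strict renewal-theory clock stops at the m-th enrollment
(`Tm = Σ w_i`), but interim review happens at arbitrary calendar times, and
the censored gap since the last enrollment is genuine information: the
Poisson-process likelihood `θ^{-m} e^{-Tm/θ}` has the same conjugate form
with `Tm` the full elapsed review time. The package therefore takes `Tm`
from the caller (defaulting to the last enrollment);
`AccrualObservation.at_last_enrollment` gives the strict variant.

## Numerical choices

* **Discrete quantiles.** NB intervals use the standard discrete quantile
  (smallest integer whose CDF reaches the tail mass), giving deterministic,
  reproducible endpoints. The exact 95% planning interval for the
  (n=158, T=24, P=0.5) worked example is (118, 203).
* **Normal approximations** are moment-matched: NB mean/variance for
  counts, beta-prime mean/variance for times, rounded outward (counts) and
  truncated at the already-observed value. They are accurate when `r` is
  large and `p` is moderate; the package warns outside `r ≥ 30`,
  `p ∈ [0.1, 0.9]` (thresholds configurable). The time approximation needs
  `r > 2` for a finite variance and errors below that. Because the beta
  prime is right-skewed, the symmetric approximation shifts both endpoints
  low — by roughly 0.7 months in the worked example — so the exact path is
  the default everywhere and the approximation exists for speed-critical
  callers.
* **Monte-Carlo paths** draw θ from the posterior and then
  Poisson(window/θ) counts or Gamma(k, θ) times, with an explicit seed; no
  hidden global RNG state anywhere in the package.
* **Degenerate inputs.** `Tm = T` collapses the count interval to
  `(m, m)`; `k = 0` collapses the time interval to `(Tm, Tm)`; `Tm > T` is
  a hard error for the fixed-window question (the window is exhausted — ask
  the time-to-target question instead). Same-day enrollments (zero waiting
  times) are permitted: the conjugate update touches the data only through
  `(m, Tm)`.

## Projection bands and the site review

The planning/interim tunnel (`projection_band`) traces the equal-tailed NB
interval of `m` plus the remaining count across a grid of future times; it
starts exactly at `(Tm, m)` and every series is non-decreasing. The
reference "planned accrual" line is the straight line from (0, 0) to
(T, n) — the only reference consistent with a constant-rate plan.

The multicenter review pools all sites into one stream, fits one posterior,
and compares each center against its share of a pooled tunnel. Here the
forward-projection band is the wrong object: at the review time itself it
collapses onto the observed pooled count, leaving nothing to compare sites
against. Instead the site tunnel re-projects cumulative accrual from trial
start under the fitted posterior — for grid time `t`, the count of arrivals
in a fresh window of length `t` is `NB(r, s/(s+t))` — which is
non-degenerate at the review snapshot and reduces to the planning band when
no data have been seen. The tunnel and the linear reference are divided
equally among the J sites (optionally by a weight vector); per-site
endpoints are kept as reals since they bound an average, not a count. A
site below its lower limit at the review time is flagged `below-band`.
Equal division is the default because per-site targets are rarely part of a
protocol; genuinely hierarchical per-site modeling is out of scope.

## Synthetic data

The generator inverts the model: exponential gaps at a configurable θ, per
site, stopped either at a subject count or at a time horizon, with
continuous offsets by default and optional rounding to whole days to mimic
date-stamped logs. A piecewise-constant θ schedule (simulated by inverting
the integrated hazard segment by segment) provides controlled violations of
the constant-rate assumption; tests confirm the violation is detectable in
the ECDF diagnostics at large m. Site streams are independent — no shared
calendar effects, center start-up staggering, or dropout — so passing tests
demonstrate correctness of the computations under the model's own
assumptions, not robustness to the full messiness of real enrollment logs.

Default validation sizes (chosen as conventional for this kind of
calibration study): 200 replicates of m = 1000 enrollments for parameter
recovery (relative bias under 2%, interval coverage near nominal), 500
simulated trials for band-coverage checks, and 200 000 draws for
Monte-Carlo cross-checks of the closed forms.

## Known limitations

* Constant accrual only: Weibull waiting times, piecewise regression
  models, and adaptive/hedging priors are out of scope.
* No formal goodness-of-fit test for the exponential assumption — the
  diagnostics are graphical/numerical summaries.
* The site review is a pooled model divided by J, not a hierarchical
  multi-site model; it flags relative under-performance, not site-specific
  rates.
* Calendar-date parsing assumes ISO-8601 dates and converts months via the
  mean Gregorian month (30.4375 days).
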