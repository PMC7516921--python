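# Methods

## Model and criteria

All criteria are cost functions over the residuals `ε_i = z_i − f(x_i, y_i)`
of a candidate surface `f`, in natural logarithms:

| criterion | definition |
|---|---|
| AIC | `n·ln(MSE) + 2k` |
| BIC | `n·ln(Var) + k·ln n` |
| AIC_H / BIC_H | spread divided by the residual entropy `H` |
| AIC_GF / BIC_GF | spread multiplied by `(1+Z²)/H` |

`MSE` is the mean of squared residuals and `Var` their *population* (1/n)
variance, so `MSE = Var + mean(ε)²` holds exactly.  This identity is the
mechanism the benchmark probes: under noise with mean μ ≠ 0 the true
model's MSE carries the extra term μ², while a least-squares fit of any
family containing a constant direction absorbs μ and sheds that term.  A
Gaussian likelihood form `−2 ln L + penalty` (ML variance plugged in) is
provided as an oracle; it equals the residual AIC plus the
model-independent constant `n(ln 2π + 1)`, and the test suite asserts this
to 1e−9.

### Residual entropy

`H = −Σ p_i ln p_i` over an equal-width histogram of the residuals with
`B = max(2, ⌈√n⌉)` bins spanning that residual vector's own range, floored
at `ε = 1/n` so a degenerate single-bin histogram cannot zero a criterion
denominator (the summary records when the floor fired).  Binning is
configurable (`n_bins`, explicit `bin_edges`).

The histogram is **per model** by default.  An earlier variant shared
pooled-range edges across candidates; when one candidate's residual range
is orders of magnitude wider than another's (which happens whenever the
fitted family cannot reproduce the generating surface), the narrower
model's histogram collapses into a single occupied bin, H degenerates to
the floor, and the `1/H` factor penalises precisely the model whose
residuals are cleanest.  With a common bin *count* instead, H is a shape
statistic on the same `[0, ln B]` scale for every candidate, which is the
comparable quantity the entropy upgrade needs.  Pooled edges remain
available (`share_entropy_bins` in the benchmark, `bin_edges` in the API).

### Goodness-of-fit z-scores

The reference distribution is the *known* noise law — fully specified, no
parameters estimated from the sample — so no composite-null corrections
(Lilliefors etc.) apply.  The z-score is the raw statistic normalised so
that it vanishes under the null as n → ∞ and stays Θ(1) under a fixed
alternative:

* **K–S**: `Z = D_n`, the sup-distance between ECDF and reference CDF.
  For the discrete Poisson reference the sup is evaluated over the union
  of the integer support and the sample points, checking both one-sided
  ECDF limits against the step CDF.  Note `D_n ≤ 1`, so `(1+Z²) ≤ 2`: the
  K–S version can inflate a criterion by at most `n·ln 2`, which bounds
  its discriminating power when the wrong model has a large MSE advantage
  (see Limitations).
* **Anderson–Darling**: `Z = A²/n` with
  `A² = −n − (1/n)·Σ (2i−1)[ln u_(i) + ln(1 − u_(n+1−i))]`, `u` the sorted
  reference-CDF transforms, clipped to `[1e−12, 1−1e−12]` so boundary
  points keep the statistic finite.  A sample whose u-values are all
  degenerate (entirely outside the reference's support) raises a numerical
  error; the benchmark excludes such replicates and counts them.
* **Chi-squared**: `Z = χ²/n` on `max(2, ⌈2n^{2/5}⌉)` equiprobable bins
  (capped at n/5) for continuous references, or on the integer support for
  Poisson, with greedy tail-merging until every expected count is ≥ 5;
  `df = #bins − 1`.

An alternative standardisation `zscore_mode="pvalue"` maps the p-value
through the upper-normal quantile (`Z = max(0, Φ⁻¹(1−p))`, with Stephens'
case-0 approximation for the A–D p-value).  It is offered for sensitivity
analysis only: under the null it is an O(1) random variable, so the GF
criteria no longer converge to the entropy versions.

## Fitting

The polynomial family (nine terms up to `x²`, `y³` and the mixed terms
`xy, x²y, xy²`) is linear in its parameters and solved exactly by least
squares; a normal-equations oracle in the tests agrees to 1e−8.  The
exponential family `a·x·e^(bx+cy) + d·x·e^(ex+fy) + g` and the power law
`c·xᵃ·yᵇ` are fitted by damped (trust-region) least squares in the
original space — the power law is *not* log-linearised, because the error
model is additive — from a seeded multi-start grid (8 sign/scale starts,
plus a log-regression start for the power law when all values are
positive), keeping the lowest-SSR solution.  Exponential fits are
canonicalised by ordering the two exponential terms by their x-rate, since
the family is invariant under swapping them.  On noiseless data all three
families recover their generating parameters to better than 1e−5 relative
error.  Non-convergent fits raise and are excluded (and counted) in scans.

## The synthetic benchmark

Each replicate draws `n` covariate pairs uniformly on the rectangle
`0 < x < 10`, `−10 < y < 10` (the power-law case uses `0.5 < y < 10` so
`y⁻¹` is defined), evaluates a generating surface and adds i.i.d. noise
from one of four laws with the study parameterisations: Gaussian(μ=0, σ=3),
Uniform(−1, 1), Poisson(λ=10), Gamma(k=3, θ=2; shape–scale).  The noise is
deliberately uncentred.  Two candidates are compared:

* **Correct** — the generating surface with true parameters.  Its `k`
  counts the free constants of the generating expression: 1 for
  `100(x+y)e⁻ˣ` (the scale), 2 for `3x + x² + y + 3y⁴` (the two
  coefficients 3), 3 for `c·x³y⁻¹` (which lies inside the fitted family);
  configurable, and `refit_correct` refits the family instead.
* **Alternative** — the case's fit family estimated by least squares.

Scans cover `n ∈ {50, 100, 200, 500, 1000, 2000}` by default (the grid is
configurable; the axes of interest start around n ≈ 100, below which the
GoF statistics are noisy) with 10 replicates per point, reporting means
and standard deviations; the intensity scan varies σ (Gaussian) or λ
(Poisson) at fixed n.  One master seed expands through `SeedSequence` into
per-replicate seeds, making every scan CSV byte-reproducible.

The headline measurements (also recomputed by `scripts/acceptance.py` at
n = 1000, 20 replicates) are: under Poisson/gamma noise the GF criteria
rank the correct model best in 100% of replicates in all three cases
(chi-squared z); under Gaussian/uniform noise all six criteria agree on
the best model whenever the candidates are distinguishable.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: uniform covariates
on a rectangle, i.i.d. additive noise, known noise law, two candidates.
It does not emulate heteroscedastic or multiplicative noise, covariate
error, model families outside the three implemented, or an unknown noise
distribution — the GF criteria *require* the reference law, and their
performance with a misspecified reference is untested here.  Passing
benchmarks therefore show the criteria separate candidates under known
additive noise, not that they are robust to noise-model misspecification.

## Design choices and limitations

* **Exponential/polynomial cases have structurally poor Alternatives.**
  The double-exponential family cannot reproduce the `y·e⁻ˣ` part of
  `100(x+y)e⁻ˣ`, and the cubic-in-y polynomial cannot track `3y⁴`; the
  fitted Alternatives in those cases carry large bias (MSE ≈ 1.7·10³ and
  ≈ 4.8·10⁶ versus ≈ 110 for the correct model under Poisson(10)).  There
  the classic criteria also pick the correct model and the GF upgrade is
  confirmatory.  The discriminating regime is the power-law case, where
  the fit family contains the generator: the Alternative absorbs the
  noise mean, classic AIC always prefers it, and only the GF criteria
  (and, via the added bias variance, BIC) recover the truth.
* **K–S boundedness.**  Because `D_n ≤ 1`, AIC_GF with the K–S z cannot
  overturn an MSE ratio above 2; the chi-squared (default recommendation
  for selection work) and A–D z-scores are unbounded and do not share this
  ceiling.  The K–S default of the scan config is kept for its robustness
  and distribution-free interpretation.
* **Near-ties under symmetric noise.**  When the fitted family contains
  the generator and the noise is zero-mean, the two candidates differ
  only by the ~k/n overfitting margin; classic criteria then pick the fit
  while the H/GF versions systematically pick the truth.  Criterion
  families genuinely disagree in this regime — the disagreement is the
  upgrade working, not instability.
* Degenerate inputs: zero-spread residuals raise rather than return −∞;
  the entropy floor and A–D clipping are logged; chi-squared needs n ≥ 10.
* `k` for a non-refitted Correct model is a convention (printed constants),
  exposed as configuration; criterion gaps at n = 1000 dwarf the penalty
  differences involved.
* The power-law generator's scale `c` is 1 by default and configurable.

## Problem sizes

Tests and the acceptance script use n = 1000 with 10–20 replicates for
selection rates, n = 10² vs 10⁴ with 50 seeds for null-convergence
medians, and 400-point noiseless fits for recovery — sizes at which every
reported rate is stable across reruns with different master seeds.
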