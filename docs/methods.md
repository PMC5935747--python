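# Methods

## The two growth curves

`sigrow` models the biomass `w(t)` (grams) of a determinate-growth organism
— in practice a crop plant — over time `t` (days) with two four-parameter
sigmoidal curves that share a biological reading of their time parameters:
growth starts at `t_b`, ends at maturity `t_e`, and the maximum biomass is
`w_max = w(t_e)`.

### NSG (new sigmoidal growth)

The NSG specifies the *rate*. It transplants the square-root
temperature–growth relation of Ratkowsky bacterial growth kinetics onto the
time axis: with `√r = c (t − t_b)(1 − e^{k(t − t_e)})`, the growth rate is

    r(t) = c² (t − t_b)² (1 − e^{k(t − t_e)})²,

zero at `t_b` and `t_e` and positive between. Biomass is the integral of
this rate from `t_b`. Expanding the square gives three analytically
integrable terms; with `x = t − t_b`,

    w(t) = c² [ x³/3 − 2·I₁(t) + I₂(t) ]
    I₁(t) = e^{k(t−t_e)} (x²/k − 2x/k² + 2/k³) − e^{k(t_b−t_e)} · 2/k³
    I₂(t) = e^{2k(t−t_e)} (x²/(2k) − x/(2k²) + 1/(4k³)) − e^{2k(t_b−t_e)} / (4k³).

Within `[t_b, t_e]` every exponent is non-positive, so the closed form is
overflow-free by construction; the tests certify it against adaptive
quadrature of the rate to better than 1e-8 relative over random parameter
draws. Because the model depends on `c` only through `c²`, the sign of `c`
is unobservable; the non-positive representative is canonical and enforced
by the parameter container.

Beyond `t_e` the squared rate becomes positive again, so the raw
antiderivative resumes growing. The package clamps NSG biomass at
`w(t_e)` for `t > t_e` by default (growth has ceased at maturity); the raw
analytic continuation is available behind the `clamp_after_te` flag, with a
saturating exponential guard against overflow.

### BSG (beta sigmoidal growth)

The BSG specifies the *biomass* directly, as the flexible beta-function
growth curve with unit shape exponent:

    w(t) = c_m (t − t_b) · (2t_e − t_m − t)/(2t_e − t_m − t_b)
           · ((t − t_b)/(t_m − t_b))^{(t_m − t_b)/(t_e − t_m)},

where `c_m` is the maximum growth rate, attained at `t_m ∈ (t_b, t_e)`.
The curve is zero at `t_b`, peaks with zero slope at `t_e`, and is undefined
for `t < t_b` (fractional power of a negative base); predictions below
`t_b` return 0, and direct evaluation there raises a domain error. The
package also ships the simplified variant with the growth start pinned at 0,
`w(t) = w_max (1 + (t_e−t)/(t_e−t_m)) (t/t_e)^{t_e/(t_e−t_m)}`, together
with its rate function; a quadrature test verifies that the curve is the
exact antiderivative of the rate. (Printed forms of this simplified curve
circulate with a garbled power term that violates `w(t_e) = w_max`; the
form here is the one certified by the integral.)

## Estimation

Parameters are estimated by unweighted least squares — minimizing the sum
of squared errors (SSE) between observed and predicted biomass — because
the measurement protocol behind typical biomass series (pooled, dried
plants) does not justify a particular heteroscedastic weighting. The
search pipeline is:

1. **Differential evolution** (scipy, `best1bin`, population 15×dim,
   ≤ 500 generations, latin-hypercube init, population-convergence
   tolerance 1e-8, vectorised population evaluation) inside a data-driven
   parameter box. Structural violations (`k ≤ 0`, `t_e ≤ t_b`, BSG `t_b`
   at or above the first observation time, `t_m` outside `(t_b, t_e)`)
   return a large finite penalty (1e12 + violation) rather than raising, so
   the global search stays total.
2. **Nelder–Mead polish** from the DE optimum (function tolerance 1e-12,
   bounds-clipped).
3. **k-profile refinement (NSG only).** The NSG likelihood has a long,
   curved, nearly flat valley in `(k, t_e)`: once `k(t_e − t_b)` is large
   the exponential shoulder occupies a sliver below `t_e`, and very
   different `(k, t_e)` pairs predict numerically indistinguishable
   trajectories. Simplexes (and prematurely collapsed DE populations)
   stall in this valley. Because the model is well conditioned once `k`
   is fixed, the profile over `k` is the robust object to search: the
   stage minimises `(c, t_b, t_e)` at fixed `k` over a geometric grid
   spanning the admissible range (multi-started from the incumbent and a
   data-driven guess), densifies around the winner, and then — among all
   profile points whose SSE is numerically indistinguishable from the best
   (an absolute window of ~100× the double-precision residual floor
   `n·(ε·max w)²`, or 1e-9 relative for noise-dominated fits) — keeps the
   **smallest** `k`. The `t_e` bias grows monotonically along the flat
   large-`k` branch, so the lower rim of the indistinguishable set is the
   least-biased point. A final full polish finishes from there.

Every stage is deterministic given the seed, respects the search box
(bound-touching optima are *flagged*, never hidden), and the returned SSE
is never worse than the DE stage's. The recovered `c` is canonicalised to
`c ≤ 0`.

**Default search box** (from the observed series): `t_b ∈ [t_min − 3R,
t_min + R/2]` and `t_e ∈ [t₀.₉₅ − Δt, t_max + 3R]`, where `R` is the
observed time range, `t₀.₉₅` the first time the series reaches 95% of its
observed maximum and `Δt` the median sampling interval (maturity can
precede the first near-maximal sample by up to one interval); NSG
`c ∈ [−5, 0]`, `k ∈ (0, 50]`; BSG `c_m ∈ (0, 10·max(w)/R]`, `t_m` boxed
like the times with the ordering `t_b < t_m < t_e` enforced by penalty.

**Goodness of fit.** `R² = 1 − SSE/SST`. The AIC uses the least-squares
form `n·ln(SSE/n) + 2p` with `p = 4` by default; the full-Gaussian constant
`n(ln 2π + 1)` is available by configuration and cancels in comparisons.
A perfect fit (SSE = 0) maps to AIC `−inf`. Model comparison fits both
curves with the same seed and convention and prefers the smaller AIC; exact
ties go to the NSG (a documented, arbitrary convention).

## Synthetic data

No raw observations behind the bundled crop parameter sets are publicly
available, so all validation runs on synthetic series: the forward model
evaluated on an observation grid plus seeded Gaussian observation noise,
either additive (σ in grams) or proportional (a coefficient of variation),
floored at zero — a slight truncation of the noise distribution consistent
with non-negative dry mass. The default design is 30 even observations
from `t_b + 1` to `t_e` with proportional noise at cv = 0.02, chosen to
resemble published field trajectories of the eight bundled crops. What
the generator does **not** emulate: irregular field sampling schedules,
between-plant variation and pooling, process (growth) noise, and any
post-maturity observations. Passing recovery tests therefore demonstrate
the estimator's correctness and precision under clean observation noise,
not robustness to all features of real field data.

`recovery_experiment` (simulate → refit → summarise over seeded
replicates) and `model_selection_experiment` (simulate → fit both → count
AIC preferences) are the validation harnesses; both derive all replicate
seeds deterministically from one master seed.

## Identifiability limits (what the tests measure)

* **`k` is weakly identified when `k(t_e − t_b) ≫ 1`.** The exponential
  factor is ≈ 0 over almost the whole growth window, and on a 30-point
  noiseless grid the SSE difference between the true `k` and a broad flat
  branch of larger-`k` alternatives falls to ~1e-24 g² — at the resolution
  of double precision arithmetic on the data themselves. The profile
  refinement recovers `t_e` to ≤ 0.1% and `w_max` to ≤ 0.1% on every
  bundled crop row regardless, but recovered `k` for the steep-shoulder
  crops (mung bean, cotton) should be read as "large", not as a point
  estimate.
* **`w_max` is bimodal under noise when sampling stops at maturity.** With
  2% observation noise on the default design, roughly a third of noise
  realisations are *better* fitted (genuinely lower SSE, R² > 0.999) by a
  low-`k` trajectory whose maturity lies beyond the sampled window, because
  no post-plateau observation pins the curve down. Such fits carry a
  `maturity estimate extrapolates beyond the observed time span` flag and
  their `w_max` is not a measurement. Among the non-extrapolating majority
  of replicates, the median `w_max` error at cv = 0.02 is ~1.2%. The
  practical reading: to estimate yield, sample past the plateau.
* **Plateau-only series** (biomass already saturated at the first
  observation) are fittable but flagged: `t_b` is unidentifiable below the
  observed range.

## Numerical choices

* Exponentials are evaluated in saturating form (exponent capped at 700)
  wherever a search candidate or an unclamped evaluation could overflow;
  the BSG power term is computed in log space with the same cap, and BSG
  residuals are clipped at 1e150 so the DE objective stays finite.
* The AIC requires `SSE > 0` and `n > p`; SSE = 0 yields the `−inf`
  sentinel rather than an exception.
* `R²` requires non-zero biomass variance; constant series raise a
  degenerate-series error before fitting starts.
* Fit reproducibility is bitwise for a fixed seed; the tests assert it.
* Problem sizes in the validation suite — 30-point designs, 50-replicate
  recovery, 100-replicate selection experiments (60 in the acceptance
  script) — were chosen as the smallest designs at which the statistics of
  interest stabilise.

## Known limitations

* No uncertainty quantification (confidence intervals, bootstrap) on the
  fitted parameters; the recovery experiment is the precision instrument.
* Unweighted least squares only; no heteroscedastic weighting option.
* Single-series fits; no hierarchical pooling across series, covariates,
  or temperature-driven variants of the rate model.
* The AIC constant convention of the original analyses of the bundled crop
  rows is unknown, and their raw data are unavailable, so published
  per-crop R²/AIC values cannot be recomputed — only the arithmetic from
  parameters to `w_max` and the qualitative AIC ranking are reproducible,
  and those are what the acceptance checks cover.
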