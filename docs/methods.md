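# Methods

## Signal model

A time-domain FLIM pixel is a TCSPC histogram of photon arrival times over
`T = 256` bins of width `h = 0.039` ns (window `T·h ≈ 9.98` ns).  Its
expectation is an exponential mixture convolved with the instrument response
function (IRF):

    E[c(t)] = IRF(t) * P · Σ_k α_k exp(−t/τ_k) + b,

with component lifetimes `τ_k` (ns), amplitude fractions `α_k ≥ 0, Σα_k = 1`,
intensity scale `P` and a constant dark-count rate `b` per bin (default 0).
Counts are independently Poisson around this expectation.  The IRF is a
unit-peak Gaussian, `IRF(t) = exp(−((t−t0)h)² · 4 ln 2 / FWHM²)`, with
`FWHM = 0.1673` ns and peak at bin `t0 = 14` (1-based), matching a two-photon
TCSPC acquisition.  Convolution is linear (full convolution truncated to the
first `T` bins), never circular: wrapping would alias long-lifetime tails
into the early bins.  The signal part of each expected curve is rescaled to a
prescribed total (or peak) photon count before noise is drawn.

Summary lifetimes for two-component decays:

* amplitude-weighted `τ_A = α τ1 + (1−α) τ2`,
* intensity-weighted `τ_I = (α τ1² + (1−α) τ2²) / τ_A`,

with `τ_I ≥ τ_A` always (Cauchy–Schwarz).

## The estimator

The core estimator is an extreme learning machine: a single-hidden-layer
network whose input weights `W` (L×m) and biases `b` are drawn once, i.i.d.
uniform on [−1, 1], and never updated.  With sigmoid features
`A[i,l] = σ(w_l·x_i + b_l)`, the output layer solves the ridge problem

    β = argmin ‖Aβ − Y‖² + λ‖β‖²  =  (AᵀA + λI)⁻¹ AᵀY,

computed by a symmetric positive-definite solve (Cholesky route), with an
augmented least-squares fallback, and the SVD minimum-norm solution when
`λ = 0`.  Training is exactly one linear solve; there is no iteration and no
back-propagation.

Inputs are unit-peak normalized histograms (counts divided by their maximum),
making inference invariant to total intensity; an all-zero pixel has no
defined shape and must be masked upstream.  Mono models regress `τ`;
bi-exponential models regress `(τ1, τ2, α)` and derive `τ_A`, `τ_I` — the
averages are never regressed directly.  Raw outputs are clipped to the
training ranges because a linear readout can extrapolate to unphysical
values; image-level display ranges, by contrast, only *flag* out-of-range
pixels (they are never silently clipped).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| hidden nodes `L` | 500 | node sweep shows no material training-MAE decrease beyond ~500 at moderate cost |
| ridge `λ` | 1e-3 | mild regularization on unit-peak inputs; near-unregularized at H ≥ 5000 but stabilizes small training sets |
| activation | sigmoid | standard choice for random-feature regression of bounded inputs |
| training size H | 20,000 | full-size training set; scaled studies use 5,000 |
| mono `τ` range | [0.1, 5] ns | sampling range of the training prior |
| bi ranges | τ1 ∈ [0.1, 1], τ2 ∈ [1, 3] ns, α ∈ [0, 1] | sampling ranges of the training prior |
| training intensity | uniform total counts [25, 2000] | spans the low-count regime up to bright pixels |

All parameters are drawn uniformly and independently over their ranges; the
sampling distribution inside each range is a modeling choice (uniform) since
only the ranges are physically prescribed.

### Error structure

The random-feature basis itself is essentially exact here: trained on
noiseless curves, the mono network recovers clean lifetimes to ~1e-4 ns.
The practical error floor (~0.04 ns median over [0.1, 5] ns) is *noise
attenuation*: training exemplars carry Poisson noise in the inputs, and ridge
regression on noisy inputs shrinks toward the prior mean (classical
errors-in-variables attenuation).  Consequently the network is robust and
fast at low counts but does not converge to zero error as test histograms
become arbitrarily clean — an exact-model iterative fit overtakes it there.
The comparison tables produced by `pipeline.run_benchmark` show exactly this
crossover; see Known limitations.

## Baseline estimators

**NLSF.** Damped least squares (`scipy.optimize.least_squares`, TRF) on the
IRF-convolved model with free amplitude and positivity bounds; default inits
τ = 2.5 ns (mono) and (0.5, 2.0, 0.5) (bi), amplitude start matched to the
histogram total.  Non-convergence is reported via a flag, never raised.  The
estimate is init-sensitive, a documented weakness of iterative fitting.

**CMM.** The histogram centroid (bin centers) minus the IRF centroid
estimates `τ_I`.  A finite window `T_w` biases the centroid to
`τ − T_w e^{−T_w/τ}/(1 − e^{−T_w/τ})`; `correct_window=True` inverts this
relation numerically.  The estimate is scale-free.

**BCMM.** With power moments `m_j = μ_j / j!` of the background-subtracted,
IRF-centroid-shifted decay, an untruncated bi-exponential satisfies
`m_j = w1 τ1^j + w2 τ2^j` where `w_k = α_k τ_k / Σ α_k τ_k`, so `(τ1, τ2)`
are the nodes of a two-point quadrature (Prony/Hankel system) and `α`
follows from the node weights.  This reconstruction of the published method
class is anchored by its noiseless-recovery property.  Finite windows bias
the raw moments severely — at `window ≈ 3.3 τ2`, over half the third
moment's mass lies beyond the window and the raw Hankel system can become
degenerate — so the default bias correction solves the *windowed* moment
equations (model moments evaluated on the same bin grid, making the
noiseless fixed point exact) with a hybrid Newton root find seeded by the
Prony solution.  Unphysical moment systems (complex/negative nodes,
effectively mono decays) return `converged=False` with the centroid lifetime
as fallback; a flag warns when `window < 5 τ̂2`.

**Phasor.** `g + is = Σ c_k e^{iωt_k} / Σ c_k` at `ω = 2π·harmonic/(T h)`
(first window harmonic by default; the laser period is irrelevant for
self-contained simulated windows).  With a measured IRF the histogram phasor
is divided by the IRF phasor, so the IRF itself calibrates to exactly (1, 0).
Uncalibrated transforms of decays with the time origin at bin 0 get the
half-sample phase `e^{iωh/2}` (bin centers), after which sampled
mono-exponentials satisfy the semicircle identity `g² + s² = g` to
~(2π/T)²/8 ≈ 7.5e-5 — truncation cancels exactly at harmonic frequencies
for origin-at-zero decays.  Gaussian-IRF-calibrated decays with τ near 5 ns
deviate from the semicircle by up to ~2e-2: a real incomplete-decay effect
of the 10 ns window, not a numerical artifact.

## Phasor projection analysis

For a two-population field of view, pixels' phasor points are filtered by
total intensity, a line `s = a·g + b` is least-squares fitted through the
cloud, intersected with the universal semicircle `(g−½)² + s² = ¼` to give
endpoints A (larger g, shorter-lifetime end) and B, and each pixel receives
the normalized chord projection

    ρ = [(g−g_B)(g_A−g_B) + (s−s_B)(s_A−s_B)] / D²,

so ρ(B)=0, ρ(A)=1, and ρ is affine along the chord.  The division is by D²
(not D) so that ρ spans [0, 1].  Endpoint polarity is configurable
(`short`: ρ=1 at the short-lifetime end, the default; `long` flips it).

ρ is a *photon-weighted* chord coordinate: a mixture pixel sits at the
intensity fraction `w1 = ατ1/(ατ1+(1−α)τ2)` along the chord, which is
monotone in α (hence in τ_A) but strongly nonlinear — populations dominated
by the long component compress into a small chord segment.  The synthetic
two-population fixture is therefore configured bright (cells 1000–4000
counts, α ∈ [0.1, 0.5]; nanoprobe blobs 2000–8000 counts, α ∈ [0.7, 0.95]),
emulating a full multi-cycle acquisition, so the projection resolves both the
between-population gap (bimodal ρ) and the within-population lifetime spread
(rank correlation with true τ_A above 0.9).  At a few hundred counts per
pixel the within-population ranks wash out while the two modes remain
separable — the regime the low-count protocol probes.

## Evaluation metrics

* `F = √I · (δx/x)`: photon-economy value with `I` the mean detected photon
  count over the batch, `δx` the sample (n−1) standard deviation of the
  estimates, `x` the true parameter.  F = 1 is the photon-limited optimum;
  F of an efficient estimator is approximately count-invariant.  The
  centroid estimator on an ideal configuration (instantaneous IRF, window ≫
  τ) attains F ≈ 1, being the sample mean of arrival times.
* `R² = 1 − SS_res/SS_tot`, absolute error `|g − ĝ|`, relative bias
  `mean((ĝ−g)/g)` (overestimation positive), MSE/MAE.
* SSIM via scikit-image with the joint value range as default dynamic range.
* Region summaries report per-region (μ, σ) over valid pixels with
  population (ddof = 0) σ, the convention used when quoting a single image's
  spread; the F-value's δx keeps the sample convention.

## Pipeline and experiments

Estimators share one fit-one-histogram interface (`estimate` /
`estimate_batch`); the pipeline never special-cases a method.  Pixel
filtering is by absolute total counts (default 100) or by fraction of the
brightest pixel (default 5% in the low-count protocol).  Reconstruction
bookkeeping guarantees `|valid| + |filtered| = total` and flags, rather than
clips, display-range violations.

`run_benchmark` replays the comparison experiments at desk scale —
64×64 phantoms, 200–500 Monte-Carlo replicates per condition — chosen to
keep a full run in minutes while preserving the statistical structure; all
problem sizes are recorded in the outputs and every stage derives its seed
from one root seed (bit-reproducible reruns).

The low-count protocol emulates shorter acquisitions by binomial thinning of
a single full-exposure cube: keeping each photon with probability f turns
Poisson(μ) bins into Poisson(fμ) bins, exactly the statistics of
proportionally fewer scanning cycles, without re-simulating.

## What the synthetic data does and does not emulate

Emulated: IRF convolution, Poisson counting noise, per-pixel count ranges
from tens to thousands, mono/bi-exponential mixtures, two-population
lifetime contrast, exposure scaling.  Not emulated: detector dead time and
pile-up, afterpulsing, incomplete-decay wrap from the 80 MHz excitation
period, IRF drift/wavelength dependence, spatial correlations
(scattering, bleed-through), autofluorescence spectra and real nanoprobe
photophysics.  Passing tests therefore certify the estimators' statistical
behavior under the stated model, not performance on any particular
instrument.

## Numerical choices

* Ridge solve: Cholesky-type `solve(..., assume_a="pos")`; SVD lstsq when
  λ = 0 (minimum-norm) or on failure.
* NLSF bounds keep lifetimes in [1e-3, 50] ns and α in [0, 1]; max 200
  residual evaluations per pixel by default (2000 in precision tests).
* BCMM root find runs in (log τ1, log τ2, logit α) to stay in-domain, with
  merged-node results (τ2/τ1 < 1+1e-6) demoted to the mono fallback.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; child seeds stay below 2³¹.
* 1-based `t0` is the external (file/CLI) convention; arrays are 0-based
  internally.

## Known limitations

* The network's attenuation floor means iterative fitting with an exact
  model and good initialization overtakes it on bright, well-modeled pixels
  (see Error structure); the comparative advantage concentrates at low
  counts, model mismatch, and throughput.
* In the three-band τ_A phantom the band with α → 1 makes τ2 nearly
  unidentifiable; the network's τ2 output reverts toward its prior mean,
  costing it accuracy there relative to a bounded exact-model fit.
* BCMM at a few hundred counts is fragile (third-moment noise); fallbacks
  keep it total but its MSE in the low-count band is an order of magnitude
  above the network's.
* K > 2 components, vendor file formats (.sdt) and hardware deployment are
  out of scope.
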