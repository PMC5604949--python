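# Methods

`hilbo` implements human-in-the-loop (HIL) optimization of a gait
parameter — walking step frequency — against a noisy, slowly-responding
physiological objective: metabolic cost measured by breath-by-breath
indirect calorimetry. This note describes the models, the default
parameters and why they have the values they do, what the synthetic
subject does and does not emulate, and the numerical choices that an
implementation has to make but a protocol description usually leaves
open.

## Instantaneous-cost estimation

Gas-exchange rates per breath (VO2, VCO2 in mL/min) are converted to
metabolic power with the Brockway equation,

    P [W] = (16.58 · VO2 + 4.51 · VCO2) / 60,

with the energy-equivalent coefficients (J/mL) exposed as overridable
module constants.

The measured respiratory response lags the mechanical demand. We model
the breath-level response as a first-order system,

    r_i = (1 − h_i/τ) r_{i−1} + (h_i/τ) c_i,

where `r_i` is the power at breath `i`, `h_i` the time since the
previous breath, `τ = 42 s` the respiratory time constant, and `c_i` the
latent *instantaneous* cost. Inverting the recursion,

    c_i = r_{i−1} + (τ/h_i)(r_i − r_{i−1}),

recovers `c_i` exactly on noiseless data (a property the test suite
checks to machine precision against the forward model). The first breath
seeds the state; inversion starts at the second breath, so a window of N
breaths yields N−1 samples.

Two summaries of the inverted samples are used:

* **zero-order** (Bayesian optimization): the sample mean — an OLS
  constant fit; 40-breath windows (~2–3 min).
* **linear** (gradient descent): OLS of `c_i` on the paired measured
  step frequencies, giving `c(x) = λ1·x + λ0`; 2 × 30-breath windows at
  ±5% of preferred frequency. Under the linear model the symmetric
  difference quotient equals `λ1` exactly, so the fitted slope *is* the
  gradient estimate. A forward-model least-squares fit (propagate the
  candidate `λ` through the dynamics and match the measured responses)
  is available behind `method="forward"`; it agrees exactly with OLS on
  noiseless data and amplifies noise less, but plain OLS on the inverted
  samples is the default because it is the estimator the experimental
  protocol describes.

Inversion amplifies breath noise: for i.i.d. noise of SD `s` on `r`, each
inverted sample has SD `s·√((1−τ/h)² + (τ/h)²) ≈ √2·(τ/h)·s` — about
15·s at τ = 42 s and 4 s breaths. Averaging over a window cancels most of
this (the sum telescopes), but irregular breath timing makes the
cancellation imperfect; this is why windowed estimates are noisier than
a naive `s/√N` argument suggests, and the simulator's noise calibration
(below) is done by Monte Carlo rather than by that formula. No outlier
rejection is applied by default (an optional 3-SD trim exists).

Step frequency is estimated from the thigh flexion angle: the signal is
smoothed with a 0.15 s moving average, maxima are detected with a 0.3 s
refractory period and a minimum prominence of 10% of the signal range,
stride time is the inter-maximum interval, and step frequency is twice
the stride frequency (symmetry assumption) averaged over the last four
steps. The smoothing window, refractory period and prominence floor are
detector details chosen here (the protocol specifies only maxima
detection); they suppress double-counting on noisy signals and shift
peak positions negligibly for symmetric peaks.

## Gaussian-process surrogate

A zero-mean GP with squared exponential kernel
`k(x,x') = σ² exp(−(x−x')²/(2l²))` and i.i.d. observation noise `σn²`.
The noise variance enters **only** the diagonal of the Gram matrix
`K + σn² I`; adding it to every kernel entry as well would double-count
noise in the standard posterior formulas

    E[c*] = k*ᵀ (K + σn² I)⁻¹ y,
    s*²   = k(x*,x*) − k*ᵀ (K + σn² I)⁻¹ k*.

The reported predictive variance is that of the latent function (no
`+σn²` term), because expected improvement targets the latent cost.

Metabolic costs are far from zero (≈4.5 W/kg gross), so raw targets
under a zero-mean prior would make distant predictions revert to 0 and
distort the acquisition. Targets are therefore centred by their sample
mean before fitting and the offset is restored in predictions; this is
logged as a modelling choice and can be disabled.

Hyperparameters θ = (σ², l, σn²) maximise the log marginal likelihood

    −½ yᵀ(K+σn²I)⁻¹y − ½ log|K+σn²I| − (n/2) log 2π,

via L-BFGS-B in log-parameter space with analytic gradients, 10 random
restarts drawn log-uniformly within bounds, best restart wins. Default
bounds scale with the data: l ∈ [0.02, 2]·(domain width),
σ² ∈ [10⁻⁴, 10²]·var(y), σn² ∈ [10⁻⁶, 1]·var(y); a jitter of
10⁻¹⁰·tr(K)/n stabilises the Cholesky factorisation. With fewer than two
observations no fit is attempted. If the targets are exactly constant
(var(y) = 0, possible with a degenerate evaluator) a small positive
variance floor keeps the bounds valid.

## Bayesian optimization

Search domain: [0.75, 1.25] × preferred step frequency. The protocol
never states the BO domain explicitly; the initial-design envelope is
adopted and proposals are clipped to it.

* **Initial design**: one uniform draw from each third of the domain
  (75–91.7%, 91.7–108.3%, 108.3–125% of preferred), order randomised.
* **Loop**: refit hyperparameters after every evaluation (including
  while the initial design completes, once n ≥ 2), then maximise
  expected improvement

      EI(x) = s*·(u·Φ(u) + φ(u)),  u = (μ_best − E[c*])/s*,

  with μ_best the minimum posterior *mean* over evaluated points (not
  the minimum raw observation), and EI ≡ 0 where s* = 0. Maximisation
  uses bound-constrained local search from the domain endpoints, the
  best points of a 257-point scan, and 10 random restarts; exact ties
  break to the lowest frequency; if EI vanishes identically (degenerate
  posterior) the maximum-variance point is proposed instead, logged.
* **Budget**: 3 initial points + 17 EI iterations = 20 evaluations
  (the protocol description is ambiguous between 20 and 23 total;
  20 is the default, both configurable).

## Gradient descent (comparator)

Initialised at 20% above or below preferred frequency (seeded coin
flip), then for n = 0 … 14:

    J_n = λ1 (from the linear fit at x_n ± δ, δ = 5% of preferred),
    x_{n+1} = clip(x_n − α_n J_n),  α_n = A0·α0 / (A0 + n·γ),

with A0 = 3, α0 = 4×10⁻⁴ Hz·mL⁻¹·min, γ = 1. The step-size constant's
units imply costs in mL O2/min; power is converted at a fixed
respiratory exchange ratio of 0.85 (1 W ≙ 60/(16.58 + 4.51·0.85) ≈
2.94 mL O2/min). A `cost_units="watt"` option bypasses the conversion.
Whether the perturbed evaluations use commanded or measured frequencies
is immaterial under the linear model (the fitted slope is the same
estimator); the fit uses measured frequencies.

## Synthetic subject

The simulator provides ground truth the real experiment lacks. Each
subject has a net (standing-subtracted, mass-normalised) cost landscape
quadratic in relative frequency deviation,

    c_net(x) = c_min + a·((x − x_opt)/x_pref)²  (+ optional cubic skew),

with defaults c_min = 3.0 W/kg, a = 16 W/kg (walking 25% off-frequency
costs +1.0 W/kg), standing cost 1.5 W/kg — magnitudes consistent with
treadmill-walking energetics. The optimum coincides with the preferred
frequency by default (grid-search fits cluster near preferred in
practice). Breath intervals are normal around 4 s (rate 0.25/s, within
the physiologic 0.2–0.3/s band), SD 0.8 s, truncated at 1 s. Metronome
tracking error is 1% (fractional, per breath). The latent response
follows the first-order dynamics driven by the gross demand at the
measured frequency; observed power adds Gaussian noise per breath.
Cohorts draw preferred frequency ~ U(1.7, 2.0) Hz and mass ~ N(65.8,
9.7²) kg truncated positive.

**Noise calibration.** The per-breath noise SD is the bridge between
breath-level noise and protocol-level behaviour. It is fixed once, by
Monte Carlo, so that the SD of a 40-breath zero-order net-cost estimate
is ≈ 0.2 W/kg (500 seeded repetitions); this gives
`breath_noise_sd = 0.27 W/kg`. The 0.2 W/kg window-level scatter is the
stated calibration target of the generator, not a fitted quantity, and
is not revisited.

**Protocol timing.** Grid search: nine 6-minute bouts in randomised
order, last two minutes averaged, 2-minute standing rests between bouts;
standing cost from a 6-minute quiet-standing bout. Optimization
conditions: a warm-up at preferred frequency puts the respiratory state
at steady state; the state carries across consecutive evaluations and
decays exponentially toward standing demand through the 5-minute rests
inserted after every 10 BO evaluations / 5 GD iterations. Per-iteration
durations are the summed breath intervals (BO ≈ 2.7 min, GD ≈ 4 min),
and time-to-convergence sums active walking only (rests excluded; for
BO the initial design's walking time is reported separately and excluded
from the default comparison column).

**What the simulator does not emulate**: cardiovascular drift,
adaptation and learning, fatigue, day-to-day variability, RER dynamics
and asymmetric gait. Passing protocol-level tests therefore shows the
estimators and optimizers behave correctly under the stated noise and
lag model — not that a human study would reproduce the same numbers.

## Post-hoc analyses

* **Termination criteria**: step-frequency kind fires at the first
  iteration-to-iteration commanded-frequency change below ε_sf of
  preferred (1% for BO, 0.41% for GD); metabolic-cost kind at the first
  relative cost-estimate change below ε_mc = 2% (the threshold is
  dimensionless; relative to the current estimate). For BO only EI-driven
  iterations are scanned; the BO iteration count excludes the 3 initial
  points. For GD the first command is the initialization, so the change
  between commands n−1 and n belongs to iteration n.
* **Landscape baseline**: GP fit to the nine net grid costs; argmin by
  2001-point dense scan plus bounded local refinement (tolerance
  10⁻⁴ Hz), ties to the lowest frequency.
* **Error metrics**: 100·|x_conv − x_ref|/x_pref with the preferred
  frequency as denominator for both the sweep-fit and preferred
  references (the source protocol leaves the denominator undefined;
  a `denominator="reference"` option exists).
* **Energy expenditure**: Σ landscape-mean(clip(x_cmd))·mass·duration,
  J → kcal (÷4184). Net cost by default (the landscape is built net);
  the study runner adds the standing component back so reported kcal are
  gross.
* **Convergence-mean convention**: summary means are over runs whose
  criterion fired. Runs that never converge within the budget — the
  analogue of a diverging subject, which treadmill HIL studies exclude
  from analysis as outliers — are flagged and reported as convergence
  rates instead.

## Problem sizes

The in-silico replication (`replicate_study`) uses 8 subjects × 25
cohort seeds — cohort size matching the analysed study population, with
seed replication to stabilise the stochastic summary statistics. Exact
oracle suites use 100 random GP instances (n ≤ 20), 10⁶-draw Monte Carlo
for EI, and 20-seed noiseless recovery runs.

## Known limitations

* 1-D parameter space only (the data structures do not preclude more
  dimensions, but nothing multi-dimensional is implemented or tested).
* The GD ↔ BO comparison inherits every simulator idealisation above;
  in particular the stationarity of the landscape favours BO, which
  accumulates all past data.
* The quadratic landscape curvature is an assumption (grid-fit bowls
  cannot be read precisely from published figures); error-magnitude
  statistics inherit that uncertainty.
* `carry_through_rest` uses the continuous-limit exponential rather
  than simulating rest breaths; the difference is far below breath
  noise.
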