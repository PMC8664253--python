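# Methods

## Motional blur and localization precision (`motional_optics`)

A structure diffusing while its photons are collected is effectively imaged
with a broadened Gaussian.  Because variances of convolved Gaussians add,

    sigma_MB^2 = sigma_PSF^2 + MSD + r^2,    MSD = 4 D dt  (2D Brownian),
    D = k_B T / (6 pi eta r)                 (Stokes-Einstein),

where r is the hydrodynamic radius of the (uniformly labelled) structure.
The r^2 term is dropped for point-like single emitters
(`uniform_label=False`).  The localization variance is the standard
pixelated estimator

    v = (s2 + a^2/12)/N + 16 pi (s2 + a^2/12)^2 (b_m + b_v^2) / (3 a^2 N^2)

with s2 = sigma_MB^2, pixel size a, collected photons N, and background
mean/variance b_m/b_v.  The background enters through the b_m + b_v^2
grouping exactly as this form is conventionally printed; other groupings
exist in the literature and the difference only matters at high background.

Defaults and their origin:

| parameter | default | why |
|---|---|---|
| emission rate | 2 µs⁻¹ | photon flux that avoids re-excitation of the fluorophore |
| collection efficiency | 0.1 | realistic detection fraction of an epifluorescence system |
| viscosity (37 °C water) | 0.6922 mPa·s | standard value for the mobile branch |
| temperature (mobile) | 310.15 K | 37 °C physiology |
| pixel size a | 100 nm | typical camera sampling at Nyquist for FWHM ≈ 200–300 nm; config-exposed |
| background b_m, b_v | 0 | the theory curves are detector-noise-free by default; config-exposed |
| FWHM ↔ σ | 2.355 | Gaussian relation |
| cryo QY factor | 1.2 (off) | quantum-yield gain under cryo-arrest; off by default so the rt/cryo folds compare equal photon budgets |

Under cryo-arrest the medium is vitrified (viscosity up by >15 orders of
magnitude) and D is set to exactly zero rather than evaluated at a cryo
viscosity.  N is collected photons = emitted × collection efficiency,
floored.  Fold improvements (rt/cryo precision ratios) therefore depend
only on the blur chain, the photon budget, and these defaults; since the
pixel size and background of the original theory figures are not part of
the model's published constants, folds should be compared at
order-of-magnitude level, not per-point.

## Two-point resolution Monte Carlo (`resolution_mc`)

Per trial, N photons are drawn from two equal Gaussians (SD sigma_MB)
separated by d along one axis (photon split binomial 50/50 by default) and
binned with pixel size a, with a bin edge at the midpoint between the
centers.  A two-component Gaussian mixture is fitted to the bin centers
weighted by counts with a hand-written vectorized EM (batched over trials).
Choices:

- **Shared component SD** by default (the two objects are identical);
  a flag relaxes this.
- **SD floor a/√12**: the quantization SD of a single bin, preventing
  collapse onto one pixel.
- **Initialization**: means at the side-centroids around the weighted
  median, mixing weights 1/2; up to 500 EM iterations, stopping when the
  means move < 1e-4 pixels.
- **Contrast**: the fitted mixture density is scanned on 257 points between
  the two fitted means (all extrema of a two-Gaussian mixture lie in that
  closed interval); C = 1 − I_min/I_max needs a strictly interior valley,
  otherwise C = 0.  Resolved ⇔ C > 1.7 % (config-exposed).
- **Resolution**: minimum d with ≥95 % of trials resolved.  d is searched
  on a geometric grid (factor 1.25) from a/2 up to 3 sigma_MB — any
  d > 3 sigma_MB is declared resolved without simulation (the "3 sigma"
  shortcut, read as a distance since a variance is not commensurable with
  d) — followed by bisection to 2 % relative width, tie-breaking toward
  larger d.  The resolved-fraction curve is isotonically smoothed before
  thresholding.  Each simulated d consumes one child seed in evaluation
  order, so estimates are bitwise reproducible from (seed, config).

Near the detection limit (d ≈ 2.2 σ) the EM landscape is nearly unimodal
and convergence is slow; the operational resolution therefore sits at
d ≈ 2.3–2.4 σ_eff (σ_eff² = σ_MB² + a²/12) rather than at the analytic
dip onset 2 σ.  Both the mobile and the arrested branch use the same
machinery, so rt/cryo fold changes are robust to this offset; absolute
resolutions carry it.

## Cooling model (`thermal_model`)

One-sided heat flow through a water column of depth L gives first-order
kinetics T(t) = ΔT(e^(−kt) − 1) + T0 with k = κA/(c·m·L).  The heat
capacity is volumetric (4 J cm⁻³ K⁻¹); with the default mass convention
m = ρAL the model is density-free, k = κ/(c_vol L²), and initial rates
scale as 1/L².  Constants: κ = 0.5562 W m⁻¹ K⁻¹, A = 2×10⁻⁵ m²
(4-mm cover slide), T0 = 37 °C, ΔT = 233 °C to liquid nitrogen.  A literal
sample mass can override ρAL; note that a fixed 0.25 mg is dimensionally
usable but inconsistent with ρAL at the 50-µm geometry, which is why the
volumetric convention is the default.  Interval mean rates (e.g. across
the 0…−130 °C band where ice can nucleate) use the closed-form inverse of
the temperature course.

The model ignores spatial temperature gradients within the sample, the
thermal mass of the thermocouple, and coolant-side convection physics; it
is an upper-envelope estimate of thermal-diffusivity-limited cooling.

## Phasor FLIM pipeline (`flim_phasor`)

**Phasor convention.** R = Σ_b c_b·e^(+iωt_b)/Σ_b c_b at the fundamental
ω = 2π/laser period, t_b bin centers.  A monoexponential decay maps to
1/(1 − iωτ) on the universal semicircle; with bin-center sampling of the
period-wrapped decay the discrete phasor lands within ~1e-4 of the
continuous value at 256 bins, so no sampling correction is applied.

**Registration.** Phase correlation (scikit-image) on time-summed frame
images against the first frame; subpixel estimates are computed, then
rounded to integers before shifting the photon cube.  Photons shifted out
of the first frame's field of view are dropped; bookkeeping is exact.

**Background.** Two estimators, cross-checked (consistency flag at 2×):
(a) image-based — the darkest `window`×`window` region (21 px default) of
the time-summed image; the window position minimizes the window-averaged
score max(median-filtered, raw), so dead pixels cannot attract the window
and bright structure repels it; the reported value is the raw window mean;
(b) histogram-based — same darkest-window logic on the aggregate decay
histogram (median 21 bins, window 51 bins, circular on the period),
extrapolated by the bin count.  For lifetimes comparable to the laser
period the wrapped decay never returns to the true floor, so (b)
systematically overestimates; the **image-based** value therefore drives
the flat per-pixel-per-bin subtraction, and (b) serves as the cross-check.

**IRF.** Modeled as a shifted Gaussian (delay t0, width s).  The aggregate
decay's phasors at harmonics 1..5 are fitted with
M_n = 1/(1 − i nωτ) · e^(i nω t0 − (nωs)²/2) over (τ, t0, s) by least
squares.  This assumes a near-monoexponential aggregate; for strongly
multi-exponential samples the estimator absorbs decay curvature into the
IRF and a measured/user-supplied IRF should be passed instead (the
pipeline accepts one).  Correction divides the pixel phasors by the IRF
phasor at the first harmonic.

**Denoising.** A simplified weighted translation-invariant Haar scheme:
the count-scaled channels U = re·N, V = im·N and the photon image N are
decomposed with a stationary (cycle-spun) Haar transform (2 levels) and
hard-thresholded, each detail coefficient at λ = 2 times its own Poisson
noise SD, propagated from the per-pixel variances (Var U ≈ N/2, Var N = N;
for orthonormal undecimated Haar, Var(coef) is the local box mean of pixel
variances).  Hard (keep-or-kill) thresholding is used because shrinking
retained coefficients would shrink U and N by different relative amounts
and bias the ratio re = U/N; cycle spinning suppresses the blocking
artifacts.  Total photons and the photon-weighted mean phasor are restored
exactly after thresholding; the denoised photon totals become the weights
of the output.  Thresholds are model-based (Poisson), so genuinely
noise-free structured inputs are treated as if Poisson-noisy.  This is a
documented variant of the published weighted-wavelet phasor denoiser, not
a re-implementation of it.

**Three-component unmixing.** Each pixel's phasor is modeled as
f_do·R_do + f_act·R_act + f_inact·R_inact with f_i ≥ 0, Σf_i = 1 and the
donor-only photon fraction fixed (0.2 default).  That leaves one free
parameter per pixel, solved in closed form by projecting onto the
active–inactive chord and clipping to the feasible interval; the per-pixel
residual distance is reported.  Component lifetimes are spatially
invariant: 3.71 ns (donor-only), 0.9 ns (active), 3.5 ns (inactive) by
default, or globally optimized by multi-start nonlinear least squares over
(τ_act, τ_inact) with the donor-only lifetime fixed at its control value
(starts (0.9, 3.5), (0.5, 3.0), (1.5, 4.2); photon-weighted residuals).

**Molecular fractions.** Photon fractions weight states by brightness;
molecular fractions divide by lifetime (a quantum-yield proxy) and
renormalize: m_i ∝ f_i/τ_i.  The activity map is
α = m_act/(1 − m_do), excluding sensors with non-absorbing acceptors.
Apparent lifetime maps use the phase lifetime tan(arg R)/ω; pixels below
a photon threshold are NaN-masked, never zero-filled.

## Synthetic scenes (`synthetic`)

`SceneSpec` describes disk-shaped labelled structures on a dark background:
per-blob molecular activity α, expected photons/pixel (1000 by default,
a realistic confocal FLIM budget), flat background (2 counts/px/frame),
256 microtime bins over a 12.5-ns laser period, optional Gaussian IRF and
rigid per-frame drift (linear or random walk; fractional drifts use
bilinear interpolation of the intensity maps).  Decay profiles are exact
bin-integrated, period-wrapped exponentials (so incomplete decays keep the
correct phasor); expected cubes are Poisson-sampled, bitwise reproducible
from the seed, and returned together with the ground truth (α map, photon
fractions, totals, true shifts).

Photon fractions follow from α with the donor-only photon fraction held
fixed: f_act = (1−f_do)·ατ_act/(ατ_act + (1−α)τ_inact), the exact inverse
of the pipeline's photon→molecular conversion.

The `lifea2_cryo` preset uses the cryo-arrest biosensor state parameters
(3.71/0.9/3.5 ns, donor-only fraction 0.2) with three activity levels
(0.7/0.45/0.2) and a 1 px/frame drift.  The `lifea2_rt` preset is a
labelled synthetic stand-in: only the 3.04-ns room-temperature donor
lifetime is a measured value; the state lifetimes (2.5/3.0 ns) are chosen
to emulate the poorly separated room-temperature regime with its ~0.2-ns
average-lifetime drop.

What the generator does **not** emulate: optical blurring of the scene by
the PSF (blobs are rasterized sharply), detector afterpulsing and dead
time, spatially varying background, and photobleaching during the stack.
Passing round-trip tests therefore demonstrates the correctness of the
estimators under the stated noise model, not robustness to every
instrumental artifact of real acquisitions.

## Problem sizes used by tests and scripts

Unit and round-trip tests run on 16–64 px images, 64–256 bins and ≤3
frames; the Monte Carlo acceptance checks use 200 trials per candidate
separation (as do the analysis scripts), 1e4 collected photons per trial
and the geometric-plus-bisection search described above.  The resolution
fold studies in `analysis/03` use four structure sizes at a 1e5-photon
budget.  All seeds are
fixed in the scripts; `scripts/acceptance.py` derives its Monte Carlo
seeds from `--seed`.

## Known limitations

- Absolute Monte Carlo resolutions carry the EM detection offset
  (~2.3–2.4 σ_eff instead of 2 σ); fold changes are insensitive to it.
- The IRF-from-harmonics estimator is biased on strongly multi-exponential
  aggregates (by design it attributes all super-monoexponential curvature
  at harmonics 2..5 to the IRF).
- The histogram background estimator overestimates whenever the longest
  lifetime is comparable to the laser period; it is kept as a cross-check
  only.
- The three-component fit uses the first harmonic only; with three free
  fractions and one complex observation the donor-only fraction must be
  fixed, as in the underlying experimental analysis.
- The cooling model is lumped (no spatial gradient through the sample
  depth) and therefore optimistic near t = 0 for thick samples.
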