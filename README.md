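# cryoblur

Computational companion to ultrarapid cryo-arrest microscopy: why freezing a
living cell *during* observation removes a fundamental resolution barrier,
how fast a thin aqueous sample actually cools, and how to read out molecular
activity maps from photon-counting FLIM data acquired under cryo-arrest.

The package serves microscopists and method developers who want to

- quantify the **motional-blur limit**: a structure of hydrodynamic radius
  *r* diffusing with coefficient *D* = k<sub>B</sub>T/(6πη r) while emitting
  photons for a time Δt is imaged with an effective Gaussian variance
  σ²<sub>MB</sub> = σ²<sub>PSF</sub> + 4DΔt + r², and no photon budget can
  beat the 4DΔt term at positive temperature;
- evaluate the pixelated **localization precision**
  v = (σ²+a²/12)/N + 16π(σ²+a²/12)²(b<sub>m</sub>+b<sub>v</sub>²)/(3a²N²)
  with σ² replaced by σ²<sub>MB</sub>;
- estimate **two-point resolution** by Monte Carlo: photons drawn from two
  Gaussians a distance *d* apart, binned into pixels, recovered with a
  two-component Gaussian mixture, and declared resolved when the contrast
  C = 1 − I<sub>min</sub>/I<sub>max</sub> exceeds 1.7 % in 95 % of trials;
- model **one-sided cooling** of a water layer of depth L,
  T(t) = ΔT(e<sup>−κA t/(cmL)</sup> − 1) + T₀, with initial rate
  κΔT/(c<sub>vol</sub>L²);
- analyze **TCSPC FLIM stacks**: drift registration, background and IRF
  estimation from the data, first-harmonic phasor transform, wavelet
  denoising, three-component global unmixing of a FRET biosensor
  (donor-only / active / inactive), and per-pixel molecular activity maps
  α = m<sub>act</sub>/(1 − m<sub>donor-only</sub>).

A synthetic TCSPC generator (`cryoblur.synthetic`) produces stacks with
known ground truth — three-state mixture decays, IRF convolution, Poisson
noise, flat background, rigid drift — so every pipeline stage is testable
without microscope data.

## Worked example

```python
from cryoblur import motional_optics as mo, resolution_mc as rmc, thermal_model as tm

# How fast does a 13-um adherent-cell sample cool?
model = tm.CoolingModel(thickness_L=13e-6)
print(f"{tm.cooling_rate(model, 0.0):,.0f} C/s")      # 191,708 C/s

# Localization-precision fold for a 100-nm structure, 1e5 emitted photons
sigma_psf = mo.fwhm_to_sigma(100e-9)
print(f"{mo.improvement_ratio(100e-9, 1e5, sigma_psf):.1f}x")   # 16.0x

# Monte Carlo resolution fold for the same structure (200 trials/point)
fold = rmc.resolution_fold(100e-9, 1e5, sigma_psf, n_trials=200, seed=11)
print(f"rt {fold['resolution_rt']*1e9:.0f} nm vs "
      f"cryo {fold['resolution_cryo']*1e9:.0f} nm -> {fold['fold']:.1f}x")
# rt 2699 nm vs cryo 166 nm -> 16.3x
```

The initial cooling rate says vitrification-speed cooling (≳100,000 °C/s)
is reachable for thin samples; the folds say that arresting Brownian motion
buys an order of magnitude or more in both precision and resolution — more
for smaller structures, because their diffusion is faster.

The FLIM pipeline runs end to end on synthetic data:

```python
from cryoblur import synthetic as syn, flim_phasor as fp
stack, truth = syn.generate_tcspc_stack(syn.lifea2_cryo(seed=0))
result = fp.run_pipeline(stack)        # register, background, phasor, denoise, unmix
alpha = result["model"].alpha          # molecular activity per pixel
```

The numbered scripts under `analysis/` rerun these studies and write tidy
CSV tables under `results/`; a thin CLI (`cryoblur limits|resolve|cool|synth|flim`)
exposes the same computations from the shell.

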