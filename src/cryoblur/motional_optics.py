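"""Closed-form physics of motional blur.

A fluorescent structure diffusing while photons are being accumulated is
imaged not with the microscope's point spread function (PSF) but with an
effective, broadened one.  Because the variance of a convolution of
Gaussians is the sum of the individual variances, the effective variance is

    sigma_MB^2 = sigma_PSF^2 + MSD + r^2

where MSD = 4*D*dt is the mean square displacement accumulated by Brownian
motion over the acquisition time dt (2D), D follows the Stokes-Einstein
relation D = k_B*T / (6*pi*eta*r_h), and r is the radius of the (uniformly
labelled) structure itself.  Substituting sigma_MB^2 for sigma_PSF^2 in the
standard pixelated localization-precision formula

    v = (s2 + a^2/12)/N + 16*pi*(s2 + a^2/12)^2*(b_m + b_v^2) / (3*a^2*N^2)

gives the motional-blur-limited localization variance, with a the pixel
size, N the collected photons and b_m, b_v the mean and variance of the
background photons per pixel.

Under cryo-arrest the viscosity of water rises by more than 15 orders of
magnitude, diffusion is treated as exactly zero, and only the static terms
sigma_PSF^2 + r^2 remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "FWHM_PER_SIGMA",
    "MediumState",
    "ParticleStructure",
    "Photophysics",
    "BlurModel",
    "LocalizationInputs",
    "WATER_37C",
    "CRYO_ARREST",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "diffusion_coefficient",
    "mean_square_displacement",
    "acquisition_time",
    "collected_photons",
    "motional_blur_variance",
    "localization_variance",
    "localization_precision",
    "blur_for_state",
    "improvement_ratio",
]

#: Boltzmann constant (J/K), 2019 SI exact value.
BOLTZMANN = 1.380649e-23

#: Gaussian FWHM = 2.355 * sigma (conversion fixed at the conventional 2.355).
FWHM_PER_SIGMA = 2.355


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its SD."""
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class MediumState:
    """Thermodynamic state of the embedding medium.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.
    viscosity : float
        Dynamic viscosity in Pa*s.
    frozen : bool
        If True, the medium is vitrified and diffusion is treated as zero
        regardless of temperature and viscosity.
    """

    temperature: float
    viscosity: float
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive (Pa*s)")


@dataclass(frozen=True)
class ParticleStructure:
    """A (sub)cellular structure of hydrodynamic radius ``radius`` (m).

    ``uniform_label`` means the structure is uniformly labelled with many
    fluorophores, so its image is additionally convolved with its own size
    and the r^2 term enters the effective variance.
    """

    radius: float
    uniform_label: bool = True

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


@dataclass(frozen=True)
class Photophysics:
    """Fluorophore emission and detection parameters.

    emission_rate: photons/s while active (default 2 per microsecond, a rate
    that avoids re-excitation); collection_efficiency: fraction of emitted
    photons reaching the detector (default 0.1); cryo_qy_factor: quantum
    yield ratio cryo/room-temperature (default 1.2).
    """

    emission_rate: float = 2e6
    collection_efficiency: float = 0.1
    cryo_qy_factor: float = 1.2

    def __post_init__(self) -> None:
        if self.emission_rate <= 0:
            raise ValueError("emission_rate must be positive")
        if not 0 < self.collection_efficiency <= 1:
            raise ValueError("collection_efficiency must be in (0, 1]")
        if self.cryo_qy_factor < 1:
            raise ValueError("cryo_qy_factor must be >= 1")


#: Water at 37 degC with the printed viscosity 0.6922 mPa*s.
WATER_37C = MediumState(temperature=310.15, viscosity=6.922e-4)

#: Vitrified medium at liquid-nitrogen temperature; diffusion is zero.
CRYO_ARREST = MediumState(temperature=77.15, viscosity=6.922e-4, frozen=True)


@dataclass(frozen=True)
class BlurModel:
    """Effective Gaussian image variance under motional blur (all in m, m^2)."""

    sigma_psf: float
    msd: float
    radius: float
    sigma_mb2: float

    @property
    def sigma_mb(self) -> float:
        return math.sqrt(self.sigma_mb2)


@dataclass(frozen=True)
class LocalizationInputs:
    """Detector-side inputs of the localization-precision formula.

    pixel_size ``a`` in m, collected photons ``n_photons``, and the mean
    ``bg_mean`` and variance ``bg_var`` of the background photons per pixel.
    """

    pixel_size: float
    n_photons: int
    bg_mean: float = 0.0
    bg_var: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.bg_mean < 0 or self.bg_var < 0:
            raise ValueError("background moments must be non-negative")


def diffusion_coefficient(medium: MediumState, particle: ParticleStructure) -> float:
    """Stokes-Einstein diffusion coefficient D = k_B*T / (6*pi*eta*r) in m^2/s.

    Returns exactly 0 for a frozen (vitrified) medium, where objects are
    considered static.
    """
    if medium.frozen:
        return 0.0
    if particle.radius <= 0:
        raise ValueError("particle radius must be positive for a mobile medium")
    return BOLTZMANN * medium.temperature / (6.0 * math.pi * medium.viscosity * particle.radius)


def mean_square_displacement(diffusion: float, dt: float) -> float:
    """2D Brownian mean square displacement MSD = 4*D*dt (m^2)."""
    if diffusion < 0 or dt < 0:
        raise ValueError("diffusion coefficient and time must be non-negative")
    return 4.0 * diffusion * dt


def acquisition_time(n_emitted: float, photophysics: Photophysics) -> float:
    """Time (s) needed to emit ``n_emitted`` photons at the stated emission rate."""
    if n_emitted < 0:
        raise ValueError("n_emitted must be non-negative")
    return n_emitted / photophysics.emission_rate


def collected_photons(
    n_emitted: float, photophysics: Photophysics, apply_cryo_qy: bool = False
) -> int:
    """Detected photons: emitted x collection efficiency, floored.

    With ``apply_cryo_qy`` the photon budget is additionally multiplied by
    the cryo/room-temperature quantum-yield ratio.
    """
    n = n_emitted * photophysics.collection_efficiency
    if apply_cryo_qy:
        n *= photophysics.cryo_qy_factor
    return int(math.floor(n))


def motional_blur_variance(
    sigma_psf: float, msd: float = 0.0, radius: float = 0.0, uniform_label: bool = True
) -> BlurModel:
    """Effective image variance sigma_MB^2 = sigma_PSF^2 + MSD + r^2.

    The r^2 term is included only for uniformly labelled structures; for a
    point-like single emitter on the structure set ``uniform_label=False``.
    """
    if sigma_psf < 0 or msd < 0 or radius < 0:
        raise ValueError("all blur contributions must be non-negative")
    r_eff = radius if uniform_label else 0.0
    sigma_mb2 = sigma_psf**2 + msd + r_eff**2
    return BlurModel(sigma_psf=sigma_psf, msd=msd, radius=r_eff, sigma_mb2=sigma_mb2)


def localization_variance(blur: BlurModel | float, loc: LocalizationInputs) -> float:
    """Motional-blur-limited localization variance (m^2).

    ``blur`` may be a :class:`BlurModel` or the effective variance
    sigma_MB^2 directly.  The background enters through the printed
    b_m + b_v^2 grouping.
    """
    s2 = blur.sigma_mb2 if isinstance(blur, BlurModel) else float(blur)
    a = loc.pixel_size
    n = loc.n_photons
    s2a = s2 + a * a / 12.0
    b = loc.bg_mean + loc.bg_var**2
    return s2a / n + 16.0 * math.pi * s2a * s2a * b / (3.0 * a * a * n * n)


def localization_precision(blur: BlurModel | float, loc: LocalizationInputs) -> float:
    """Localization precision = sqrt of :func:`localization_variance` (m)."""
    return math.sqrt(localization_variance(blur, loc))


def blur_for_state(
    structure_diameter: float,
    n_emitted: float,
    sigma_psf: float,
    medium: MediumState,
    photophysics: Photophysics,
    uniform_label: bool = True,
) -> BlurModel:
    """Full chain diffusion -> MSD -> effective variance for one medium state.

    The acquisition time is the time to emit ``n_emitted`` photons; a frozen
    medium contributes MSD = 0.
    """
    particle = ParticleStructure(radius=structure_diameter / 2.0, uniform_label=uniform_label)
    d = diffusion_coefficient(medium, particle)
    dt = acquisition_time(n_emitted, photophysics)
    msd = mean_square_displacement(d, dt)
    return motional_blur_variance(sigma_psf, msd, particle.radius, uniform_label=uniform_label)


def improvement_ratio(
    structure_diameter: float,
    n_emitted: float,
    sigma_psf: float,
    medium_rt: MediumState = WATER_37C,
    medium_cryo: MediumState = CRYO_ARREST,
    photophysics: Photophysics = Photophysics(),
    pixel_size: float = 100e-9,
    bg_mean: float = 0.0,
    bg_var: float = 0.0,
    apply_cryo_qy: bool = False,
) -> float:
    """Fold improvement in localization precision by cryo-arrest.

    Evaluates sqrt(v_rt)/sqrt(v_cryo) through the full diffusion -> MSD ->
    blur -> variance chain.  By default room-temperature and cryo branches
    compare at equal emitted photons; ``apply_cryo_qy`` multiplies the cryo
    photon budget by the quantum-yield gain.
    """
    if medium_rt.frozen or not medium_cryo.frozen:
        raise ValueError("medium_rt must be mobile and medium_cryo frozen")
    n_rt = collected_photons(n_emitted, photophysics)
    n_cryo = collected_photons(n_emitted, photophysics, apply_cryo_qy=apply_cryo_qy)
    blur_rt = blur_for_state(structure_diameter, n_emitted, sigma_psf, medium_rt, photophysics)
    blur_cryo = blur_for_state(structure_diameter, n_emitted, sigma_psf, medium_cryo, photophysics)
    v_rt = localization_variance(
        blur_rt, LocalizationInputs(pixel_size, n_rt, bg_mean, bg_var)
    )
    v_cryo = localization_variance(
        blur_cryo, LocalizationInputs(pixel_size, n_cryo, bg_mean, bg_var)
    )
    return math.sqrt(v_rt) / math.sqrt(v_cryo)
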