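"""Phasor-based FLIM analysis of TCSPC photon-counting stacks.

The pipeline mirrors a confocal FLIM workflow for a three-state FRET
biosensor: rigid drift registration of the frame stack, background
estimation from both the image and the decay histogram, instrument response
function (IRF) estimation from the higher harmonics of the aggregate decay,
per-pixel first-harmonic phasor transform, optional translation-invariant
Haar wavelet denoising of the phasor channels, constrained three-component
unmixing of each pixel's phasor into donor-only / active / inactive photon
fractions, and conversion to molecular fractions and the active fraction
alpha.

Phasor convention: R = sum_b counts_b * exp(+i*omega*t_b) / sum_b counts_b
with omega = 2*pi/laser_period and t_b the microtime bin centers, so a
monoexponential decay of lifetime tau maps to

    R(tau) = 1 / (1 - i*omega*tau) = (1, omega*tau) / (1 + (omega*tau)^2)

on the universal semicircle |R - 1/2| = 1/2.  The transform is linear in
counts, so a mixture's phasor is the photon-fraction-weighted sum of the
component phasors — the basis of the three-component fit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "TCSPCStack",
    "PhasorImage",
    "BackgroundEstimate",
    "IRFEstimate",
    "ThreeComponentModel",
    "phasor_of_lifetime",
    "register_stack",
    "estimate_background_image",
    "estimate_background_histogram",
    "estimate_background",
    "estimate_irf",
    "phasor_transform",
    "denoise_phasors",
    "fit_three_components",
    "optimize_lifetimes",
    "molecular_fraction_maps",
    "average_lifetime_map",
    "fret_efficiency",
    "run_pipeline",
]


@dataclass(frozen=True)
class TCSPCStack:
    """A TCSPC photon-counting cube with axes (frame, y, x, microtime bin).

    ``bin_width`` and ``laser_period`` are in ns; bins must tile at most one
    laser period.  The fundamental angular frequency is
    omega = 2*pi/laser_period (rad/ns).
    """

    counts: np.ndarray
    bin_width: float
    laser_period: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 4:
            raise ValueError("counts must be 4D (frame, y, x, bin)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0 or self.laser_period <= 0:
            raise ValueError("bin_width and laser_period must be positive")
        if c.shape[3] * self.bin_width > self.laser_period * (1 + 1e-9):
            raise ValueError("bins must fit within one laser period")
        object.__setattr__(self, "counts", c)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def height(self) -> int:
        return self.counts.shape[1]

    @property
    def width(self) -> int:
        return self.counts.shape[2]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[3]

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.laser_period

    @property
    def bin_centers(self) -> np.ndarray:
        """Microtime bin centers (ns)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def intensity_frames(self) -> np.ndarray:
        """Per-frame intensity images: counts summed over microtime bins."""
        return self.counts.sum(axis=3)

    def summed_image(self) -> np.ndarray:
        """Time- and frame-summed photon-counting image."""
        return self.counts.sum(axis=(0, 3))

    def decay_histogram(self) -> np.ndarray:
        """Aggregate decay histogram summed over frames and pixels."""
        return self.counts.sum(axis=(0, 1, 2))

    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class PhasorImage:
    """Per-pixel first-harmonic phasor coordinates with photon counts.

    ``mask`` flags pixels with a defined phasor (positive corrected total).
    """

    re: np.ndarray
    im: np.ndarray
    photons: np.ndarray
    mask: np.ndarray
    omega: float

    @property
    def complex(self) -> np.ndarray:
        return self.re + 1j * self.im

    def photon_weighted_mean(self) -> complex:
        w = np.where(self.mask, self.photons, 0.0)
        tot = w.sum()
        if tot <= 0:
            return complex(np.nan, np.nan)
        re = np.where(self.mask, self.re, 0.0)
        im = np.where(self.mask, self.im, 0.0)
        return complex((w * re).sum() / tot, (w * im).sum() / tot)

    def semicircle_residual(self) -> np.ndarray:
        """Per-pixel distance from the universal semicircle |R-1/2|=1/2."""
        return np.abs(np.hypot(self.re - 0.5, self.im) - 0.5)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Image-based vs histogram-based total background, cross-checked.

    ``per_pixel_per_bin`` is the flat background level used for phasor
    correction; ``consistent`` is True when the two totals agree within the
    multiplicative ``tolerance``.
    """

    image_based: float
    histogram_based: float
    per_pixel_per_bin: float
    consistent: bool
    tolerance: float = 2.0


@dataclass(frozen=True)
class IRFEstimate:
    """Gaussian IRF: delay ``shift_ns`` and SD ``width_ns`` (both ns)."""

    shift_ns: float = 0.0
    width_ns: float = 0.0

    def phasor(self, omega: float, harmonic: int = 1) -> complex:
        """IRF phasor exp(i*n*omega*t0 - (n*omega*s)^2/2) at harmonic n."""
        w = harmonic * omega
        return np.exp(1j * w * self.shift_ns - 0.5 * (w * self.width_ns) ** 2)


def phasor_of_lifetime(tau: float, omega: float) -> complex:
    """Phasor of a monoexponential decay: 1/(1 - i*omega*tau)."""
    return 1.0 / (1.0 - 1j * omega * tau)


@dataclass
class ThreeComponentModel:
    """Three spatially invariant biosensor states and per-pixel fractions.

    States: donor-only (sensor with non-absorbing acceptor, fixed photon
    fraction), active (closed, high-FRET, short lifetime) and inactive
    (extended, low-FRET).  ``photon_fractions`` and ``molecular_fractions``
    are (H, W, 3) arrays ordered (donor_only, active, inactive);
    ``alpha`` = m_active / (1 - m_donor_only).
    """

    tau_donor_only: float = 3.71
    tau_active: float = 0.9
    tau_inactive: float = 3.5
    donor_only_fraction: float = 0.2
    photon_fractions: np.ndarray | None = None
    molecular_fractions: np.ndarray | None = None
    alpha: np.ndarray | None = None
    residual: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for tau in (self.tau_donor_only, self.tau_active, self.tau_inactive):
            if tau <= 0:
                raise ValueError("lifetimes must be positive")
        if not 0 <= self.donor_only_fraction < 1:
            raise ValueError("donor_only_fraction must be in [0, 1)")

    def lifetimes(self) -> np.ndarray:
        return np.array([self.tau_donor_only, self.tau_active, self.tau_inactive])

    def component_phasors(self, omega: float) -> np.ndarray:
        return np.array([phasor_of_lifetime(t, omega) for t in self.lifetimes()])


# ---------------------------------------------------------------------------
# registration


def _shift_frame(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer-shift a (y, x, bin) frame; photons moved out of bounds are lost."""
    out = np.zeros_like(frame)
    h, w = frame.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def register_stack(stack: TCSPCStack) -> tuple[TCSPCStack, np.ndarray, int]:
    """Rigid translation-only registration of every frame to the first.

    Shifts are estimated by phase correlation on the time-summed intensity
    images (subpixel refinement is computed, then rounded to the nearest
    integer before application).  Photons shifted outside the field of view
    of the first frame are dropped.  Returns (registered stack, integer
    shifts (n_frames, 2) as (dy, dx), photons dropped).
    """
    frames = stack.intensity_frames().astype(float)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    out = stack.counts.copy()
    ref = frames[0]
    for f in range(1, stack.n_frames):
        if frames[f].sum() == 0:
            logger.warning("frame %d contains no photons; shift set to (0, 0)", f)
            continue
        shift, _, _ = phase_cross_correlation(ref, frames[f], upsample_factor=10)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts[f] = (dy, dx)
        if dy or dx:
            out[f] = _shift_frame(stack.counts[f], dy, dx)
    registered = TCSPCStack(out, stack.bin_width, stack.laser_period)
    dropped = stack.total_photons() - registered.total_photons()
    return registered, shifts, dropped


# ---------------------------------------------------------------------------
# background


def estimate_background_image(
    stack: TCSPCStack, window: int = 21, median_size: int = 9
) -> float:
    """Per-pixel background (counts over all frames and bins).

    The time-summed image is median filtered (``median_size`` square
    window) to suppress dark outliers, the darkest position located, and
    the raw image averaged over a ``window`` x ``window`` square around
    it.  The position is the minimum of the window-averaged score image
    max(median, raw): the window itself must be the darkest available
    region (it cannot straddle a bright structure next to a locally dim
    pixel), dead pixels cannot attract it, and bright pixels repel it at
    full resolution.
    """
    img = stack.summed_image().astype(float)
    if window > min(img.shape):
        warnings.warn("background window exceeds image; shrinking", stacklevel=2)
        window = min(img.shape)
    den = ndimage.median_filter(img, size=median_size, mode="nearest")
    win_mean = ndimage.uniform_filter(np.maximum(den, img), size=window, mode="nearest")
    half = window // 2
    # restrict to positions whose window lies fully inside the image
    interior = win_mean[
        half : img.shape[0] - window + half + 1, half : img.shape[1] - window + half + 1
    ]
    p = np.unravel_index(np.argmin(interior), interior.shape)
    y0, x0 = p[0], p[1]
    return float(img[y0 : y0 + window, x0 : x0 + window].mean())


def estimate_background_histogram(
    stack: TCSPCStack, window: int = 51, median_size: int = 21
) -> tuple[float, float]:
    """Background floor from the aggregate decay histogram.

    The histogram (summed over frames and pixels) is median filtered
    (``median_size`` bins, circular on the laser period), the darkest
    position located, and the raw histogram averaged over a ``window``-bin
    span around it.  As in the image-based estimator the position is the
    minimum of the window-averaged denoised histogram, so the averaging
    span cannot wrap across the excitation peak next to the pre-pulse
    trough.  Returns (per-bin floor for the whole image, total = floor x
    n_bins).
    """
    hist = stack.decay_histogram().astype(float)
    if window > hist.size:
        warnings.warn("histogram window exceeds bin count; shrinking", stacklevel=2)
        window = hist.size
    den = ndimage.median_filter(hist, size=median_size, mode="wrap")
    win_mean = ndimage.uniform_filter1d(den, size=window, mode="wrap")
    p = int(np.argmin(win_mean))
    half = window // 2
    idx = (np.arange(p - half, p - half + window)) % hist.size  # circular span
    per_bin = float(hist[idx].mean())
    return per_bin, per_bin * stack.n_bins


def estimate_background(
    stack: TCSPCStack,
    image_window: int = 21,
    hist_window: int = 51,
    tolerance: float = 2.0,
) -> BackgroundEstimate:
    """Run both background estimators and cross-check their totals.

    Totals are expressed as background photons of the whole image.  The
    image-based estimate provides the flat per-pixel-per-bin level used for
    phasor correction: the histogram floor systematically overestimates the
    background when lifetimes are comparable to the laser period, because
    the wrapped (incomplete) decay tail never returns to the true floor.
    """
    npix = stack.height * stack.width
    per_px = estimate_background_image(stack, window=image_window)
    image_total = per_px * npix
    per_bin, hist_total = estimate_background_histogram(stack, window=hist_window)
    lo = min(image_total, hist_total)
    hi = max(image_total, hist_total)
    consistent = bool(lo > 0 and hi / lo <= tolerance) or (lo == hi == 0)
    if not consistent:
        logger.warning(
            "background estimates disagree: image=%.3g histogram=%.3g", image_total, hist_total
        )
    return BackgroundEstimate(
        image_based=image_total,
        histogram_based=hist_total,
        per_pixel_per_bin=per_px / stack.n_bins,
        consistent=consistent,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# IRF


def estimate_irf(
    stack: TCSPCStack,
    background: BackgroundEstimate | float | None = None,
    n_harmonics: int = 5,
    min_photons: int = 1000,
) -> IRFEstimate:
    """Estimate a Gaussian IRF from the higher harmonics of the histogram.

    The aggregate decay is assumed near-monoexponential; its measured
    phasors at harmonics 1..K are fitted with the product of a
    monoexponential decay phasor and a shifted-Gaussian IRF phasor,

        M_n = 1/(1 - i*n*omega*tau) * exp(i*n*omega*t0 - (n*omega*s)^2/2),

    over (tau, t0, s) by least squares.  For strongly multi-exponential
    aggregates the estimate is biased; supply a measured IRF instead.
    """
    hist = stack.decay_histogram().astype(float)
    if background is not None:
        per_bin = (
            background.per_pixel_per_bin * stack.height * stack.width
            if isinstance(background, BackgroundEstimate)
            else float(background)
        )
        hist = np.clip(hist - per_bin, 0.0, None)
    total = hist.sum()
    if total < min_photons:
        warnings.warn("too few photons for IRF estimation; returning identity IRF",
                      stacklevel=2)
        return IRFEstimate()
    omega = stack.omega
    t = stack.bin_centers
    harmonics = np.arange(1, n_harmonics + 1)
    measured = np.array(
        [np.sum(hist * np.exp(1j * n * omega * t)) / total for n in harmonics]
    )

    def model(params: np.ndarray) -> np.ndarray:
        tau, t0, s = params
        w = harmonics * omega
        return (1.0 / (1.0 - 1j * w * tau)) * np.exp(1j * w * t0 - 0.5 * (w * s) ** 2)

    def residuals(params: np.ndarray) -> np.ndarray:
        diff = model(params) - measured
        return np.concatenate([diff.real, diff.imag])

    phase1 = np.angle(measured[0])
    tau0 = float(np.clip(math.tan(phase1) / omega, 0.05, stack.laser_period))
    fit = optimize.least_squares(
        residuals,
        x0=[tau0, 0.0, 0.05],
        bounds=([1e-3, -stack.laser_period / 2, 0.0],
                [stack.laser_period * 4, stack.laser_period / 2, stack.laser_period / 4]),
    )
    _, t0, s = fit.x
    return IRFEstimate(shift_ns=float(t0), width_ns=float(s))


# ---------------------------------------------------------------------------
# phasor transform


def phasor_transform(
    stack: TCSPCStack,
    background: BackgroundEstimate | float | None = None,
    irf: IRFEstimate | complex | None = None,
) -> PhasorImage:
    """Per-pixel first-harmonic phasor transform with corrections.

    ``background`` supplies a flat per-pixel-per-bin count subtracted before
    the transform; ``irf`` a Gaussian IRF (or its complex first-harmonic
    phasor) divided out.  Pixels with non-positive corrected totals are
    masked.  Photon totals are clamped at zero.
    """
    omega = stack.omega
    t = stack.bin_centers
    counts = stack.counts.sum(axis=0).astype(float)  # (H, W, B)
    if background is not None:
        per_bin = (
            background.per_pixel_per_bin
            if isinstance(background, BackgroundEstimate)
            else float(background)
        )
        counts = counts - per_bin
    kernel = np.exp(1j * omega * t)
    numer = counts @ kernel
    total = counts.sum(axis=2)
    mask = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask, numer / np.where(mask, total, 1.0), np.nan + 0j)
    if irf is not None:
        g = irf.phasor(omega) if isinstance(irf, IRFEstimate) else complex(irf)
        r = r / g
    photons = np.clip(total, 0.0, None)
    return PhasorImage(
        re=np.where(mask, r.real, np.nan),
        im=np.where(mask, r.imag, np.nan),
        photons=photons,
        mask=mask,
        omega=omega,
    )


# ---------------------------------------------------------------------------
# denoising


def _swt_denoise(img: np.ndarray, var_img: np.ndarray, level: int, lam: float) -> np.ndarray:
    """Weighted translation-invariant Haar soft-thresholding of one channel.

    Each stationary-wavelet detail coefficient is thresholded at ``lam``
    times its own noise SD, propagated from the per-pixel noise variance
    map ``var_img``: for the orthonormal undecimated Haar transform a
    level-j coefficient is supported on a 2^j x 2^j box with squared filter
    weights 4^-j, so Var(coef) is the local box mean of the pixel
    variances.  Thresholding is hard (keep-or-kill): coefficients
    consistent with pure noise are removed while genuine structure (edges,
    gradients) is kept exactly — shrinking retained coefficients would
    shrink the count-scaled phasor channels by different relative amounts
    than the photon channel and bias their ratio; the translation
    averaging of the stationary transform suppresses the blocking
    artifacts hard thresholding would otherwise cause.
    """
    pad = (-img.shape[0]) % (1 << level), (-img.shape[1]) % (1 << level)
    padded = np.pad(img, ((0, pad[0]), (0, pad[1])), mode="symmetric")
    var_pad = np.pad(var_img, ((0, pad[0]), (0, pad[1])), mode="symmetric")
    coeffs = pywt.swt2(padded, "haar", level=level, norm=True)
    out = []
    for i, (approx, details) in enumerate(coeffs):
        j = level - i  # coeffs[0] is the coarsest level
        sd = np.sqrt(ndimage.uniform_filter(var_pad, size=1 << j, mode="nearest"))
        thr = lam * sd
        out.append(
            (approx, tuple(np.where(np.abs(d) > thr, d, 0.0) for d in details))
        )
    rec = pywt.iswt2(out, "haar", norm=True)
    return rec[: img.shape[0], : img.shape[1]]


def denoise_phasors(phasor: PhasorImage, level: int = 2, lam: float = 2.0) -> PhasorImage:
    """Translation-invariant Haar wavelet denoising of the phasor channels.

    A simplified weighted scheme: the count-scaled channels re*photons and
    im*photons and the photon image itself are hard-thresholded in a
    stationary (cycle-spun) Haar transform, each coefficient at ``lam``
    times its own Poisson noise SD (Var(re*N) ~ N/2, Var(N) = N per
    pixel).  Bright pixels thereby carry proportionally larger
    coefficients, and the final ratio re = (re*N)_denoised/N_denoised is a
    photon-weighted local mean wherever smoothing occurs.  The returned
    photon counts are the denoised totals (the natural weights of the
    denoised phasors); total photons and the photon-weighted mean phasor
    of the image are restored exactly after thresholding.
    """
    w = np.where(phasor.mask, phasor.photons, 0.0)
    u = np.where(phasor.mask, phasor.re * w, 0.0)
    v = np.where(phasor.mask, phasor.im * w, 0.0)
    var_uv = np.clip(w, 1.0, None) / 2.0
    var_w = np.clip(w, 1.0, None)
    u_d = _swt_denoise(u, var_uv, level, lam)
    v_d = _swt_denoise(v, var_uv, level, lam)
    w_d = _swt_denoise(w, var_w, level, lam)
    # restore totals and the photon-weighted mean (leakage from padding)
    npix_on = max(int(phasor.mask.sum()), 1)
    u_d[phasor.mask] += (u.sum() - u_d[phasor.mask].sum()) / npix_on
    v_d[phasor.mask] += (v.sum() - v_d[phasor.mask].sum()) / npix_on
    w_d[phasor.mask] += (w.sum() - w_d[phasor.mask].sum()) / npix_on
    ok = phasor.mask & (w_d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        re = np.where(ok, u_d / np.where(ok, w_d, 1.0), np.nan)
        im = np.where(ok, v_d / np.where(ok, w_d, 1.0), np.nan)
    return PhasorImage(re=re, im=im, photons=w_d, mask=ok, omega=phasor.omega)


# ---------------------------------------------------------------------------
# three-component global analysis


def fit_three_components(
    phasor: PhasorImage, model: ThreeComponentModel
) -> ThreeComponentModel:
    """Constrained per-pixel unmixing into the three state photon fractions.

    Each observed phasor is modelled as f_do*R_do + f_act*R_act +
    f_inact*R_inact with the donor-only photon fraction fixed, f_i >= 0 and
    sum f_i = 1, leaving one free parameter per pixel solved in closed form
    (least-squares projection onto the active-inactive chord, clipped to the
    feasible interval).  Component lifetimes are spatially invariant.
    """
    r_do, r_act, r_in = model.component_phasors(phasor.omega)
    f_do = model.donor_only_fraction
    obs = phasor.complex
    z = obs - f_do * r_do - (1.0 - f_do) * r_in
    v = r_act - r_in
    x = (z * np.conj(v)).real / (abs(v) ** 2)
    f_act = np.clip(x, 0.0, 1.0 - f_do)
    f_inact = 1.0 - f_do - f_act
    resid = np.abs(z - f_act * v)
    h, w = phasor.re.shape
    fractions = np.empty((h, w, 3))
    fractions[..., 0] = f_do
    fractions[..., 1] = f_act
    fractions[..., 2] = f_inact
    fractions[~phasor.mask] = np.nan
    fitted = replace(model)
    fitted.photon_fractions = fractions
    fitted.residual = np.where(phasor.mask, resid, np.nan)
    fitted.mask = phasor.mask.copy()
    return molecular_fraction_maps(fitted)


def optimize_lifetimes(
    phasor: PhasorImage,
    model: ThreeComponentModel,
    starts: tuple[tuple[float, float], ...] = ((0.9, 3.5), (0.5, 3.0), (1.5, 4.2)),
) -> ThreeComponentModel:
    """Globally optimize (tau_active, tau_inactive) by weighted least squares.

    The donor-only lifetime stays fixed at its control value.  Multi-start
    nonlinear least squares minimizes the photon-weighted unmixing residual
    over all pixels; the best start wins.  Returns a fitted model with
    fractions from the optimal lifetimes.
    """
    w = np.sqrt(np.where(phasor.mask, phasor.photons, 0.0)).ravel()

    def cost(params: np.ndarray) -> np.ndarray:
        trial = replace(model, tau_active=float(params[0]), tau_inactive=float(params[1]))
        fitted = fit_three_components(phasor, trial)
        resid = np.nan_to_num(fitted.residual, nan=0.0).ravel()
        return w * resid

    best = None
    for x0 in starts:
        try:
            fit = optimize.least_squares(
                cost, x0=list(x0), bounds=([0.05, 0.05], [20.0, 20.0]), xtol=1e-8
            )
        except ValueError:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise RuntimeError("lifetime optimization failed for every start")
    tuned = replace(
        model, tau_active=float(best.x[0]), tau_inactive=float(best.x[1])
    )
    if tuned.tau_active > tuned.tau_inactive:
        tuned = replace(
            tuned, tau_active=tuned.tau_inactive, tau_inactive=tuned.tau_active
        )
    return fit_three_components(phasor, tuned)


def molecular_fraction_maps(model: ThreeComponentModel) -> ThreeComponentModel:
    """Convert photon fractions to molecular fractions and the alpha map.

    Photon fractions weight states by brightness; dividing by the lifetime
    (a proxy for quantum yield) and renormalizing gives molecular fractions
    m_i = (f_i/tau_i) / sum_j (f_j/tau_j).  The active fraction is
    renormalized to exclude donor-only sensors: alpha = m_act/(1 - m_do).
    """
    if model.photon_fractions is None:
        raise ValueError("model has no photon fractions; run fit_three_components first")
    taus = model.lifetimes()
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    q = model.photon_fractions / taus[None, None, :]
    m = q / q.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = m[..., 1] / (1.0 - m[..., 0])
    model.molecular_fractions = m
    model.alpha = alpha
    return model


# ---------------------------------------------------------------------------
# maps and scalar relations


def average_lifetime_map(
    phasor: PhasorImage, min_photons: float = 0.0
) -> np.ndarray:
    """Per-pixel apparent (phase) lifetime tau = tan(arg R)/omega in ns.

    Pixels with fewer than ``min_photons`` corrected photons (or an
    undefined phasor) are NaN-masked, not zero-filled.
    """
    ok = phasor.mask & (phasor.photons >= min_photons)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.tan(np.arctan2(phasor.im, phasor.re)) / phasor.omega
    return np.where(ok, tau, np.nan)


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """FRET efficiency E = 1 - tau_DA/tau_D from donor lifetimes."""
    if tau_d <= 0:
        raise ValueError("donor lifetime must be positive")
    if not 0 <= tau_da <= tau_d:
        raise ValueError("tau_da must satisfy 0 <= tau_da <= tau_d")
    return 1.0 - tau_da / tau_d


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(
    stack: TCSPCStack,
    model: ThreeComponentModel | None = None,
    register: bool = True,
    subtract_background: bool = True,
    irf: IRFEstimate | str | None = None,
    denoise: bool = True,
    fit_lifetimes: bool = False,
    min_photons: float = 50.0,
) -> dict:
    """End-to-end FLIM analysis returning all intermediate products.

    ``irf`` may be an :class:`IRFEstimate` (user supplied), the string
    ``"estimate"`` to estimate it from the data harmonics, or None for no
    IRF correction.  Returns a dict with keys ``stack`` (registered),
    ``shifts``, ``dropped``, ``background``, ``irf``, ``phasor`` (possibly
    denoised), ``model`` (with fraction maps), ``tau_map``.
    """
    model = model if model is not None else ThreeComponentModel()
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    dropped = 0
    if register:
        stack, shifts, dropped = register_stack(stack)
    background = estimate_background(stack) if subtract_background else None
    if irf == "estimate":
        irf = estimate_irf(stack, background=background)
    phasor = phasor_transform(stack, background=background, irf=irf)
    if denoise:
        phasor = denoise_phasors(phasor)
    if fit_lifetimes:
        fitted = optimize_lifetimes(phasor, model)
    else:
        fitted = fit_three_components(phasor, model)
    low = phasor.photons < min_photons
    for arr in (fitted.photon_fractions, fitted.molecular_fractions):
        arr[low] = np.nan
    fitted.alpha[low] = np.nan
    tau_map = average_lifetime_map(phasor, min_photons=min_photons)
    return {
        "stack": stack,
        "shifts": shifts,
        "dropped": dropped,
        "background": background,
        "irf": irf if isinstance(irf, IRFEstimate) else None,
        "phasor": phasor,
        "model": fitted,
        "tau_map": tau_map,
    }
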