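"""Config-file loading for the optics/medium/photophysics setup.

TOML (or YAML) files with sections::

    [optics]
    fwhm_nm = 100.0
    pixel_nm = 100.0
    bg_mean = 0.0
    bg_var = 0.0

    [medium.rt]
    temperature = 310.15
    viscosity_mpas = 0.6922

    [medium.cryo]
    frozen = true

    [photophysics]
    emission_rate_per_us = 2.0
    collection_efficiency = 0.1
    cryo_qy_factor = 1.2

Omitted sections and keys fall back to the package defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import motional_optics as mo

__all__ = ["Setup", "load_setup"]


@dataclass(frozen=True)
class Setup:
    """A complete evaluation setup for the blur/resolution calculations."""

    sigma_psf: float
    pixel_size: float
    bg_mean: float
    bg_var: float
    medium_rt: mo.MediumState
    medium_cryo: mo.MediumState
    photophysics: mo.Photophysics


def _read(path) -> dict:
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        return yaml.safe_load(path.read_text()) or {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_setup(path) -> Setup:
    """Load a :class:`Setup` from a TOML or YAML file."""
    raw = _read(path)
    optics = raw.get("optics", {})
    medium = raw.get("medium", {})
    rt = medium.get("rt", {})
    cryo = medium.get("cryo", {})
    phot = raw.get("photophysics", {})
    medium_rt = mo.MediumState(
        temperature=float(rt.get("temperature", 310.15)),
        viscosity=float(rt.get("viscosity_mpas", 0.6922)) * 1e-3,
        frozen=bool(rt.get("frozen", False)),
    )
    medium_cryo = mo.MediumState(
        temperature=float(cryo.get("temperature", 77.15)),
        viscosity=float(cryo.get("viscosity_mpas", 0.6922)) * 1e-3,
        frozen=bool(cryo.get("frozen", True)),
    )
    photophysics = mo.Photophysics(
        emission_rate=float(phot.get("emission_rate_per_us", 2.0)) * 1e6,
        collection_efficiency=float(phot.get("collection_efficiency", 0.1)),
        cryo_qy_factor=float(phot.get("cryo_qy_factor", 1.2)),
    )
    return Setup(
        sigma_psf=mo.fwhm_to_sigma(float(optics.get("fwhm_nm", 100.0)) * 1e-9),
        pixel_size=float(optics.get("pixel_nm", 100.0)) * 1e-9,
        bg_mean=float(optics.get("bg_mean", 0.0)),
        bg_var=float(optics.get("bg_var", 0.0)),
        medium_rt=medium_rt,
        medium_cryo=medium_cryo,
        photophysics=photophysics,
    )
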