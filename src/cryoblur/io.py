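"""Reading and writing TCSPC stacks and result maps.

HDF5 layout: dataset ``/counts`` (uint32, axes frame, y, x, microtime bin)
with attributes ``bin_width_ns`` and ``laser_period_ns``.  A TIFF
hyperstack fallback stores the same cube with the metadata in the image
description.  Result maps are written as 32-bit floating-point TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .flim_phasor import TCSPCStack

__all__ = [
    "read_tcspc",
    "write_tcspc_h5",
    "read_tcspc_h5",
    "write_tcspc_tiff",
    "read_tcspc_tiff",
    "write_maps",
    "write_fit_report",
]


def write_tcspc_h5(stack: TCSPCStack, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "counts", data=np.asarray(stack.counts, dtype=np.uint32), compression="gzip"
        )
        d.attrs["bin_width_ns"] = stack.bin_width
        d.attrs["laser_period_ns"] = stack.laser_period


def read_tcspc_h5(path) -> TCSPCStack:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        return TCSPCStack(d[...], float(d.attrs["bin_width_ns"]),
                          float(d.attrs["laser_period_ns"]))


def write_tcspc_tiff(stack: TCSPCStack, path) -> None:
    meta = {"bin_width_ns": stack.bin_width, "laser_period_ns": stack.laser_period}
    tifffile.imwrite(
        path,
        np.asarray(stack.counts, dtype=np.uint32),
        description=json.dumps(meta),
    )


def read_tcspc_tiff(path) -> TCSPCStack:
    with tifffile.TiffFile(path) as tif:
        counts = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return TCSPCStack(counts, float(meta["bin_width_ns"]), float(meta["laser_period_ns"]))


def read_tcspc(path) -> TCSPCStack:
    """Dispatch on suffix: .h5/.hdf5 or .tif/.tiff."""
    suffix = Path(path).suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        return read_tcspc_h5(path)
    if suffix in {".tif", ".tiff"}:
        return read_tcspc_tiff(path)
    raise ValueError(f"unsupported TCSPC container: {suffix}")


def write_maps(out_dir, **maps) -> list[Path]:
    """Write each named 2D map as a 32-bit float TIFF; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in maps.items():
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths.append(p)
    return paths


def write_fit_report(out_path, result: dict) -> None:
    """JSON fit report: lifetimes, mean fractions, residuals, registration."""
    model = result["model"]
    phasor = result["phasor"]
    bg = result.get("background")
    irf = result.get("irf")

    def _nanmean(a):
        return None if a is None else float(np.nanmean(a))

    report = {
        "tau_donor_only_ns": model.tau_donor_only,
        "tau_active_ns": model.tau_active,
        "tau_inactive_ns": model.tau_inactive,
        "donor_only_photon_fraction": model.donor_only_fraction,
        "mean_alpha": _nanmean(model.alpha),
        "mean_photon_fraction_active": _nanmean(
            None if model.photon_fractions is None else model.photon_fractions[..., 1]
        ),
        "mean_residual": _nanmean(model.residual),
        "mean_phasor_re": float(phasor.photon_weighted_mean().real),
        "mean_phasor_im": float(phasor.photon_weighted_mean().imag),
        "registration_shifts": np.asarray(result["shifts"]).tolist(),
        "photons_dropped": int(result["dropped"]),
        "background_image_based": None if bg is None else bg.image_based,
        "background_histogram_based": None if bg is None else bg.histogram_based,
        "background_consistent": None if bg is None else bg.consistent,
        "irf_shift_ns": None if irf is None else irf.shift_ns,
        "irf_width_ns": None if irf is None else irf.width_ns,
    }
    Path(out_path).write_text(json.dumps(report, indent=2))
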