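#!/usr/bin/env python
"""End-to-end phasor FLIM analysis of a synthetic biosensor acquisition.

Generates a cryo-arrest three-state biosensor scene (known activity map),
runs the full pipeline — registration, background estimation, phasor
transform, wavelet denoising, three-component unmixing — and scores the
recovered molecular activity map against the ground truth.  Typical
outcome at 1000 photons/pixel: planted drifts recovered exactly, alpha
recovered with RMSE ~0.04 and |bias| < 0.02.

Writes results/flim/ (maps as float TIFF, fit report, recovery summary).
"""

import json
from pathlib import Path

import numpy as np

from cryoblur import flim_phasor as fp
from cryoblur import io as cio
from cryoblur import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "flim"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2026


def main() -> None:
    spec = syn.lifea2_cryo(seed=SEED)
    stack, truth = syn.generate_tcspc_stack(spec)
    result = fp.run_pipeline(stack)

    model = result["model"]
    sel = np.isfinite(model.alpha) & np.isfinite(truth["alpha"])
    err = model.alpha[sel] - truth["alpha"][sel]
    summary = {
        "n_pixels_scored": int(sel.sum()),
        "alpha_bias": float(err.mean()),
        "alpha_rmse": float(np.sqrt((err**2).mean())),
        "recovered_shifts": result["shifts"].tolist(),
        "true_drift": truth["shifts"].tolist(),
        "photons_dropped": int(result["dropped"]),
        "background_image_based": result["background"].image_based,
        "background_true": spec.background_rate
        * spec.n_frames
        * spec.shape[0]
        * spec.shape[1],
    }
    cio.write_maps(
        OUT,
        alpha_recovered=model.alpha,
        alpha_true=truth["alpha"],
        tau_ns=result["tau_map"],
        photons=result["phasor"].photons,
    )
    cio.write_fit_report(OUT / "fit_report.json", result)
    (OUT / "recovery_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"registration: recovered {summary['recovered_shifts']} "
          f"for planted drift {summary['true_drift']} "
          f"({summary['photons_dropped']} photons dropped at the edges)")
    print(f"background: estimated {summary['background_image_based']:.0f} photons "
          f"vs {summary['background_true']:.0f} true")
    print(f"alpha recovery over {summary['n_pixels_scored']} pixels: "
          f"bias {summary['alpha_bias']:+.3f}, RMSE {summary['alpha_rmse']:.3f}")
    print(f"wrote maps and reports to {OUT}")


if __name__ == "__main__":
    main()
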