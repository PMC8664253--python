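#!/usr/bin/env python
"""Closed-form localization-precision limits under motional blur.

Tabulates the effective image SD (sigma_MB) and localization precision for
structures of 10-1000 nm at photon budgets of 1e4-1e7 emitted photons, for
a mobile 37 degC medium versus cryo-arrest, at three PSFs (FWHM 340, 100
and 40 nm).  The headline numbers: at FWHM 100 nm and 1e5 emitted photons,
cryo-arrest improves localization precision ~16-fold for a 100-nm
structure and ~70-fold for a 10-nm structure — Brownian blur, not photon
count, limits the mobile case.

Writes results/localization_limits.csv and results/precision_folds.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cryoblur import motional_optics as mo

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    phot = mo.Photophysics()
    sizes = np.array([10, 20, 50, 100, 200, 500, 1000]) * 1e-9
    budgets = [1e4, 1e5, 1e6, 1e7]
    fwhms = [340e-9, 100e-9, 40e-9]
    rows = []
    for fwhm in fwhms:
        sigma_psf = mo.fwhm_to_sigma(fwhm)
        for size in sizes:
            for n_emitted in budgets:
                for state, medium in (("rt", mo.WATER_37C), ("cryo", mo.CRYO_ARREST)):
                    blur = mo.blur_for_state(size, n_emitted, sigma_psf, medium, phot)
                    n = mo.collected_photons(n_emitted, phot)
                    prec = mo.localization_precision(
                        blur, mo.LocalizationInputs(100e-9, n)
                    )
                    rows.append(
                        {
                            "fwhm_nm": round(fwhm * 1e9, 3),
                            "size_nm": round(size * 1e9, 3),
                            "photons_emitted": n_emitted,
                            "state": state,
                            "sigma_mb_nm": blur.sigma_mb * 1e9,
                            "precision_nm": prec * 1e9,
                        }
                    )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "localization_limits.csv", index=False)

    wide = table.pivot_table(
        index=["fwhm_nm", "size_nm", "photons_emitted"],
        columns="state",
        values="precision_nm",
    ).reset_index()
    wide["fold"] = wide["rt"] / wide["cryo"]
    wide.to_csv(OUT / "precision_folds.csv", index=False)

    sel = wide[(wide.fwhm_nm == 100) & (wide.photons_emitted == 1e5)]
    for _, row in sel.iterrows():
        print(
            f"FWHM 100 nm, 1e5 photons, {row.size_nm:4.0f} nm structure: "
            f"rt {row.rt:7.2f} nm vs cryo {row.cryo:5.2f} nm -> {row.fold:5.1f}x"
        )
    # diminishing returns of photon budget at rt
    rt100 = table[
        (table.state == "rt") & (table.size_nm == 100) & (table.fwhm_nm == 100)
    ]
    p5, p7 = (
        rt100[rt100.photons_emitted == b].precision_nm.iloc[0] for b in (1e5, 1e7)
    )
    print(f"rt 100-nm structure: 100x more photons improves precision only "
          f"{p5 / p7:.2f}x (motional blur dominates)")
    print(f"wrote {OUT / 'localization_limits.csv'} and precision_folds.csv")


if __name__ == "__main__":
    main()
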