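#!/usr/bin/env python
"""Global pKa fit, sample-temperature calibration, ITC extrapolation.

Fits a shared pKa to six synthetic reporter residues (1H and 15N series
fitted separately, then combined by inverse-variance weighting), evaluates
the water-shift temperature calibration, and demonstrates the
buffer-ionization extrapolation on a synthetic multi-buffer ITC set with a
known proton-release count.

Finding: the separate 1H and 15N global fits agree with the generating
pKa within their Monte-Carlo errors; the calibration gives 285 K at a
water shift of 4.89 ppm; the ITC regression recovers the planted slope
(protons released) and intercept (buffer-independent binding enthalpy)
exactly, and -T dS follows as dH - dG.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from redorlab.io import write_titration_tsv
from redorlab.synthetic import SyntheticConfig, gen_titration
from redorlab.titration import (
    ItcSeries,
    effective_temperature,
    global_fit_pka,
    itc_extrapolate,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    series, truth = gen_titration(SyntheticConfig(seed=seed))
    write_titration_tsv(series, RESULTS / "titration_shifts.tsv")

    fits = {}
    for nuc in ("H", "N"):
        sub = [s for s in series if s.nucleus == nuc]
        fits[nuc] = global_fit_pka(sub, n_mc=200, seed=seed)
        print(f"{nuc}-series global pKa: {fits[nuc].pka:.3f} "
              f"+/- {fits[nuc].sigma_pka:.3f}")
    w = {n: fits[n].sigma_pka**-2 for n in fits}
    combined = sum(w[n] * fits[n].pka for n in fits) / sum(w.values())
    sigma_c = sum(w.values()) ** -0.5
    print(f"inverse-variance combined pKa: {combined:.3f} +/- {sigma_c:.3f} "
          f"(truth {truth.true_pka[0]:.3f})")

    t_eff = effective_temperature(4.89)
    print(f"effective temperature at water shift 4.89 ppm: {t_eff:.1f} K")

    # synthetic multi-buffer set: 0.8 protons released, dH_binding -20 kJ/mol
    dh_ion = np.array([3.6, 20.4, 47.5])  # typical buffer ionization enthalpies
    itc = ItcSeries(7.5, dh_ion, 0.8 * dh_ion - 20.0, dg_kj_mol=-41.1)
    dh, mtds, n_h = itc_extrapolate(itc)
    print(f"ITC at pH {itc.ph}: dH = {dh:.1f} kJ/mol, -TdS = {mtds:.1f} "
          f"kJ/mol, protons released = {n_h:.2f}")

    pd.DataFrame(
        [
            {"quantity": "pka_H", "value": fits["H"].pka,
             "sigma": fits["H"].sigma_pka},
            {"quantity": "pka_N", "value": fits["N"].pka,
             "sigma": fits["N"].sigma_pka},
            {"quantity": "pka_combined", "value": combined, "sigma": sigma_c},
            {"quantity": "true_pka", "value": truth.true_pka[0], "sigma": 0.0},
            {"quantity": "t_eff_kelvin", "value": t_eff, "sigma": 0.0},
            {"quantity": "itc_dh_kj_mol", "value": dh, "sigma": 0.0},
            {"quantity": "itc_minus_tds_kj_mol", "value": mtds, "sigma": 0.0},
            {"quantity": "itc_protons_released", "value": n_h, "sigma": 0.0},
        ]
    ).to_csv(RESULTS / "titration_itc.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
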