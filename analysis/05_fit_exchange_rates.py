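#!/usr/bin/env python
"""Fit four-site 19F exchange buildup/decay curves with Monte-Carlo errors.

Generates a synthetic exchange dataset at the study conditions (mixing
times 0.1-80 ms, per-peak rates spanning the observed 165-318 1/s range,
plateaus near the 0.25 equilibration value), row-normalizes the volumes,
propagates SNR point errors, and fits all 16 diagonal/cross curves.

Finding: fitted rates recover the generating rates well within the
Monte-Carlo uncertainties, and the diagonal + three cross plateaus of each
row sum to ~1, as required by intensity conservation.
"""

from pathlib import Path

import pandas as pd

from redorlab.exchange import fit_exchange, normalize_rows, point_error
from redorlab.io import write_exchange_tsv
from redorlab.synthetic import SyntheticConfig, gen_exchange

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 1, n_mc: int = 500) -> None:
    ds, _, truth = gen_exchange(SyntheticConfig(seed=seed))
    write_exchange_tsv(ds, RESULTS / "exchange_volumes.tsv")
    norm = normalize_rows(ds)
    rows = []
    for i in range(4):
        plateaus = 0.0
        for j in range(4):
            y = norm[:, i, j]
            eps = point_error(y, ds.snr[:, i, j], ds.snr_norm[i])
            kind = "diagonal" if i == j else "cross"
            fit = fit_exchange(ds.mixing_times_s, y, eps, kind,
                               n_mc=n_mc, seed=seed + 16 * i + j)
            plateaus += fit.plateau
            rows.append(
                {
                    "peak_from": i + 1, "peak_to": j + 1, "type": kind,
                    "rate_s": fit.rate, "sigma_rate_s": fit.sigma_rate,
                    "plateau": fit.plateau, "true_rate_s": truth.rate_s[i],
                }
            )
        rows[-1]["row_plateau_sum"] = plateaus
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "exchange_fits.tsv", sep="\t", index=False)
    diag = df[df.type == "diagonal"]
    print(diag[["peak_from", "true_rate_s", "rate_s", "sigma_rate_s"]]
          .to_string(index=False))
    print(f"fitted diagonal rates span "
          f"{diag.rate_s.min():.0f}-{diag.rate_s.max():.0f} 1/s "
          f"(truth {truth.rate_s.min():.0f}-{truth.rate_s.max():.0f})")


if __name__ == "__main__":
    main()
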