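#!/usr/bin/env python
"""Fit H(N)-F distances for a synthetic 116-site measurement set.

Generates noisy dephasing curves for 92 weak + 24 measured sites (matching
the composition of the experimental dataset), extracts distances by
grid-search RMSD minimization with the 0.2 threshold, and reports how often
the truth falls inside the reported uncertainty interval.

Finding: with intensity noise of sd 0.05 at three mixing times, the fitted
interval covers the true distance for ~95% or more of the measurable sites,
and essentially all >= 10 A sites are correctly flagged as lower bounds.
"""

from pathlib import Path

import pandas as pd

from redorlab.io import write_curves_tsv, write_fits_tsv
from redorlab.spinsim import fit_distance
from redorlab.synthetic import SyntheticConfig, default_sequence, gen_redor_curves

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    cfg = SyntheticConfig(seed=seed)
    curves, truth, library = gen_redor_curves(cfg, seq=default_sequence())
    write_curves_tsv(curves, RESULTS / "redor_curves.tsv")

    fits = [fit_distance(c, library) for c in curves]
    write_fits_tsv(fits, RESULTS / "distance_fits.tsv")

    fit_df = pd.DataFrame(
        {
            "site_id": [f.site_id for f in fits],
            "best": [f.best_distance for f in fits],
            "lower": [f.lower for f in fits],
            "upper": [f.upper for f in fits],
            "lower_bound_only": [f.is_lower_bound_only for f in fits],
        }
    ).merge(truth, on="site_id")

    meas = fit_df[~fit_df.weak]
    weak = fit_df[fit_df.weak]
    covered = (
        (meas.lower <= meas.true_distance) & (meas.true_distance <= meas.upper)
    ).mean()
    flagged = weak.lower_bound_only.mean()
    print(f"sites: {len(fit_df)} ({len(meas)} measured, {len(weak)} weak)")
    print(f"measured sites with truth inside [lower, upper]: {covered:.1%}")
    print(f"weak sites flagged as >= 10 A lower bounds:      {flagged:.1%}")
    fit_df.to_csv(RESULTS / "distance_fit_vs_truth.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
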