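#!/usr/bin/env python
"""Simulate REDOR dephasing curves across the 3.0-15.0 A distance grid.

Builds the ideal-pulse curve library at the three protein-ligand mixing
times (64/96/144 rotor periods at 38 kHz MAS), compares a finite-pulse +
19F-CSA simulation against the ideal curves at a few distances, and writes
the library plus a diagnostic figure under results/.

Finding: finite 5 us pulses with a 60 ppm aryl-fluorine CSA leave the
curves essentially unchanged beyond ~9 A but shift the deeply dephased
oscillatory region (short contacts, longest mixing time) appreciably, so
the ideal library is a good default for weak couplings while short
contacts benefit from the finite-pulse simulator.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from redorlab.powder import PowderScheme
from redorlab.spinsim import (
    RedorSequenceParams,
    SpinPairGeometry,
    build_curve_library,
    simulate_redor,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    seq = RedorSequenceParams(
        powder=PowderScheme("spiral", 256, 16), csa_span_ppm=0.0
    )
    library = build_curve_library(seq)
    rows = []
    for i, d in enumerate(library.distances):
        for j, t in enumerate(library.mixing_times_s):
            rows.append(
                {"distance_angstrom": d, "mixing_time_s": t,
                 "s_ratio": library.s_matrix[i, j]}
            )
    pd.DataFrame(rows).to_csv(RESULTS / "redor_library.tsv", sep="\t",
                              index=False)
    library.save(RESULTS / "redor_library.npz")

    seq_fp = RedorSequenceParams(
        powder=PowderScheme("spiral", 128, 8), pulse_length_deph_s=5e-6
    )
    fig, ax = plt.subplots(figsize=(5, 3.5))
    print("distance  ideal S/S0 (1.68/2.53/3.79 ms)   finite-pulse+CSA")
    for d in (4.0, 6.0, 9.0, 12.0):
        s_id = library.curve(d).s_ratio
        s_fp = simulate_redor(SpinPairGeometry(d), seq_fp).s_ratio
        print(f"{d:5.1f} A  {np.round(s_id, 3)}  {np.round(s_fp, 3)}")
        ax.plot(library.mixing_times_s * 1e3, s_id, "o-", label=f"{d} A ideal")
        ax.plot(library.mixing_times_s * 1e3, s_fp, "s--",
                label=f"{d} A finite+CSA")
    ax.set_xlabel("mixing time (ms)")
    ax.set_ylabel("S/S0")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(RESULTS / "redor_curves.png", dpi=150)
    print(f"library with {len(library.distances)} distances -> "
          f"{RESULTS / 'redor_library.tsv'}")


if __name__ == "__main__":
    main()
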