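"""Tab-separated readers/writers for every tabular format the package uses.

All tables are plain TSV with a header row.  Readers are tolerant of two
equivalent REDOR-curve layouts: explicit ``s_ratio``/``s_ratio_err``
columns, or raw ``s0``/``s`` volumes with per-spectrum SNRs from which the
ratio and its error are derived as (S/S0) * sqrt(1/SNR_S^2 + 1/SNR_S0^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exchange import ExchangeDataset
from .hydration import RecoveryCurve
from .restraints import AmbiguousRestraint
from .spinsim import DistanceFit, RedorCurve
from .structures import AtomSelector, StructureModel
from .titration import ItcSeries, TitrationSeries

__all__ = [
    "read_curves_tsv",
    "write_curves_tsv",
    "write_fits_tsv",
    "read_restraints_tsv",
    "write_restraints_tsv",
    "export_md_restraints",
    "read_exchange_tsv",
    "write_exchange_tsv",
    "read_recovery_tsv",
    "write_recovery_tsv",
    "read_titration_tsv",
    "write_titration_tsv",
    "read_itc_tsv",
]


# --------------------------------------------------------------------- REDOR


def read_curves_tsv(path) -> list[RedorCurve]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    curves = []
    for site, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("mixing_time_s")
        if "s_ratio" in grp.columns:
            ratio = grp["s_ratio"].to_numpy(float)
        else:
            ratio = (grp["s"] / grp["s0"]).to_numpy(float)
        if "s_ratio_err" in grp.columns:
            err = grp["s_ratio_err"].to_numpy(float)
        elif {"snr_s", "snr_s0"} <= set(grp.columns):
            err = ratio * np.sqrt(
                grp["snr_s"].to_numpy(float) ** -2.0
                + grp["snr_s0"].to_numpy(float) ** -2.0
            )
        else:
            err = None
        overlapped = bool(grp["overlapped"].iloc[0]) if "overlapped" in grp else False
        curves.append(
            RedorCurve(
                site_id=str(site),
                mixing_times_s=grp["mixing_time_s"].to_numpy(float),
                s_ratio=ratio,
                s_ratio_err=err,
                overlapped=overlapped,
            )
        )
    return curves


def write_curves_tsv(curves: list[RedorCurve], path) -> None:
    rows = []
    for c in curves:
        for i, t in enumerate(c.mixing_times_s):
            rows.append(
                {
                    "site_id": c.site_id,
                    "mixing_time_s": t,
                    "s_ratio": c.s_ratio[i],
                    "s_ratio_err": (
                        c.s_ratio_err[i] if c.s_ratio_err is not None else np.nan
                    ),
                    "overlapped": c.overlapped,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fits_tsv(fits: list[DistanceFit], path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": f.site_id,
                "best_distance": f.best_distance,
                "lower": f.lower,
                "upper": f.upper,
                "is_lower_bound_only": f.is_lower_bound_only,
                "best_rmsd": f.best_rmsd,
            }
            for f in fits
        ]
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- restraints


def write_restraints_tsv(restraints: list[AmbiguousRestraint], path) -> None:
    rows = []
    for r in restraints:
        row = {
            "proton": str(r.proton_site),
            "kind": r.kind,
            "lower": r.lower,
            "upper": r.upper,
            "target": r.target if r.target is not None else np.nan,
            "assigned": str(r.assigned_fluorine) if r.assigned_fluorine else "",
        }
        for i, f in enumerate(r.fluorine_sites, start=1):
            row[f"fluorine_{i}"] = str(f)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path) -> list[AmbiguousRestraint]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        target = row.get("target", "")
        out.append(
            AmbiguousRestraint(
                proton_site=AtomSelector.parse(row["proton"]),
                fluorine_sites=tuple(
                    AtomSelector.parse(row[f"fluorine_{i}"]) for i in range(1, 5)
                ),
                kind=row["kind"],
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                target=(
                    float(target)
                    if target not in ("", "nan") and not pd.isna(target)
                    else None
                ),
                assigned_fluorine=(
                    AtomSelector.parse(row["assigned"]) if row["assigned"] else None
                ),
            )
        )
    return out


def export_md_restraints(
    restraints: list[AmbiguousRestraint],
    model: StructureModel,
    path,
    flat_width_angstrom: float = 0.5,
) -> None:
    """Export single-pair restraints as an r0/r1/r2 distance-restraint table.

    Mirrors a piecewise-linear restraining potential: restoring force below
    r0 and between r1 and r2, flat in [r0, r1], constant above r2 (r2 = r1
    + ``flat_width_angstrom``).  Atom indices follow the model's atom
    order.  Ambiguous (unassigned measured) restraints are skipped.
    """
    index = {key: i + 1 for i, key in enumerate(model.atom_keys)}
    rows = []
    for r in restraints:
        partner = r.assigned_fluorine
        if partner is None:
            continue
        ai = index[(r.proton_site.chain, r.proton_site.resseq, r.proton_site.atom)]
        aj = index[(partner.chain, partner.resseq, partner.atom)]
        upper = r.upper if np.isfinite(r.upper) else 999.0
        rows.append(
            {
                "ai": ai,
                "aj": aj,
                "r0": r.lower,
                "r1": upper,
                "r2": upper + flat_width_angstrom,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- exchange


def write_exchange_tsv(dataset: ExchangeDataset, path) -> None:
    rows = []
    for it, t in enumerate(dataset.mixing_times_s):
        for i in range(4):
            for j in range(4):
                rows.append(
                    {
                        "mixing_time_s": t,
                        "peak_from": i + 1,
                        "peak_to": j + 1,
                        "volume": dataset.volumes[it, i, j],
                        "snr": dataset.snr[it, i, j],
                        "snr_norm": dataset.snr_norm[i],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exchange_tsv(path) -> ExchangeDataset:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    times = np.sort(df["mixing_time_s"].unique())
    volumes = np.zeros((len(times), 4, 4))
    snr = np.zeros_like(volumes)
    snr_norm = np.zeros(4)
    t_index = {t: i for i, t in enumerate(times)}
    for _, row in df.iterrows():
        it = t_index[row["mixing_time_s"]]
        i, j = int(row["peak_from"]) - 1, int(row["peak_to"]) - 1
        volumes[it, i, j] = row["volume"]
        snr[it, i, j] = row["snr"]
        snr_norm[i] = row["snr_norm"]
    return ExchangeDataset(
        mixing_times_s=times, volumes=volumes, snr=snr, snr_norm=snr_norm
    )


# ----------------------------------------------------- recovery and titration


def write_recovery_tsv(curves: list[RecoveryCurve], path) -> None:
    rows = []
    for c in curves:
        for i, t in enumerate(c.relax_delays_s):
            rows.append(
                {
                    "site_id": c.site_id,
                    "relax_delay_s": t,
                    "intensity": c.intensities[i],
                    "error": c.errors[i] if c.errors is not None else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_recovery_tsv(path) -> list[RecoveryCurve]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for site, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("relax_delay_s")
        err = grp["error"].to_numpy(float) if "error" in grp.columns else None
        if err is not None and np.all(np.isnan(err)):
            err = None
        out.append(
            RecoveryCurve(
                site_id=str(site),
                relax_delays_s=grp["relax_delay_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                errors=err,
            )
        )
    return out


def read_titration_tsv(path) -> list[TitrationSeries]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for (res, nuc), grp in df.groupby(["residue", "nucleus"], sort=False):
        grp = grp.sort_values("ph")
        out.append(
            TitrationSeries(
                residue_id=str(res),
                nucleus=str(nuc),
                ph=grp["ph"].to_numpy(float),
                shift_ppm=grp["shift_ppm"].to_numpy(float),
            )
        )
    return out


def write_titration_tsv(series: list[TitrationSeries], path) -> None:
    rows = []
    for s in series:
        for i, ph in enumerate(s.ph):
            rows.append(
                {
                    "residue": s.residue_id,
                    "nucleus": s.nucleus,
                    "ph": ph,
                    "shift_ppm": s.shift_ppm[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_itc_tsv(path) -> list[ItcSeries]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for ph, grp in df.groupby("ph", sort=True):
        out.append(
            ItcSeries(
                ph=float(ph),
                dh_ionization_kj_mol=grp["dh_ion"].to_numpy(float),
                dh_observed_kj_mol=grp["dh_obs"].to_numpy(float),
                dg_kj_mol=float(grp["dg"].iloc[0]),
            )
        )
    return out
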