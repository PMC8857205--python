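"""Henderson-Hasselbalch pKa fitting, composite shifts, temperature, ITC.

A single titratable group shifts each reporter resonance between its
protonated (delta_H) and deprotonated (delta_D) endpoint values:

    delta(pH) = (delta_H 10^-pH + delta_D 10^-pKa) / (10^-pH + 10^-pKa)

Several residues near the protonation site are fit globally to one shared
pKa with free per-residue endpoints.  The module also provides the
composite 1H/15N (and 13C) shift-difference norm, the water-shift sample
temperature calibration Teff(K) = 96.9 (7.83 - delta_H2O), and the ITC
buffer-ionization extrapolation that separates intrinsic binding enthalpy
from buffer deprotonation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationSeries",
    "PkaFit",
    "ItcSeries",
    "hh_shift",
    "global_fit_pka",
    "composite_shift_diff",
    "effective_temperature",
    "itc_extrapolate",
]


@dataclass
class TitrationSeries:
    """Chemical shifts of one residue/nucleus across pH values."""

    residue_id: str
    nucleus: str  # "H" | "N" | "CA" | "CO"
    ph: np.ndarray
    shift_ppm: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, float)
        self.shift_ppm = np.asarray(self.shift_ppm, float)
        if self.ph.shape != self.shift_ppm.shape:
            raise ValueError("pH and shift arrays differ in length")


@dataclass
class PkaFit:
    """Globally shared pKa with per-series endpoints."""

    pka: float
    sigma_pka: float
    endpoints: dict[str, tuple[float, float]]  # series key -> (delta_H, delta_D)
    excluded: list[str]


def hh_shift(ph, pka, delta_h, delta_d):
    """Henderson-Hasselbalch chemical shift at a given pH."""
    ph = np.asarray(ph, float)
    wa = 10.0 ** (-ph)
    wb = 10.0 ** (-pka)
    out = (delta_h * wa + delta_d * wb) / (wa + wb)
    return out if out.ndim else float(out)


def _endpoints_for(pka: float, s: TitrationSeries) -> tuple[float, float, float]:
    """Linear least-squares endpoints for a fixed pKa; returns (dH, dD, sse)."""
    wa = 10.0 ** (-s.ph)
    wb = 10.0 ** (-pka)
    fa = wa / (wa + wb)
    design = np.column_stack([fa, 1.0 - fa])
    coef, *_ = np.linalg.lstsq(design, s.shift_ppm, rcond=None)
    resid = s.shift_ppm - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _series_key(s: TitrationSeries) -> str:
    return f"{s.residue_id}:{s.nucleus}"


def global_fit_pka(
    series: list[TitrationSeries],
    n_mc: int = 200,
    seed: int = 0,
    pka_bounds: tuple[float, float] = (2.0, 12.0),
    flat_range_ppm: float = 1e-4,
) -> PkaFit:
    """Fit one shared pKa across residues, endpoints free per series.

    For a fixed pKa the endpoints are linear parameters, so the profile
    objective is minimized over pKa alone (bounded scalar search).  Flat
    series (shift range below ``flat_range_ppm``) are excluded with a
    warning.  sigma_pka is the sd of refits over Monte-Carlo resampled
    datasets perturbed by each series' residual scale.
    """
    if not series:
        raise ValueError("need at least one titration series")
    active = []
    excluded = []
    for s in series:
        if np.ptp(s.shift_ppm) < flat_range_ppm:
            excluded.append(_series_key(s))
        else:
            active.append(s)
    if excluded:
        warnings.warn(f"excluding flat series: {excluded}", stacklevel=2)
    if not active:
        raise ValueError("all series are flat; nothing to fit")

    def sse_total(pka: float, members: list[TitrationSeries]) -> float:
        return sum(_endpoints_for(pka, s)[2] for s in members)

    def solve(members: list[TitrationSeries]) -> float:
        res = minimize_scalar(
            sse_total, args=(members,), bounds=pka_bounds, method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x)

    pka = solve(active)
    endpoints = {
        _series_key(s): _endpoints_for(pka, s)[:2] for s in active
    }

    rng = np.random.default_rng(seed)
    noise_scales = []
    for s in active:
        _, _, sse = _endpoints_for(pka, s)
        dof = max(len(s.ph) - 3, 1)
        noise_scales.append(np.sqrt(sse / dof))
    draws = []
    for _ in range(n_mc):
        perturbed = [
            TitrationSeries(
                s.residue_id,
                s.nucleus,
                s.ph,
                s.shift_ppm + rng.normal(0.0, sc, size=s.ph.shape),
            )
            for s, sc in zip(active, noise_scales)
        ]
        draws.append(solve(perturbed))
    sigma = float(np.std(draws, ddof=1)) if len(draws) > 1 else float("nan")
    return PkaFit(pka=pka, sigma_pka=sigma, endpoints=endpoints, excluded=excluded)


def composite_shift_diff(delta_h, delta_n, scale: float = 0.10):
    """Composite shift difference sqrt(0.5 [dH^2 + (scale*dN)^2]).

    ``scale=0.10`` weights 15N against 1H; use ``scale=1.0`` for the
    CA/CO carbon composite.
    """
    delta_h = np.asarray(delta_h, float)
    delta_n = np.asarray(delta_n, float)
    out = np.sqrt(0.5 * (delta_h**2 + (scale * delta_n) ** 2))
    return out if out.ndim else float(out)


def effective_temperature(delta_water_ppm: float) -> float:
    """Sample temperature from the water 1H shift: Teff = 96.9 (7.83 - d)."""
    t = 96.9 * (7.83 - delta_water_ppm)
    if t <= 0:
        warnings.warn(
            f"water shift {delta_water_ppm} ppm gives non-physical {t:.1f} K",
            stacklevel=2,
        )
    return t


@dataclass
class ItcSeries:
    """Observed binding enthalpies across buffers at one pH."""

    ph: float
    dh_ionization_kj_mol: np.ndarray
    dh_observed_kj_mol: np.ndarray
    dg_kj_mol: float

    def __post_init__(self) -> None:
        self.dh_ionization_kj_mol = np.asarray(self.dh_ionization_kj_mol, float)
        self.dh_observed_kj_mol = np.asarray(self.dh_observed_kj_mol, float)
        if len(self.dh_ionization_kj_mol) < 2:
            raise ValueError("need at least two buffers for extrapolation")


def itc_extrapolate(series: ItcSeries) -> tuple[float, float, float]:
    """Extrapolate observed enthalpy to zero buffer-ionization enthalpy.

    Linear regression of dH_obs on dH_ion: the intercept is the
    buffer-independent binding enthalpy, the slope the number of protons
    released, and the entropic term follows from dG = dH - T dS, i.e.
    -T dS = dG - dH.  Returns (dH_binding, -T dS, n_protons).
    """
    x = series.dh_ionization_kj_mol
    if np.ptp(x) == 0:
        raise ValueError("buffers share one ionization enthalpy (singular design)")
    slope, intercept = np.polyfit(x, series.dh_observed_kj_mol, 1)
    dh = float(intercept)
    minus_tds = series.dg_kj_mol - dh
    return dh, float(minus_tds), float(slope)
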