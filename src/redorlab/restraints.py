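"""Four-fold-ambiguous H(N)-F distance restraints and structure scoring.

The ligand carries four chemically equivalent fluorines, so a measured
amide-proton dephasing cannot by itself be assigned to one fluorine: a
measured restraint is satisfied if the *nearest* of the four fluorines lies
within the fitted distance interval.  Weak dephasing only bounds the
distance from below; such a measurement expands into four independent
single-pair constraints requiring every fluorine to be at least 10 A away.
Candidate structures are scored by their total violation and their number
of violations, and the best structure is used to disambiguate the measured
restraints to specific proton-fluorine pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .spinsim import DistanceFit, WEAK_LOWER_A
from .structures import AtomSelector, StructureEnsemble, StructureModel

__all__ = [
    "AmbiguousRestraint",
    "ViolationReport",
    "effective_distance",
    "violation",
    "score_structures",
    "build_restraints",
    "disambiguate",
]

DISTANCE_TIE_TOL_A = 1e-6


@dataclass(frozen=True)
class AmbiguousRestraint:
    """One proton site versus the four equivalent ligand fluorines."""

    proton_site: AtomSelector
    fluorine_sites: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]
    kind: str  # "measured" | "lower_bound"
    lower: float
    upper: float
    target: float | None = None
    assigned_fluorine: AtomSelector | None = None

    def __post_init__(self) -> None:
        if len(self.fluorine_sites) != 4:
            raise ValueError("exactly four fluorine sites are required")
        if self.kind not in ("measured", "lower_bound"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if not self.lower <= self.upper:
            raise ValueError("require lower <= upper")
        if self.kind == "lower_bound" and self.target is not None:
            raise ValueError("lower-bound restraints carry no target distance")


@dataclass
class ViolationReport:
    """Per-model violation statistics."""

    model_id: str
    sum_violation: float
    n_violations: int
    per_restraint: dict[int, float] = field(default_factory=dict)


def _pair_distances(model: StructureModel, r: AmbiguousRestraint) -> np.ndarray:
    p = model.position(r.proton_site)
    return np.array(
        [np.linalg.norm(p - model.position(f)) for f in r.fluorine_sites]
    )


def effective_distance(model: StructureModel, r: AmbiguousRestraint) -> float:
    """Minimum proton-fluorine distance, or the assigned pair's distance."""
    if r.assigned_fluorine is not None:
        p = model.position(r.proton_site)
        return float(np.linalg.norm(p - model.position(r.assigned_fluorine)))
    return float(_pair_distances(model, r).min())


def violation(model: StructureModel, r: AmbiguousRestraint) -> float:
    """Violation magnitude (A) of one restraint in one model.

    Measured restraints penalize the effective distance falling outside
    [lower, upper].  Lower-bound restraints require each fluorine (or only
    the assigned one, if set) to individually satisfy the bound; shortfalls
    are summed.
    """
    if r.kind == "measured":
        d = effective_distance(model, r)
        return max(0.0, d - r.upper) + max(0.0, r.lower - d)
    if r.assigned_fluorine is not None:
        d = effective_distance(model, r)
        return max(0.0, r.lower - d)
    return float(np.maximum(0.0, r.lower - _pair_distances(model, r)).sum())


def score_structures(
    ensemble: StructureEnsemble, restraints: list[AmbiguousRestraint]
) -> tuple[list[ViolationReport], list[int], list[int]]:
    """Score every model; return reports and two rankings (model indices).

    Ranking A orders by ascending sum of violations; ranking B by ascending
    violation count, ties broken by the sum.  Both are stable with respect
    to the input model order.
    """
    if len(ensemble) < 1 or len(restraints) < 1:
        raise ValueError("need at least one model and one restraint")
    reports = []
    for model in ensemble:
        per = {i: violation(model, r) for i, r in enumerate(restraints)}
        reports.append(
            ViolationReport(
                model_id=model.model_id,
                sum_violation=float(sum(per.values())),
                n_violations=int(sum(v > 0 for v in per.values())),
                per_restraint=per,
            )
        )
    order = range(len(reports))
    rank_sum = sorted(order, key=lambda i: (reports[i].sum_violation, i))
    rank_count = sorted(
        order, key=lambda i: (reports[i].n_violations, reports[i].sum_violation, i)
    )
    return reports, rank_sum, rank_count


def build_restraints(
    fits: list[DistanceFit],
    site_map: dict[str, tuple[AtomSelector, tuple[AtomSelector, ...]]],
) -> list[AmbiguousRestraint]:
    """Turn distance fits into restraints.

    ``site_map`` maps each fit's site id to its proton selector and the four
    fluorine selectors.  A lower-bound-only fit expands into four >= 10 A
    single-pair constraints (one per fluorine); a measured fit yields one
    ambiguous restraint with the fitted [lower, upper] interval, so the
    total count is 4 * n_weak + n_measured.
    """
    out: list[AmbiguousRestraint] = []
    for fit in fits:
        if fit.site_id not in site_map:
            raise KeyError(f"no proton/fluorine mapping for site {fit.site_id!r}")
        proton, fluorines = site_map[fit.site_id]
        fluorines = tuple(fluorines)
        if fit.is_lower_bound_only:
            for f in fluorines:
                out.append(
                    AmbiguousRestraint(
                        proton_site=proton,
                        fluorine_sites=fluorines,
                        kind="lower_bound",
                        lower=WEAK_LOWER_A,
                        upper=float("inf"),
                        assigned_fluorine=f,
                    )
                )
        else:
            out.append(
                AmbiguousRestraint(
                    proton_site=proton,
                    fluorine_sites=fluorines,
                    kind="measured",
                    lower=fit.lower,
                    upper=fit.upper,
                    target=fit.best_distance,
                )
            )
    return out


def disambiguate(
    restraints: list[AmbiguousRestraint], reference: StructureModel
) -> list[AmbiguousRestraint]:
    """Assign each measured restraint to the nearest fluorine in a reference.

    Ties within 1e-6 A keep the restraint ambiguous (with a warning).
    Because the nearest fluorine realizes the effective distance, the
    assignment leaves every violation unchanged on the reference model.
    """
    out = []
    for r in restraints:
        if r.kind != "measured" or r.assigned_fluorine is not None:
            out.append(r)
            continue
        d = _pair_distances(reference, r)
        order = np.argsort(d)
        if d[order[1]] - d[order[0]] < DISTANCE_TIE_TOL_A:
            warnings.warn(
                f"restraint {r.proton_site}: nearest-fluorine tie within "
                f"{DISTANCE_TIE_TOL_A} A; keeping ambiguous",
                stacklevel=2,
            )
            out.append(r)
        else:
            out.append(replace(r, assigned_fluorine=r.fluorine_sites[order[0]]))
    return out
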