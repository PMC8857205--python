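"""Structural-ensemble metrics: pairwise RMSD, ensemble distances, waters.

Pairwise RMSD superposes each model pair on the same atom selection that is
being measured (switchable to a common backbone superposition).  Ensemble
distances are per-model Euclidean (or minimum-over-set) distances reduced
to mean +/- sd across models.  Binding-pocket waters are oxygens within a
cutoff of any ligand atom whose z coordinate lies between two bounding
atoms, assuming the deposited frame has z along the membrane normal.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    AtomSelector,
    Selection,
    StructureEnsemble,
    StructureModel,
    WATER_RESNAMES,
)

__all__ = [
    "superpose",
    "pairwise_rmsd",
    "ensemble_distance",
    "count_pocket_waters",
]


def superpose(
    model_a: StructureModel, model_b: StructureModel, selection: Selection
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of b onto a over a selection.

    Returns (rotation 3x3, translation 3, post-fit RMSD in A).  Requires at
    least three non-collinear selected atoms.
    """
    keys = selection.keys(model_a)
    keys = [k for k in keys if k in model_b._coords]
    if len(keys) < 3:
        raise ValueError("selection must resolve to >= 3 shared atoms")
    xa = model_a.coords_for(keys)
    xb = model_b.coords_for(keys)
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    ya, yb = xa - ca, xb - cb
    if np.linalg.matrix_rank(ya, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, rssd = Rotation.align_vectors(ya, yb)
    rmsd = rssd / np.sqrt(len(keys))
    translation = ca - rot.as_matrix() @ cb
    return rot.as_matrix(), translation, float(rmsd)


def pairwise_rmsd(
    ensemble: StructureEnsemble,
    selection: Selection,
    superpose_on: Selection | None = None,
) -> tuple[float, float]:
    """Mean +/- sd of RMSD over all model pairs.

    By default each pair is superposed on the measured selection itself;
    pass ``superpose_on`` (e.g. the backbone) to fit on one selection and
    measure on another.  The sd uses n-1 degrees of freedom.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two models")
    vals = []
    for a, b in itertools.combinations(range(len(ensemble)), 2):
        ma, mb = ensemble[a], ensemble[b]
        if superpose_on is None:
            _, _, rmsd = superpose(ma, mb, selection)
        else:
            rot, trans, _ = superpose(ma, mb, superpose_on)
            keys = [k for k in selection.keys(ma) if k in mb._coords]
            if len(keys) == 0:
                raise ValueError("selection resolves to no shared atoms")
            xa = ma.coords_for(keys)
            xb = mb.coords_for(keys) @ rot.T + trans
            rmsd = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
        vals.append(rmsd)
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def ensemble_distance(
    ensemble: StructureEnsemble,
    sel_a: AtomSelector,
    sel_b: AtomSelector | list[AtomSelector],
    reducer: str = "pair",
) -> tuple[float, float]:
    """Ensemble mean +/- sd of an inter-atomic distance.

    ``reducer='pair'`` takes a single atom on each side; ``'min_over_b'``
    takes the minimum distance from atom a to a set of atoms b per model.
    """
    vals = []
    for model in ensemble:
        pa = model.position(sel_a)
        if reducer == "pair":
            if isinstance(sel_b, list):
                raise ValueError("pair reducer needs a single atom on each side")
            vals.append(np.linalg.norm(pa - model.position(sel_b)))
        elif reducer == "min_over_b":
            bs = sel_b if isinstance(sel_b, list) else [sel_b]
            vals.append(
                min(np.linalg.norm(pa - model.position(b)) for b in bs)
            )
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    vals = np.asarray(vals, float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def count_pocket_waters(
    model: StructureModel,
    ligand_selection: Selection,
    z_bound_atoms: tuple[AtomSelector, AtomSelector],
    cutoff_angstrom: float = 15.0,
) -> int:
    """Count water oxygens near the ligand inside the membrane z-window.

    A water oxygen counts if it lies within ``cutoff_angstrom`` of *any*
    ligand atom and its z coordinate falls between the z coordinates of the
    two bounding atoms (order-normalized).
    """
    lig_keys = ligand_selection.keys(model)
    if not lig_keys:
        raise ValueError("ligand selection resolves to no atoms")
    lig = model.coords_for(lig_keys)
    z1 = model.position(z_bound_atoms[0])[2]
    z2 = model.position(z_bound_atoms[1])[2]
    z_lo, z_hi = min(z1, z2), max(z1, z2)
    count = 0
    for key in model.atom_keys:
        chain, resseq, atom = key
        resname, element = model._meta[key]
        if resname not in WATER_RESNAMES or element.upper() != "O":
            continue
        pos = model._coords[key]
        if not (z_lo <= pos[2] <= z_hi):
            continue
        if np.min(np.linalg.norm(lig - pos, axis=1)) <= cutoff_angstrom:
            count += 1
    return count
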