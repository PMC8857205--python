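"""Shared structural containers: atom selectors, models, multi-model ensembles.

Structures are read with gemmi (PDB and mmCIF, MODEL/ENDMDL records define
the ensemble).  Alternate locations prefer blank then 'A'; insertion codes
are rejected because the selection grammar has no way to address them.

Selections use a small ``chain:resrange:atoms`` grammar, e.g.::

    A:1-105:N,CA,C,O     backbone of chain A residues 1-105
    *:*:P                every atom named P
    A,B:14:CD            E14 side-chain carboxyl carbons of both chains

plus named presets ``backbone`` (N, CA, C, O) and ``heavy`` (non-hydrogen).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSelector",
    "StructureModel",
    "StructureEnsemble",
    "Selection",
    "load_ensemble",
    "write_ensemble_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"}


@dataclass(frozen=True)
class AtomSelector:
    """One atom addressed by chain, residue number, and atom name."""

    chain: str
    resseq: int
    atom: str

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        chain, resseq, atom = text.split(":")
        return cls(chain, int(resseq), atom)

    def __str__(self) -> str:
        return f"{self.chain}:{self.resseq}:{self.atom}"


class StructureModel:
    """One atomic model with O(1) atom lookup by (chain, resseq, atom name)."""

    def __init__(self, model_id: str):
        self.model_id = model_id
        self._coords: dict[tuple[str, int, str], np.ndarray] = {}
        self._meta: dict[tuple[str, int, str], tuple[str, str]] = {}  # resname, element

    def add_atom(
        self,
        chain: str,
        resseq: int,
        resname: str,
        atom: str,
        element: str,
        xyz,
    ) -> None:
        key = (chain, resseq, atom)
        self._coords[key] = np.asarray(xyz, float)
        self._meta[key] = (resname, element)

    @property
    def atom_keys(self) -> list[tuple[str, int, str]]:
        return list(self._coords)

    def position(self, sel: AtomSelector) -> np.ndarray:
        try:
            return self._coords[(sel.chain, sel.resseq, sel.atom)]
        except KeyError:
            raise KeyError(f"atom {sel} not found in model {self.model_id}") from None

    def has(self, sel: AtomSelector) -> bool:
        return (sel.chain, sel.resseq, sel.atom) in self._coords

    def resname(self, chain: str, resseq: int, atom: str) -> str:
        return self._meta[(chain, resseq, atom)][0]

    def element(self, chain: str, resseq: int, atom: str) -> str:
        return self._meta[(chain, resseq, atom)][1]

    def coords_for(self, keys) -> np.ndarray:
        return np.array([self._coords[k] for k in keys])


@dataclass
class StructureEnsemble:
    """Ordered set of models sharing an atom dictionary."""

    models: list[StructureModel]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i) -> StructureModel:
        return self.models[i]


class Selection:
    """Predicate over (chain, resseq, atom name, resname, element)."""

    def __init__(
        self,
        chains: set[str] | None = None,
        res_range: tuple[int, int] | None = None,
        atoms: set[str] | None = None,
        heavy_only: bool = False,
        exclude_water: bool = True,
    ):
        self.chains = chains
        self.res_range = res_range
        self.atoms = atoms
        self.heavy_only = heavy_only
        self.exclude_water = exclude_water

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``chain:resrange:atoms`` or the presets backbone / heavy."""
        if text == "backbone":
            return cls(atoms=set(BACKBONE_ATOMS))
        if text == "heavy":
            return cls(heavy_only=True)
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"cannot parse selection {text!r}")
        chain_s, res_s, atom_s = parts
        chains = None if chain_s == "*" else set(chain_s.split(","))
        if res_s == "*":
            res_range = None
        elif "-" in res_s:
            lo, hi = res_s.split("-")
            res_range = (int(lo), int(hi))
        else:
            res_range = (int(res_s), int(res_s))
        atoms = None if atom_s == "*" else set(atom_s.split(","))
        return cls(chains=chains, res_range=res_range, atoms=atoms)

    def keys(self, model: StructureModel) -> list[tuple[str, int, str]]:
        out = []
        for key in model.atom_keys:
            chain, resseq, atom = key
            resname, element = model._meta[key]
            if self.exclude_water and resname in WATER_RESNAMES:
                continue
            if self.chains is not None and chain not in self.chains:
                continue
            if self.res_range is not None and not (
                self.res_range[0] <= resseq <= self.res_range[1]
            ):
                continue
            if self.atoms is not None and atom not in self.atoms:
                continue
            if self.heavy_only and element.upper() in ("H", "D"):
                continue
            out.append(key)
        return out


def _to_model(gm: gemmi.Model, model_id: str) -> StructureModel:
    model = StructureModel(model_id)
    for chain in gm:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at {chain.name}:{res.seqid.num} "
                    "is not supported"
                )
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue  # prefer blank altloc, then A
                model.add_atom(
                    chain.name,
                    res.seqid.num,
                    res.name,
                    atom.name,
                    atom.element.name,
                    [atom.pos.x, atom.pos.y, atom.pos.z],
                )
    return model


def load_ensemble(path) -> StructureEnsemble:
    """Read a multi-model PDB or mmCIF file into a StructureEnsemble."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = [
        _to_model(m, str(getattr(m, "name", None) or getattr(m, "num", i + 1)))
        for i, m in enumerate(st)
    ]
    if not models:
        raise ValueError(f"no models found in {path}")
    return StructureEnsemble(models)


def write_ensemble_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write models as a multi-model PDB (MODEL/ENDMDL records)."""
    lines = []
    for i, model in enumerate(ensemble, start=1):
        lines.append(f"MODEL     {i:4d}")
        serial = 1
        for (chain, resseq, atom), xyz in model._coords.items():
            resname, element = model._meta[(chain, resseq, atom)]
            record = "HETATM" if resname in WATER_RESNAMES | {"TPP", "LIG"} else "ATOM  "
            name = atom if len(atom) >= 4 else f" {atom:<3s}"
            lines.append(
                f"{record}{serial:5d} {name:<4s}{resname:>4s} {chain:1s}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
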