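"""Structure parsing, segment excision and legacy-position bookkeeping.

A prepared protein chain is represented as an ordered list of residues in
"legacy" numbering: the 1-based mature-protein numbering of the source
database, with negative positions denoting a signal peptide.  Excising
segments (e.g. a proteolytically removed domain) renumbers the survivors
into contiguous 0-based node indices; :class:`NodeIndexMap` records the
bijection so that mutation positions quoted in legacy coordinates can be
placed on network nodes later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ExcisionPlan",
    "NodeIndexMap",
    "FVIII_EXCISION_PLAN",
    "parse_structure",
    "excise_segments",
    "map_legacy_position",
]

#: Three- to one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    legacy_position: int
    name: str  # 3-letter code
    atoms: list[Atom]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """One protein chain: ordered residues with atom coordinates."""

    chain_id: str
    residues: list[Residue]
    has_hydrogens: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError("structure contains no residues")
        positions = [r.legacy_position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise StructureError("legacy positions must be strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise StructureError(f"residue {r.legacy_position} has no atoms")
            for a in r.atoms:
                if not all(math.isfinite(c) for c in a.xyz):
                    raise StructureError(
                        f"non-finite coordinate in residue {r.legacy_position}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def legacy_positions(self) -> list[int]:
        return [r.legacy_position for r in self.residues]

    def sequence(self) -> str:
        """One-letter sequence in residue order (X for non-standard)."""
        return "".join(r.one_letter for r in self.residues)

    def sequence_by_position(self) -> dict[int, str]:
        return {r.legacy_position: r.one_letter for r in self.residues}


@dataclass(frozen=True)
class ExcisionPlan:
    """Closed intervals of legacy positions to remove, normalized and sorted."""

    ranges: tuple[tuple[int, int], ...] = ()

    def __init__(self, ranges: Iterable[tuple[int, int]] = ()):
        norm = []
        for start, end in ranges:
            if start > end:
                raise ValueError(f"malformed interval: start {start} > end {end}")
            norm.append((int(start), int(end)))
        norm.sort()
        # merge overlapping / adjacent intervals
        merged: list[tuple[int, int]] = []
        for start, end in norm:
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "ranges", tuple(merged))

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.ranges)


#: Default plan for activated coagulation factor VIII: remove the signal
#: peptide and the a1/a2 linker and B-domain segments (legacy numbering).
FVIII_EXCISION_PLAN = ExcisionPlan([(-19, -1), (336, 372), (711, 740), (741, 1689)])


@dataclass
class NodeIndexMap:
    """Bijection legacy position -> contiguous 0-based node id (order preserving)."""

    pairs: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, pos: int) -> Optional[int]:
        return self.pairs.get(pos)

    def positions(self) -> list[int]:
        return sorted(self.pairs, key=self.pairs.get)

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.pairs.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("legacy_position\tnode_id\n")
            for pos in self.positions():
                fh.write(f"{pos}\t{self.pairs[pos]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeIndexMap":
        pairs = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("legacy_position"):
                fh.seek(0)
            for line in fh:
                pos, nid = line.split()
                pairs[int(pos)] = int(nid)
        return cls(pairs)


def _load_atom_array(path: str | Path):
    """Read the first model of a PDB or mmCIF file into a biotite AtomArray."""
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            cif = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(
                cif, model=1, altloc="all", extra_fields=["occupancy"]
            )
        else:
            pdb_file = pdb.PDBFile.read(str(path))
            atoms = pdb_file.get_structure(
                model=1, altloc="all", extra_fields=["occupancy"]
            )
    except Exception as exc:  # noqa: BLE001 - rewrap as domain error
        raise StructureError(f"could not parse structure file {path}: {exc}") from exc
    return atoms


def parse_structure(path: str | Path, chain: str) -> StructureModel:
    """Parse one chain of a PDB/mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc letter); insertion codes are rejected because
    they would corrupt the legacy-position bookkeeping.  Hydrogens are
    retained in the model (and flagged) but downstream geometry defaults
    to heavy atoms only.
    """
    import biotite.structure as struc

    atoms = _load_atom_array(path)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        available = sorted(set(_load_atom_array(path).chain_id))
        raise StructureError(
            f"chain {chain!r} not found or empty (available: {available})"
        )
    if any(code.strip() for code in atoms.ins_code):
        raise StructureError(
            "structure uses insertion codes; renumber before use to keep "
            "legacy positions unambiguous"
        )

    residues: list[Residue] = []
    has_hydrogens = False
    seen_order: list[int] = []
    by_res: dict[int, dict[str, tuple]] = {}
    for i in range(atoms.array_length()):
        res_id = int(atoms.res_id[i])
        if res_id not in by_res:
            by_res[res_id] = {}
            seen_order.append(res_id)
        name = str(atoms.atom_name[i])
        occ = float(atoms.occupancy[i]) if atoms.occupancy is not None else 1.0
        altloc = str(atoms.altloc_id[i]) if hasattr(atoms, "altloc_id") else ""
        entry = (occ, altloc, i)
        prev = by_res[res_id].get(name)
        # keep highest occupancy; ties broken by altloc letter order
        if prev is None or occ > prev[0] or (occ == prev[0] and altloc < prev[1]):
            by_res[res_id][name] = entry

    for res_id in seen_order:
        chosen = by_res[res_id]
        idx = [entry[2] for entry in chosen.values()]
        idx.sort()
        res_atoms = []
        res_name = str(atoms.res_name[idx[0]])
        for i in idx:
            element = str(atoms.element[i])
            if element.upper() in ("H", "D"):
                has_hydrogens = True
            res_atoms.append(
                Atom(
                    name=str(atoms.atom_name[i]),
                    element=element,
                    xyz=tuple(float(c) for c in atoms.coord[i]),
                )
            )
        residues.append(Residue(legacy_position=res_id, name=res_name, atoms=res_atoms))

    return StructureModel(chain_id=chain, residues=residues, has_hydrogens=has_hydrogens)


def excise_segments(
    s: StructureModel, plan: ExcisionPlan
) -> tuple[StructureModel, NodeIndexMap]:
    """Remove all residues inside the plan's intervals; renumber survivors.

    Returns the excised structure and the legacy-position -> node-id map.
    Relative residue order is preserved and node ids are contiguous from 0.
    """
    survivors = [r for r in s.residues if not plan.contains(r.legacy_position)]
    if not survivors:
        raise StructureError("excision plan removes every residue")
    mapping = NodeIndexMap(
        {r.legacy_position: i for i, r in enumerate(survivors)}
    )
    out = StructureModel(
        chain_id=s.chain_id, residues=survivors, has_hydrogens=s.has_hydrogens
    )
    return out, mapping


def map_legacy_position(m: NodeIndexMap, pos: int) -> Optional[int]:
    """Node id for a legacy position, or None for excised/out-of-range positions."""
    return m.get(pos)
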