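"""Protein structure containers and PDB I/O.

Structures are stored as a chain -> residue -> atom hierarchy. Predicted
models from AlphaFold-style predictors carry per-residue confidence
(pLDDT, 0-100) in the B-factor column; by convention the pLDDT of a
residue is the B-factor of its C-alpha atom.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Partition",
    "EmptyStructureError",
    "PartitionError",
    "read_pdb",
    "write_pdb",
    "write_fasta",
    "residue_plddt_profile",
    "split_partners",
]

# 3-letter -> 1-letter, standard residues plus common modified forms
# that map onto a parent amino acid.
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues with a standard parent
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "HYP": "P", "MLY": "K", "PCA": "E",
}

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class EmptyStructureError(ValueError):
    """Raised when a file or selection yields zero protein atoms."""


class PartitionError(ValueError):
    """Raised for invalid receptor/ligand chain partitions."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_pos: int
    aa: str  # one-letter code
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""  # PDB insertion code, usually empty

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def plddt(self) -> float:
        ca = self.ca
        if ca is None:
            raise ValueError(
                f"residue {self.chain_id}{self.seq_pos}{self.icode} has no CA atom; "
                "pLDDT undefined"
            )
        return ca.bfactor

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.icode)


class Structure:
    """An ordered collection of chains, each an ordered list of residues."""

    def __init__(self, id: str = "", chains: dict[str, list[Residue]] | None = None):
        self.id = id
        self.chains: dict[str, list[Residue]] = dict(chains) if chains else {}
        seen: set[tuple[str, int, str]] = set()
        for cid, residues in self.chains.items():
            for r in residues:
                if r.key in seen:
                    raise ValueError(f"duplicate residue {r.key} in structure {id!r}")
                seen.add(r.key)

    # -- iteration helpers -------------------------------------------------

    def residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues]

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue(self, chain_id: str, seq_pos: int, icode: str = "") -> Residue:
        for r in self.chains[chain_id]:
            if r.seq_pos == seq_pos and r.icode == icode:
                return r
        raise KeyError((chain_id, seq_pos, icode))

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    # -- bulk coordinate access (engine and metrics use these) -------------

    def coords(self) -> np.ndarray:
        """All atom coordinates, structure order, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = self.atoms()
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(atoms, coords):
            a.coords = xyz.copy()

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def subset(self, chain_ids: list[str], id: str | None = None) -> "Structure":
        missing = [c for c in chain_ids if c not in self.chains]
        if missing:
            raise KeyError(f"chains {missing} absent from structure {self.id!r}")
        chains = {c: copy.deepcopy(self.chains[c]) for c in chain_ids}
        return Structure(id if id is not None else self.id, chains)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Structure {self.id!r}: {len(self.chains)} chains, "
            f"{self.n_residues} residues, {self.n_atoms} atoms>"
        )


@dataclass(frozen=True)
class Partition:
    """Receptor/ligand split of a complex by chain id."""

    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]

    def __post_init__(self) -> None:
        rec, lig = set(self.receptor_chains), set(self.ligand_chains)
        if not rec or not lig:
            raise PartitionError("both partners need at least one chain")
        if rec & lig:
            raise PartitionError(f"chains {sorted(rec & lig)} on both partners")

    @classmethod
    def from_spec(cls, spec: str) -> "Partition":
        """Parse a partition string like ``"AB_C"`` (receptor_ligand)."""
        parts = spec.split("_")
        if len(parts) != 2 or not all(parts):
            raise PartitionError(
                f"partition spec {spec!r} must look like '<receptor>_<ligand>', e.g. 'A_B'"
            )
        rec, lig = tuple(parts[0]), tuple(parts[1])
        if len(set(rec)) != len(rec) or len(set(lig)) != len(lig):
            raise PartitionError(f"chain repeated within a partner in {spec!r}")
        return cls(rec, lig)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only protein ATOM records are kept (HETATM, waters, nucleic acids
    dropped); alternate locations are resolved to the highest-occupancy
    conformer. Modified residues with a standard parent (e.g. MSE) are
    mapped to the parent one-letter code; unknown residues are dropped
    with a warning.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    arr = arr[bts.filter_amino_acids(arr) & ~arr.hetero]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no protein ATOM records")

    chains: dict[str, list[Residue]] = {}
    res: Residue | None = None
    dropped: set[str] = set()
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        key = (cid, int(arr.res_id[i]), str(arr.ins_code[i]))
        if res is None or res.key != key:
            aa = _AA3TO1.get(str(arr.res_name[i]))
            if aa is None:
                dropped.add(str(arr.res_name[i]))
                res = None
                continue
            res = Residue(chain_id=cid, seq_pos=key[1], aa=aa, icode=key[2])
            chains.setdefault(cid, []).append(res)
        res.atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).capitalize(),
                coords=np.array(arr.coord[i], dtype=float),
                bfactor=float(arr.b_factor[i]),
            )
        )
    if dropped:
        warnings.warn(f"dropped residues without a standard parent: {sorted(dropped)}")
    if not chains:
        raise EmptyStructureError(f"{path}: no standard protein residues")

    import os

    return Structure(id=os.path.splitext(os.path.basename(str(path)))[0], chains=chains)


def write_pdb(structure: Structure, path) -> None:
    """Write ``structure`` as PDB ATOM records, one TER per chain."""
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    lines: list[str] = []
    serial = 1
    for cid, residues in structure.chains.items():
        last = None
        for r in residues:
            res3 = _AA1TO3.get(r.aa, "UNK")
            for a in r.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:>5d} {name:<4s} {res3:<3s} {cid:1s}"
                    f"{r.seq_pos:>4d}{r.icode or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{1.00:6.2f}{a.bfactor:6.2f}          "
                    f"{a.element.upper():>2s}  "
                )
                serial += 1
            last = r
        if last is not None:
            res3 = _AA1TO3.get(last.aa, "UNK")
            lines.append(
                f"TER   {serial:>5d}      {res3:<3s} {cid:1s}{last.seq_pos:>4d}"
                f"{last.icode or ' ':1s}"
            )
            serial += 1
    lines.append("END")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(structure: Structure, path) -> None:
    """One FASTA record per chain, id ``<structure id>_<chain>``."""
    with open(str(path), "w") as fh:
        for cid in structure.chain_ids():
            fh.write(f">{structure.id}_{cid}\n{structure.sequence(cid)}\n")


# ---------------------------------------------------------------------------
# pLDDT and partitioning
# ---------------------------------------------------------------------------

def residue_plddt_profile(structure: Structure) -> list[tuple[str, int, float]]:
    """Per-residue pLDDT profile ``[(chain_id, seq_pos, plddt), ...]``.

    pLDDT is read from the C-alpha B-factor; a residue without a C-alpha
    raises, naming the residue.
    """
    profile = []
    for r in structure.residues():
        profile.append((r.chain_id, r.seq_pos, r.plddt))
    return profile


def split_partners(
    structure: Structure, partition_spec: str
) -> tuple[Structure, Structure, Partition]:
    """Split a complex into (receptor, ligand, partition) per a spec like "AB_C"."""
    part = Partition.from_spec(partition_spec)
    for cid in part.receptor_chains + part.ligand_chains:
        if cid not in structure.chains:
            raise PartitionError(f"chain {cid!r} absent from structure {structure.id!r}")
    receptor = structure.subset(list(part.receptor_chains), id=f"{structure.id}_receptor")
    ligand = structure.subset(list(part.ligand_chains), id=f"{structure.id}_ligand")
    return receptor, ligand, part
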