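"""Docking quality assessment: fnat, interface RMSD, ligand RMSD, DockQ.

DockQ combines three classical CAPRI quantities into one score in [0, 1]:

    DockQ = (fnat + s(iRMSD, 1.5) + s(LRMSD, 8.5)) / 3,   s(x, d) = 1 / (1 + (x/d)^2)

* fnat — fraction of the native complex's cross-partner residue contacts
  (any heavy-atom pair < 5 A) reproduced by the model;
* iRMSD — backbone (N, CA, C, O) RMSD over native interface residues
  (10 A heavy-atom criterion) after superposing those residues;
* LRMSD — backbone RMSD over the ligand after superposing the receptors.

CAPRI categories: incorrect < 0.23 <= acceptable <= 0.49 < medium <= 0.8 < high.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import kabsch_superpose
from .structure_io import Partition, Residue, Structure

__all__ = [
    "CapriClass",
    "DockQResult",
    "native_contacts",
    "fnat",
    "interface_rmsd",
    "ligand_rmsd",
    "dockq",
    "dockq_score",
    "capri_class",
]

FNAT_CUTOFF = 5.0  # A, heavy-atom contact for fnat
IRMS_INTERFACE_CUTOFF = 10.0  # A, native interface definition for iRMSD
D1_IRMS = 1.5  # A, iRMSD scaling constant
D2_LRMS = 8.5  # A, LRMSD scaling constant
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class CapriClass(str, enum.Enum):
    INCORRECT = "incorrect"
    ACCEPTABLE = "acceptable"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass
class DockQResult:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    capri: CapriClass

    def to_dict(self) -> dict:
        return {
            "fnat": self.fnat,
            "irms": self.irms,
            "lrms": self.lrms,
            "dockq": self.dockq,
            "capri": self.capri.value,
        }


def _partner_residues(
    complex: Structure, partition: Partition
) -> tuple[list[Residue], list[Residue]]:
    rec = [r for c in partition.receptor_chains for r in complex.chains[c]]
    lig = [r for c in partition.ligand_chains for r in complex.chains[c]]
    if not rec or not lig:
        raise ValueError("both partners must be non-empty")
    return rec, lig


def _heavy(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords, idx = [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            if a.element != "H":
                coords.append(a.coords)
                idx.append(i)
    return np.array(coords), np.array(idx)


def native_contacts(
    native: Structure, partition: Partition, cutoff: float = FNAT_CUTOFF
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Cross-partner residue pairs with any heavy-atom distance < cutoff.

    Pairs are keyed by (chain_id, seq_pos) so they can be compared across
    structures sharing a numbering.
    """
    rec, lig = _partner_residues(native, partition)
    xr, ir = _heavy(rec)
    xl, il = _heavy(lig)
    close = cdist(xr, xl) < cutoff
    pairs = set()
    for i, j in zip(*np.nonzero(close)):
        pairs.add(
            ((rec[ir[i]].chain_id, rec[ir[i]].seq_pos), (lig[il[j]].chain_id, lig[il[j]].seq_pos))
        )
    return pairs


def fnat(model: Structure, native: Structure, partition: Partition) -> float:
    """Fraction of native cross-partner contacts reproduced by the model."""
    ref = native_contacts(native, partition)
    if not ref:
        raise ValueError("native structure has no cross-partner contacts; not a complex")
    mod = native_contacts(model, partition)
    return len(ref & mod) / len(ref)


def _backbone_pairs(
    model: Structure, native: Structure, residues: list[Residue]
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coords (model, native) for the given native residues."""
    xm, xn = [], []
    for r in residues:
        try:
            rm = model.residue(r.chain_id, r.seq_pos, r.icode)
        except KeyError:
            continue
        for name in BACKBONE_ATOMS:
            am, an = rm.atom(name), r.atom(name)
            if am is not None and an is not None:
                xm.append(am.coords)
                xn.append(an.coords)
    return np.array(xm), np.array(xn)


def interface_rmsd(model: Structure, native: Structure, partition: Partition) -> float:
    """Backbone RMSD over native interface residues after interface superposition.

    The interface is defined on the native complex: residues of either
    partner with any heavy atom within 10 A of the other partner.
    """
    rec, lig = _partner_residues(native, partition)
    xr, ir = _heavy(rec)
    xl, il = _heavy(lig)
    close = cdist(xr, xl) < IRMS_INTERFACE_CUTOFF
    iface = [rec[i] for i in sorted(set(ir[close.any(axis=1)].tolist()))]
    iface += [lig[j] for j in sorted(set(il[close.any(axis=0)].tolist()))]
    if not iface:
        raise ValueError("native structure has no interface at 10 A")
    xm, xn = _backbone_pairs(model, native, iface)
    _, rmsd = kabsch_superpose(xm, xn)
    return rmsd


def ligand_rmsd(model: Structure, native: Structure, partition: Partition) -> float:
    """Backbone RMSD over the ligand after superposing receptor backbones."""
    rec, lig = _partner_residues(native, partition)
    xm_rec, xn_rec = _backbone_pairs(model, native, rec)
    transform, _ = kabsch_superpose(xm_rec, xn_rec)
    xm_lig, xn_lig = _backbone_pairs(model, native, lig)
    if len(xm_lig) == 0:
        raise ValueError("no matched ligand backbone atoms")
    moved = transform.apply(xm_lig)
    return float(np.sqrt(np.mean(np.sum((moved - xn_lig) ** 2, axis=1))))


def _scale(x: float, d: float) -> float:
    return 1.0 / (1.0 + (x / d) ** 2)


def dockq_score(fnat_value: float, irms: float, lrms: float) -> float:
    """Combine the three terms: (fnat + s(irms, 1.5) + s(lrms, 8.5)) / 3."""
    return (fnat_value + _scale(irms, D1_IRMS) + _scale(lrms, D2_LRMS)) / 3.0


def capri_class(dockq_value: float) -> CapriClass:
    """CAPRI quality category for a DockQ value.

    Boundaries: < 0.23 incorrect; [0.23, 0.49] acceptable; (0.49, 0.8]
    medium; > 0.8 high. The 0.23 boundary counts as a success
    (acceptable).
    """
    if not 0.0 <= dockq_value <= 1.0:
        raise ValueError(f"DockQ value {dockq_value} outside [0, 1]")
    if dockq_value < 0.23:
        return CapriClass.INCORRECT
    if dockq_value <= 0.49:
        return CapriClass.ACCEPTABLE
    if dockq_value <= 0.8:
        return CapriClass.MEDIUM
    return CapriClass.HIGH


def dockq(model: Structure, native: Structure, partition: Partition) -> DockQResult:
    """Full docking-quality assessment of ``model`` against ``native``.

    Chains must be pre-matched by id between the two structures.
    """
    f = fnat(model, native, partition)
    i = interface_rmsd(model, native, partition)
    l = ligand_rmsd(model, native, partition)
    q = dockq_score(f, i, l)
    return DockQResult(fnat=f, irms=i, lrms=l, dockq=q, capri=capri_class(q))
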