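"""AlphaFold-derived docking confidence metrics and the routing gate.

The central quantity is interface-pLDDT: the mean per-residue pLDDT over
the residues at the predicted interface (any heavy atom within 8 A of the
other partner). Predicted complexes with interface-pLDDT <= 85 are routed
to global rigid-body docking; above 85 the predicted orientation is
trusted and only local flexible refinement is run. Residues with pLDDT
below 80 (in contiguous runs) are treated as mobile during refinement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_curve, roc_auc_score

from .structure_io import Partition, Residue, Structure

__all__ = [
    "GateParams",
    "Route",
    "ConfidenceReport",
    "MobileSegments",
    "SigmoidFit",
    "interface_residues",
    "interface_contacts",
    "average_plddt",
    "interface_plddt",
    "confidence_report",
    "gate_decision",
    "select_mobile_residues",
    "roc_auc",
    "confusion_at_thresholds",
    "fit_sigmoid",
]


@dataclass(frozen=True)
class GateParams:
    interface_cutoff: float = 8.0  # A, heavy-atom interface definition
    contact_cutoff: float = 5.0  # A, Cbeta-Cbeta contact count
    gate_threshold: float = 85.0  # interface-pLDDT at/below -> global dock
    mobile_threshold: float = 80.0  # per-residue pLDDT below -> mobile
    min_segment_len: int = 3
    inclusive_cutoffs: bool = False  # flip "within" from strict < to <=

    def __post_init__(self) -> None:
        if self.interface_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        for thr in (self.gate_threshold, self.mobile_threshold):
            if not 0 < thr < 100:
                raise ValueError("pLDDT thresholds must lie in (0, 100)")


class Route(str, enum.Enum):
    GLOBAL_DOCK = "global_dock"
    LOCAL_DOCK = "local_dock"


@dataclass
class ConfidenceReport:
    interface_residues: dict[str, list[Residue]]  # "receptor"/"ligand" -> residues
    n_interface_residues: int
    n_interface_contacts: int
    avg_plddt: float
    interface_plddt: float | None
    gate: Route

    def to_dict(self) -> dict:
        return {
            "interface_residues": {
                side: [(r.chain_id, r.seq_pos) for r in res]
                for side, res in self.interface_residues.items()
            },
            "n_interface_residues": self.n_interface_residues,
            "n_interface_contacts": self.n_interface_contacts,
            "avg_plddt": self.avg_plddt,
            "interface_plddt": self.interface_plddt,
            "gate": self.gate.value,
        }


@dataclass
class MobileSegments:
    """Contiguous low-confidence residue runs: (chain_id, start, end) inclusive."""

    segments: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Interface geometry
# ---------------------------------------------------------------------------

def _heavy_coords(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Stacked heavy-atom coords and the residue index of each atom."""
    coords, idx = [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            if a.element != "H":
                coords.append(a.coords)
                idx.append(i)
    return np.array(coords), np.array(idx)


def _partner_residues(
    complex: Structure, partition: Partition
) -> tuple[list[Residue], list[Residue]]:
    rec = [r for c in partition.receptor_chains for r in complex.chains[c]]
    lig = [r for c in partition.ligand_chains for r in complex.chains[c]]
    if not rec or not lig:
        raise ValueError("both partners must be non-empty")
    return rec, lig


def interface_residues(
    complex: Structure,
    partition: Partition,
    cutoff: float = 8.0,
    inclusive: bool = False,
) -> dict[str, list[Residue]]:
    """Residues of each partner with any heavy atom within ``cutoff`` of the other.

    "Within" is strict (<) by default; ``inclusive`` flips to <=.
    """
    rec, lig = _partner_residues(complex, partition)
    xr, ir = _heavy_coords(rec)
    xl, il = _heavy_coords(lig)
    d = cdist(xr, xl)
    close = d <= cutoff if inclusive else d < cutoff
    rec_hit = sorted(set(ir[close.any(axis=1)].tolist()))
    lig_hit = sorted(set(il[close.any(axis=0)].tolist()))
    return {
        "receptor": [rec[i] for i in rec_hit],
        "ligand": [lig[i] for i in lig_hit],
    }


def _cb_coords(residues: list[Residue]) -> np.ndarray:
    """Cbeta coordinate per residue; glycine (or missing Cbeta) falls back to Calpha."""
    out = []
    for r in residues:
        a = r.atom("CB") or r.ca
        if a is None:
            raise ValueError(f"residue {r.chain_id}{r.seq_pos} has neither CB nor CA")
        out.append(a.coords)
    return np.array(out)


def interface_contacts(
    complex: Structure,
    partition: Partition,
    cutoff: float = 5.0,
    inclusive: bool = False,
) -> int:
    """Count of cross-partner residue pairs with Cbeta-Cbeta distance within ``cutoff``."""
    rec, lig = _partner_residues(complex, partition)
    d = cdist(_cb_coords(rec), _cb_coords(lig))
    close = d <= cutoff if inclusive else d < cutoff
    return int(close.sum())


# ---------------------------------------------------------------------------
# pLDDT summaries and the gate
# ---------------------------------------------------------------------------

def average_plddt(structure: Structure) -> float:
    """Unweighted mean pLDDT over every residue of the structure."""
    residues = structure.residues()
    if not residues:
        raise ValueError("empty structure")
    return float(np.mean([r.plddt for r in residues]))


def interface_plddt(
    complex: Structure, partition: Partition, params: GateParams = GateParams()
) -> float | None:
    """Mean pLDDT over the union of both partners' interface residues; None if no interface."""
    iface = interface_residues(
        complex, partition, params.interface_cutoff, params.inclusive_cutoffs
    )
    pool = iface["receptor"] + iface["ligand"]
    if not pool:
        return None
    return float(np.mean([r.plddt for r in pool]))


def confidence_report(
    complex: Structure, partition: Partition, params: GateParams = GateParams()
) -> ConfidenceReport:
    iface = interface_residues(
        complex, partition, params.interface_cutoff, params.inclusive_cutoffs
    )
    pool = iface["receptor"] + iface["ligand"]
    ipl = float(np.mean([r.plddt for r in pool])) if pool else None
    gate = Route.GLOBAL_DOCK if (ipl is None or ipl <= params.gate_threshold) else Route.LOCAL_DOCK
    return ConfidenceReport(
        interface_residues=iface,
        n_interface_residues=len(pool),
        n_interface_contacts=interface_contacts(
            complex, partition, params.contact_cutoff, params.inclusive_cutoffs
        ),
        avg_plddt=average_plddt(complex),
        interface_plddt=ipl,
        gate=gate,
    )


def gate_decision(report: ConfidenceReport, params: GateParams = GateParams()) -> Route:
    """Route on interface-pLDDT: <= threshold (or missing) -> global docking."""
    ipl = report.interface_plddt
    if ipl is None or ipl <= params.gate_threshold:
        return Route.GLOBAL_DOCK
    return Route.LOCAL_DOCK


def select_mobile_residues(
    profile: list[tuple[str, int, float]], params: GateParams = GateParams()
) -> MobileSegments:
    """Maximal contiguous runs of residues with pLDDT below the mobile threshold.

    Runs are per chain, in profile order; runs shorter than
    ``min_segment_len`` are discarded. Segment bounds are author sequence
    positions, inclusive.
    """
    segments: list[tuple[str, int, int]] = []
    run: list[tuple[str, int]] = []

    def flush() -> None:
        if len(run) >= params.min_segment_len:
            segments.append((run[0][0], run[0][1], run[-1][1]))
        run.clear()

    prev_chain: str | None = None
    for chain_id, seq_pos, plddt in profile:
        contiguous = (
            run
            and chain_id == prev_chain
            and seq_pos == run[-1][1] + 1
        )
        if not contiguous:
            flush()
        if plddt < params.mobile_threshold:
            run.append((chain_id, seq_pos))
        else:
            flush()
        prev_chain = chain_id
    flush()
    return MobileSegments(segments=segments)


# ---------------------------------------------------------------------------
# Discriminator evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores: list[float], labels: list[int]) -> tuple[np.ndarray, float]:
    """ROC curve points ((fpr, tpr) rows) and trapezoidal AUC.

    Ties are handled rank-wise, so the AUC equals the probabilistic
    (Mann-Whitney) AUC. Raises if only one class is present.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(labels, scores))


def confusion_at_thresholds(
    interface_plddts: list[float],
    irmsds: list[float],
    params: GateParams = GateParams(),
    irmsd_threshold: float = 4.0,
) -> dict:
    """2x2 confusion of the interface-pLDDT classifier against docking quality.

    Predicted positive: interface-pLDDT >= gate threshold (85). Actual
    positive: near-native docking, iRMSD <= 4 A.
    """
    if len(interface_plddts) != len(irmsds):
        raise ValueError("interface-pLDDT and iRMSD lists must have equal length")
    if not interface_plddts:
        raise ValueError("empty inputs")
    pred = np.asarray(interface_plddts) >= params.gate_threshold
    actual = np.asarray(irmsds) <= irmsd_threshold
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    fn = int(np.sum(~pred & actual))
    tn = int(np.sum(~pred & ~actual))
    n = tp + fp + fn + tn
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
    }


@dataclass
class SigmoidFit:
    midpoint: float
    slope: float
    floor: float
    ceiling: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _logistic4(np.asarray(x, dtype=float), self.midpoint, self.slope, self.floor, self.ceiling)


def _logistic4(x, midpoint, slope, floor, ceiling):
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_sigmoid(x: list[float], y: list[float]) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of y (e.g. DockQ) on x (interface-pLDDT).

    Deterministic initialization: midpoint = median(x), slope = 0.1,
    floor = min(y), ceiling = max(y). If the optimizer fails the
    initialization is returned, flagged as unconverged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a 4-parameter fit")
    p0 = [float(np.median(x)), 0.1, float(y.min()), float(y.max())]
    try:
        popt, _ = curve_fit(_logistic4, x, y, p0=p0, maxfev=10000)
        return SigmoidFit(*map(float, popt), converged=True)
    except RuntimeError:
        return SigmoidFit(*p0, converged=False)
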