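"""Residue correspondence, optimal rigid superposition, rigid transforms.

Superposition is C-alpha based throughout: the Kabsch algorithm gives the
least-squares proper rotation + translation; reflections are excluded by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structure_io import Residue, Structure

__all__ = [
    "ResidueCorrespondence",
    "RigidTransform",
    "align_sequences",
    "correspond_structures",
    "kabsch_superpose",
    "apply_transform",
]


@dataclass
class ResidueCorrespondence:
    """Aligned position pairs between two sequences (or structures).

    ``pairs`` holds 0-based index pairs into the two sequences, strictly
    increasing in both (no crossings); gapped columns are excluded and
    terminal overhangs do not appear. ``residue_pairs`` is populated when
    the correspondence was lifted onto two structures.
    """

    pairs: list[tuple[int, int]]
    coverage: float
    residue_pairs: list[tuple[Residue, Residue]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation, self.translation = R, t

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# Sequence alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # terminal gaps are lightly penalized: overhangs are trimmed rather than
    # forced into a mismatched register, but a degenerate all-gap alignment
    # never beats aligning equal-length sequences
    try:
        aligner.open_end_gap_score = -1.0
        aligner.extend_end_gap_score = -0.5
    except AttributeError:  # older Biopython attribute names
        aligner.end_open_gap_score = -1.0
        aligner.end_extend_gap_score = -0.5
    return aligner


def align_sequences(seq_a: str, seq_b: str) -> ResidueCorrespondence:
    """Globally align two amino-acid sequences; return matched columns.

    Scoring: match +1, mismatch -1, gap open -10, extend -0.5; terminal
    overhangs are free and excluded from the correspondence, as are gapped
    columns. Mismatched (but aligned) pairs are kept — unbound/bound
    partners may differ by point mutations — and logged.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _make_aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    mismatches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] != seq_b[j]:
                mismatches += 1
    if mismatches:
        warnings.warn(f"alignment kept {mismatches} mismatched residue pairs")
    coverage = len(pairs) / min(len(seq_a), len(seq_b))
    return ResidueCorrespondence(pairs=pairs, coverage=coverage)


def correspond_structures(a: Structure, b: Structure) -> ResidueCorrespondence:
    """Residue correspondence between two structures, chain by chain.

    Chains are paired by order of appearance; each chain pair is sequence
    aligned and the matched columns are lifted onto residue references.
    """
    ids_a, ids_b = a.chain_ids(), b.chain_ids()
    if len(ids_a) != len(ids_b):
        raise ValueError(
            f"chain count mismatch: {len(ids_a)} vs {len(ids_b)}"
        )
    residue_pairs: list[tuple[Residue, Residue]] = []
    pairs: list[tuple[int, int]] = []
    off_a = off_b = 0
    total_min = 0
    for ca, cb in zip(ids_a, ids_b):
        res_a, res_b = a.chains[ca], b.chains[cb]
        corr = align_sequences(a.sequence(ca), b.sequence(cb))
        for i, j in corr.pairs:
            residue_pairs.append((res_a[i], res_b[j]))
            pairs.append((off_a + i, off_b + j))
        off_a += len(res_a)
        off_b += len(res_b)
        total_min += min(len(res_a), len(res_b))
    return ResidueCorrespondence(
        pairs=pairs,
        coverage=len(pairs) / total_min if total_min else 0.0,
        residue_pairs=residue_pairs,
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns the optimal proper transform (reflections forbidden) and the
    resulting RMSD. Requires at least 3 non-collinear points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = a0.T @ b0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(a) - b) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(
    structure: Structure, t: RigidTransform, chains: list[str] | None = None
) -> Structure:
    """Return a copy with the named chains (default: all) rigidly moved."""
    out = structure.copy()
    target = out.chain_ids() if chains is None else list(chains)
    for cid in target:
        if cid not in out.chains:
            raise KeyError(f"chain {cid!r} not in structure {structure.id!r}")
        for r in out.chains[cid]:
            for a in r.atoms:
                a.coords = t.apply(a.coords[None, :])[0]
    return out
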