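"""Synthetic two-chain complexes with known ground truth.

The generator builds idealized poly-alanine/glycine helices (1.5 A rise,
100 deg twist per residue) and plants:

* a **bound** pose — the receptor (chain A) is a helix folded into two
  arms forming an open V-groove; the ligand (chain B) is a short helix
  whose glycine half carries no C-beta (a thin end) and whose alanine
  half does (a fat end), seated in the groove at the global minimum of
  the coarse contact score. The V breaks the azimuthal symmetry a
  straight helix pair would have, and the thin/fat ligand asymmetry
  breaks the end-for-end flip degeneracy, so the planted pose is a
  distinctive energy-funnel minimum. For the default geometry the pose
  was located once by an exhaustive seeded search with local rigid
  minimization and is shipped as a frozen rigid transform; fixture
  construction re-settles it with a short deterministic minimization.
  Non-default geometries fall back to a coarse placement grid followed
  by minimization, which may find only a local optimum;
* an **unbound** conformer — the ligand's hinge-segment interior is
  rotated about the axis through the segment's anchor C-alphas (a
  backrub-type motion), so bound and unbound differ only inside the
  hinge and the motion is exactly invertible by backbone sampling;
* a **model** — the unbound backbone at the planted pose (optionally
  with a rigid pose offset), carrying synthetic per-residue pLDDT in the
  B-factors: baseline 95, depressed to 60-75 on displaced residues,
  Gaussian jitter (sigma 3), clipped to [0, 100].

Every output is reproducible from the seed. The truth table records the
per-residue C-alpha displacement both raw (no superposition: exactly
zero outside the hinge) and after a global C-alpha superposition (what a
whole-protein per-residue RMSD analysis reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RigidTransform, kabsch_superpose
from .structure_io import Atom, Partition, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "generate_toy_complex",
    "set_uniform_plddt",
    "generate_discriminator_cohort",
]

_RISE = 1.5  # A per residue along the helix axis
_TWIST = 100.0  # deg per residue
_CA_RADIUS = 2.3  # A

# Planted ligand pose for the default geometry (receptor 24 residues,
# fold 150 deg, groove gap 10 A; ligand 9 residues, gly 1-4 / ala 5-9):
# rigid transform from the centered canonical ligand CA trace to the
# global minimum of the coarse contact score, precomputed by exhaustive
# seeded search + rigid minimization over the fixture definition.
_PLANTED_R = np.array(
    [
        [0.069426757329, -0.270760782348, -0.960139846121],
        [0.265419856679, 0.932784730254, -0.243854355479],
        [0.961629983438, -0.237910163188, 0.136625507153],
    ]
)
_PLANTED_T = np.array([3.004531681524, 4.550451216565, 11.453935249634])


@dataclass(frozen=True)
class ToyComplexSpec:
    receptor_len: int = 24  # folded into two arms of len/2 each
    ligand_len: int = 9  # first half glycine (no CB), second half alanine
    arm_fold_deg: float = 150.0  # fold angle between the receptor arms
    groove_gap: float = 10.0  # A between the arm axes at the fold
    hinge_start: int = 3  # ligand seq positions, inclusive anchors
    hinge_end: int = 7
    hinge_angle_deg: float = 40.0  # unbound conformer swing; 0 -> unbound == bound
    model_offset: tuple[float, float] = (0.0, 0.0)  # (translation A, rotation deg)
    plddt_baseline: float = 95.0
    plddt_depressed: tuple[float, float] = (60.0, 75.0)
    plddt_jitter: float = 3.0
    displaced_cutoff: float = 0.5  # A displacement marking a residue "displaced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor_len < 8 or self.ligand_len < 8:
            raise ValueError("toy chains need at least 8 residues")
        if not (1 <= self.hinge_start < self.hinge_end <= self.ligand_len):
            raise ValueError("hinge segment must lie within the ligand")
        if self.hinge_end - self.hinge_start + 1 < 3:
            raise ValueError("hinge segment must span at least 3 residues")

    @property
    def is_default_geometry(self) -> bool:
        return (
            self.receptor_len == 24
            and self.ligand_len == 9
            and self.arm_fold_deg == 150.0
            and self.groove_gap == 10.0
        )


@dataclass
class ToyComplex:
    bound: Structure
    unbound: Structure
    model: Structure
    truth: pd.DataFrame
    planted_transform: RigidTransform
    partition: Partition = field(default_factory=lambda: Partition(("A",), ("B",)))
    hinge_segment: tuple[str, int, int] = ("B", 0, 0)


# ---------------------------------------------------------------------------
# Ideal helix construction
# ---------------------------------------------------------------------------

def _helix_ca_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.radians(_TWIST) * i
    return np.column_stack(
        [_CA_RADIUS * np.cos(theta), _CA_RADIUS * np.sin(theta), _RISE * i]
    )


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _atoms_from_ca_trace(ca: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Backbone + CB positions from a CA trace via local helical frames."""
    n = len(ca)
    out = []
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        e = ca[hi] - ca[lo]
        e = e / np.linalg.norm(e)
        if 0 < i < n - 1:
            u = ca[i] - 0.5 * (ca[i - 1] + ca[i + 1])
        else:
            j = 1 if i == 0 else n - 2
            u = ca[j] - 0.5 * (ca[j - 1] + ca[j + 1])
        u = u - np.dot(u, e) * e
        u = u / np.linalg.norm(u)
        b = np.cross(e, u)
        out.append(
            {
                "N": ca[i] - 1.2 * e + 0.6 * u,
                "CA": ca[i],
                "C": ca[i] + 1.2 * e + 0.4 * u,
                "O": ca[i] + 1.6 * e + 1.0 * u + 0.5 * b,
                "CB": ca[i] + 1.5 * u - 0.5 * b,
            }
        )
    return out


def _build_chain(chain_id: str, ca: np.ndarray, aas: str, plddt: float = 0.0) -> list[Residue]:
    residues = []
    for pos, (atom_map, aa) in enumerate(zip(_atoms_from_ca_trace(ca), aas), start=1):
        atoms = [
            Atom(name=name, element=name[0], coords=xyz.copy(), bfactor=plddt)
            for name, xyz in atom_map.items()
            if not (aa == "G" and name == "CB")  # glycine has no C-beta
        ]
        residues.append(Residue(chain_id=chain_id, seq_pos=pos, aa=aa, atoms=atoms))
    return residues


def _receptor_trace(spec: ToyComplexSpec) -> np.ndarray:
    """Straight helix folded into two arms about an offset axis: a V-groove."""
    ca = _helix_ca_trace(spec.receptor_len)
    mid = spec.receptor_len // 2
    z_max = ca[-1, 2]
    q = np.array([0.0, spec.groove_gap / 2.0, z_max / 2.0])
    R = _rotation(np.array([1.0, 0.0, 0.0]), math.radians(spec.arm_fold_deg))
    ca[mid:] = (ca[mid:] - q) @ R.T + q
    return ca


def _ligand_aas(n: int) -> str:
    return "G" * (n // 2) + "A" * (n - n // 2)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Build the (bound, unbound, model) fixture triple with truth tables."""
    from .redock import CoarseContactScore, _Packed, _minimize_rigid

    rng = np.random.default_rng(spec.seed)
    score = CoarseContactScore()
    part = Partition(("A",), ("B",))

    rec_ca = _receptor_trace(spec)
    lig_ca0 = _helix_ca_trace(spec.ligand_len)
    lig_ca0 = lig_ca0 - lig_ca0.mean(axis=0)
    lig_aas = _ligand_aas(spec.ligand_len)

    def assemble(lig_ca: np.ndarray, id: str = "toy") -> Structure:
        return Structure(
            id,
            {
                "A": _build_chain("A", rec_ca, "A" * spec.receptor_len),
                "B": _build_chain("B", lig_ca, lig_aas),
            },
        )

    if spec.is_default_geometry:
        start = assemble(lig_ca0 @ _PLANTED_R.T + _PLANTED_T)
        settle_iters = 50
    else:
        best = None
        for dy in (-2.0, -1.0, 0.0, 1.0, 2.0):
            for dz in (-4.0, -2.0, 0.0, 2.0, 4.0):
                for roll in range(0, 360, 60):
                    R = _rotation(np.array([0.0, 0.0, 1.0]), math.radians(roll))
                    lig = lig_ca0 @ R.T + rec_ca.mean(axis=0) + np.array([0.0, dy, dz])
                    e = score(assemble(lig), part)
                    if best is None or e < best[0]:
                        best = (e, lig)
        start = assemble(best[1])
        settle_iters = 300
    packed = _Packed(start, part)
    coords, _ = _minimize_rigid(packed, packed.coords0, score, max_iters=settle_iters)
    bound = packed.structure_with(coords)
    bound.id = "toy_bound"
    lig_ca_bound = np.array([r.ca.coords for r in bound.chains["B"]])
    planted, _ = kabsch_superpose(lig_ca0, lig_ca_bound)

    # unbound conformer: backrub-style hinge swing of the ligand segment interior
    unbound = bound.copy()
    unbound.id = "toy_unbound"
    seg = ("B", spec.hinge_start, spec.hinge_end)
    if spec.hinge_angle_deg != 0.0:
        res_b = unbound.chains["B"]
        p0 = res_b[spec.hinge_start - 1].ca.coords
        p1 = res_b[spec.hinge_end - 1].ca.coords
        R_h = _rotation(p1 - p0, math.radians(spec.hinge_angle_deg))
        for r in res_b[spec.hinge_start : spec.hinge_end - 1]:
            for a in r.atoms:
                a.coords = R_h @ (a.coords - p0) + p0

    # truth tables: raw and superposition-fitted per-residue CA displacement;
    # residue-level displacement for the pLDDT rule uses the max over atoms,
    # since a hinge-interior CA can sit near the rotation axis.
    keys, raw, atom_disp = [], [], []
    for rb, ru in zip(bound.residues(), unbound.residues()):
        keys.append((rb.chain_id, rb.seq_pos))
        raw.append(float(np.linalg.norm(rb.ca.coords - ru.ca.coords)))
        atom_disp.append(
            max(
                float(np.linalg.norm(ab.coords - au.coords))
                for ab, au in zip(rb.atoms, ru.atoms)
            )
        )
    ca_b = np.array([r.ca.coords for r in bound.residues()])
    ca_u = np.array([r.ca.coords for r in unbound.residues()])
    fit, _ = kabsch_superpose(ca_u, ca_b)
    fitted = np.linalg.norm(fit.apply(ca_u) - ca_b, axis=1)

    # model: unbound backbone at the planted pose, optional rigid pose error
    model = unbound.copy()
    model.id = "toy_model"
    t_off, r_off = spec.model_offset
    if t_off or r_off:
        lig_atoms = [a for r in model.chains["B"] for a in r.atoms]
        xyz = np.array([a.coords for a in lig_atoms])
        centroid = xyz.mean(axis=0)
        R_off = _rotation(_unit(rng), math.radians(r_off)) if r_off else np.eye(3)
        shift = t_off * _unit(rng) if t_off else np.zeros(3)
        xyz = (xyz - centroid) @ R_off.T + centroid + shift
        for a, x in zip(lig_atoms, xyz):
            a.coords = x

    # depression extends one residue beyond the displaced run: predictors
    # lose confidence across a flexible region including its pivots, and
    # this keeps the low-confidence run aligned with the hinge anchors.
    displaced = [d > spec.displaced_cutoff for d in atom_disp]
    dilated = list(displaced)
    for i, (cid, _) in enumerate(keys):
        for j in (i - 1, i + 1):
            if 0 <= j < len(keys) and keys[j][0] == cid and displaced[j]:
                dilated[i] = True
    lo_d, hi_d = spec.plddt_depressed
    plddts = []
    for low in dilated:
        base = rng.uniform(lo_d, hi_d) if low else spec.plddt_baseline
        plddts.append(float(np.clip(base + rng.normal(0, spec.plddt_jitter), 0, 100)))
    for r, p in zip(model.residues(), plddts):
        for a in r.atoms:
            a.bfactor = p

    truth = pd.DataFrame(
        {
            "chain": [k[0] for k in keys],
            "seq_pos": [k[1] for k in keys],
            "displacement_raw": raw,
            "displacement_fitted": fitted,
            "max_atom_displacement": atom_disp,
            "is_hinge_interior": [
                k[0] == "B" and spec.hinge_start < k[1] < spec.hinge_end for k in keys
            ],
            "plddt": plddts,
        }
    )
    return ToyComplex(
        bound=bound,
        unbound=unbound,
        model=model,
        truth=truth,
        planted_transform=planted,
        hinge_segment=seg,
    )


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def segment_ca_rmsd(
    model: Structure,
    reference: Structure,
    segment: tuple[str, int, int],
) -> float:
    """Conformational CA RMSD of a segment after superposing its chain.

    The model's chain is superposed onto the reference chain over all its
    C-alphas, then the RMSD is taken over the segment residues only. This
    isolates backbone conformation from rigid-body pose.
    """
    chain_id, start, end = segment
    xm = np.array([r.ca.coords for r in model.chains[chain_id]])
    xr = np.array([r.ca.coords for r in reference.chains[chain_id]])
    fit, _ = kabsch_superpose(xm, xr)
    moved = fit.apply(xm)
    idx = [
        i
        for i, r in enumerate(model.chains[chain_id])
        if start <= r.seq_pos <= end
    ]
    return float(np.sqrt(np.mean(np.sum((moved[idx] - xr[idx]) ** 2, axis=1))))


def set_uniform_plddt(structure: Structure, value: float) -> Structure:
    """Copy of ``structure`` with every B-factor set to ``value``."""
    out = structure.copy()
    for a in out.atoms():
        a.bfactor = value
    return out


def generate_discriminator_cohort(
    n: int,
    seed: int = 0,
    good_iface_plddt: tuple[float, float] = (88.0, 97.0),
    bad_iface_plddt: tuple[float, float] = (60.0, 84.0),
    jitter: float = 1.5,
) -> list[dict]:
    """A cohort of (model, native) pairs for discriminator evaluation.

    Half the models sit at the planted (near-native) pose with high
    interface pLDDT; half are re-oriented at a random contact point with
    depressed interface pLDDT. Non-interface residues stay near the 95
    baseline, so interface-localized confidence separates the classes
    while average pLDDT separates them only weakly.
    """
    from .confidence import interface_residues
    from .redock import randomize_orientation

    rng = np.random.default_rng(seed)
    base = generate_toy_complex(ToyComplexSpec(hinge_angle_deg=0.0, seed=seed))
    part = base.partition
    cohort = []
    for i in range(n):
        good = i % 2 == 0
        if good:
            model = base.bound.copy()
        else:
            model = randomize_orientation(
                base.bound, part, np.random.default_rng(int(rng.integers(2**31)))
            )
        model.id = f"cohort_{i:03d}"
        lo, hi = good_iface_plddt if good else bad_iface_plddt
        target = rng.uniform(lo, hi)
        iface = interface_residues(model, part, 8.0)
        iface_keys = {(r.chain_id, r.seq_pos) for side in iface.values() for r in side}
        for r in model.residues():
            base_p = target if (r.chain_id, r.seq_pos) in iface_keys else 95.0
            p = float(np.clip(base_p + rng.normal(0, jitter), 0, 100))
            for a in r.atoms:
                a.bfactor = p
        cohort.append({"model": model, "native": base.bound, "partition": part})
    return cohort
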