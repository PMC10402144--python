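"""Temperature replica-exchange Monte Carlo docking engine.

Global docking performs an exhaustive rigid-body search: the ligand is
re-oriented at random around the receptor, then sampled with 4 A / 8 deg
rigid-body perturbations across a ladder of three temperature replicas
(inverse temperatures 1/1.5, 1/3, 1/5 kcal^-1 mol) over 8 independent
trajectories, with periodic temperature-swap attempts between adjacent
replicas. Local docking uses smaller rigid moves (1 A / 3 deg) mixed 1:3
with backrub-style backbone perturbations directed at low-confidence
(mobile) residue segments.

The energy model is pluggable. The built-in coarse score rewards
cross-partner C-beta contacts in a 4-6 A well (cosine-switched to zero
over 3.5-4 A and 6-8 A) and quadratically penalizes pairs closer than
3.5 A. It is strictly finite-range and cross-partner, so the interface
score (complex minus separated partners) equals the score itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import kabsch_superpose
from .structure_io import Partition, Structure

__all__ = [
    "MoveParams",
    "ReplicaLadder",
    "Decoy",
    "DecoySet",
    "ClusterSet",
    "CoarseContactScore",
    "default_score",
    "interface_score",
    "randomize_orientation",
    "rigid_move",
    "backbone_perturb",
    "metropolis_accept",
    "exchange_attempt",
    "run_global_dock",
    "run_local_dock",
    "cluster_decoys",
    "rank_decoys",
    "ligand_rmsd_ca",
]


@dataclass(frozen=True)
class MoveParams:
    trans_mag: float = 4.0  # A, max rigid translation per move
    rot_mag: float = 8.0  # deg, max rigid rotation per move
    backbone_weight: float = 0.0  # probability of a backbone move per trial
    backbone_angle_sigma: float = 2.5  # deg, backrub angle spread
    backbone_angle_cap: float = 10.0  # deg, hard cap on backrub angle

    def __post_init__(self) -> None:
        if self.trans_mag < 0 or self.rot_mag < 0:
            raise ValueError("move magnitudes must be non-negative")
        if not 0.0 <= self.backbone_weight <= 1.0:
            raise ValueError("backbone_weight must lie in [0, 1]")

    @classmethod
    def global_defaults(cls) -> "MoveParams":
        """4 A translations, 8 deg rotations, no backbone moves."""
        return cls(trans_mag=4.0, rot_mag=8.0, backbone_weight=0.0)

    @classmethod
    def local_defaults(cls) -> "MoveParams":
        """1 A translations, 3 deg rotations, 3:1 backbone:rigid weighting."""
        return cls(trans_mag=1.0, rot_mag=3.0, backbone_weight=0.75)


@dataclass(frozen=True)
class ReplicaLadder:
    inverse_temperatures: tuple[float, ...] = (1 / 1.5, 1 / 3.0, 1 / 5.0)
    n_trajectories: int = 8

    def __post_init__(self) -> None:
        betas = self.inverse_temperatures
        if len(betas) < 2:
            raise ValueError("replica exchange needs at least 2 replicas")
        if any(b2 >= b1 for b1, b2 in zip(betas, betas[1:])):
            raise ValueError("inverse temperatures must be strictly decreasing")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


@dataclass
class Decoy:
    """A scored docking candidate with full provenance."""

    coords: np.ndarray  # full complex coordinates, template atom order
    interface_score: float
    trajectory: int
    replica: int
    step: int
    seed: int
    _template: Structure | None = field(default=None, repr=False)

    @property
    def structure(self) -> Structure:
        if self._template is None:
            raise ValueError("decoy has no template structure attached")
        s = self._template.copy()
        s.set_coords(self.coords)
        return s

    @property
    def provenance(self) -> tuple[int, int, int, int]:
        return (self.trajectory, self.replica, self.step, self.seed)


@dataclass
class DecoySet:
    decoys: list[Decoy]
    template: Structure
    partition: Partition

    def __len__(self) -> int:
        return len(self.decoys)

    def __iter__(self):
        return iter(self.decoys)


@dataclass
class ClusterSet:
    centers: list[Decoy]
    members: dict[int, int]  # decoy index (in the ranked list) -> cluster index
    rmsd_cutoff: float


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class CoarseContactScore:
    """Finite-range cross-partner C-beta contact score.

    E = w_rep * sum max(0, d_clash - d)^2  -  w_att * sum S(d)

    with S(d) = 1 on [4, 6] A, cosine-switched to 0 over [3.5, 4] and
    [6, 8] A, 0 elsewhere. Deterministic and rigid-motion invariant.
    """

    cross_partner_only = True

    def __init__(self, d_clash: float = 3.5, w_rep: float = 10.0, w_att: float = 1.0):
        self.d_clash = d_clash
        self.w_rep = w_rep
        self.w_att = w_att

    def switch(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        s = np.zeros_like(d)
        up = (d > 3.5) & (d < 4.0)
        s[up] = 0.5 * (1.0 - np.cos(np.pi * (d[up] - 3.5) / 0.5))
        s[(d >= 4.0) & (d <= 6.0)] = 1.0
        down = (d > 6.0) & (d < 8.0)
        s[down] = 0.5 * (1.0 + np.cos(np.pi * (d[down] - 6.0) / 2.0))
        return s

    def energy(self, dmat: np.ndarray) -> float:
        """Energy from the cross-partner C-beta distance matrix."""
        rep = np.clip(self.d_clash - dmat, 0.0, None)
        return float(self.w_rep * np.sum(rep**2) - self.w_att * np.sum(self.switch(dmat)))

    def __call__(self, complex: Structure, partition: Partition) -> float:
        rec_cb, lig_cb = _partner_cb_coords(complex, partition)
        return self.energy(cdist(rec_cb, lig_cb))


def _partner_cb_coords(complex: Structure, partition: Partition) -> tuple[np.ndarray, np.ndarray]:
    def cb(chains):
        out = []
        for cid in chains:
            for r in complex.chains[cid]:
                a = r.atom("CB") or r.ca
                if a is None:
                    raise ValueError(f"residue {r.chain_id}{r.seq_pos} lacks CB and CA")
                out.append(a.coords)
        return np.array(out)

    return cb(partition.receptor_chains), cb(partition.ligand_chains)


def default_score(
    complex: Structure, partition: Partition, score_fn: CoarseContactScore | None = None
) -> float:
    """Evaluate the built-in coarse contact score on a complex."""
    return (score_fn or CoarseContactScore())(complex, partition)


def interface_score(complex: Structure, partition: Partition, score_fn=None) -> float:
    """score(complex) - score(partners at effectively infinite separation).

    Works for any callable (Structure, Partition) -> score; for the
    finite-range built-in score the separated term is exactly zero.
    """
    fn = score_fn or CoarseContactScore()
    bound = fn(complex, partition)
    if getattr(fn, "cross_partner_only", False):
        return bound
    apart = complex.copy()
    for cid in partition.ligand_chains:
        for r in apart.chains[cid]:
            for a in r.atoms:
                a.coords = a.coords + np.array([500.0, 0.0, 0.0])
    return bound - fn(apart, partition)


# ---------------------------------------------------------------------------
# Packed representation (engine internal)
# ---------------------------------------------------------------------------

class _Packed:
    """Flat numpy view of a complex for the MC hot loop."""

    def __init__(self, complex: Structure, partition: Partition | None):
        self.template = complex.copy()
        self.partition = partition
        atoms = self.template.atoms()
        self.coords0 = np.array([a.coords for a in atoms], dtype=float)

        lig_chains = set(partition.ligand_chains) if partition is not None else set()
        self.lig_atom_idx: list[int] = []
        self.rec_atom_idx: list[int] = []
        rec_cb, lig_cb, rec_ca, lig_ca = [], [], [], []
        self.res_atom_ranges: dict[tuple[str, int], tuple[int, int]] = {}
        self.res_ca_idx: dict[tuple[str, int], int] = {}
        i = 0
        for cid, residues in self.template.chains.items():
            is_lig = cid in lig_chains
            for r in residues:
                start = i
                ca_i = cb_i = None
                for a in r.atoms:
                    (self.lig_atom_idx if is_lig else self.rec_atom_idx).append(i)
                    if a.name == "CA":
                        ca_i = i
                    elif a.name == "CB":
                        cb_i = i
                    i += 1
                self.res_atom_ranges[(cid, r.seq_pos)] = (start, i)
                if ca_i is not None:
                    self.res_ca_idx[(cid, r.seq_pos)] = ca_i
                    (lig_ca if is_lig else rec_ca).append(ca_i)
                score_i = cb_i if cb_i is not None else ca_i
                if score_i is not None:
                    (lig_cb if is_lig else rec_cb).append(score_i)
        self.lig_atom_idx = np.array(self.lig_atom_idx)
        self.rec_atom_idx = np.array(self.rec_atom_idx)
        self.rec_cb = np.array(rec_cb)
        self.lig_cb = np.array(lig_cb)
        self.rec_ca = np.array(rec_ca)
        self.lig_ca = np.array(lig_ca)

    def energy(self, coords: np.ndarray, score: CoarseContactScore) -> float:
        return score.energy(cdist(coords[self.rec_cb], coords[self.lig_cb]))

    def structure_with(self, coords: np.ndarray) -> Structure:
        s = self.template.copy()
        s.set_coords(coords)
        return s


# ---------------------------------------------------------------------------
# Move kernels
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rigid_move_kernel(
    coords: np.ndarray, idx: np.ndarray, params: MoveParams, rng: np.random.Generator
) -> np.ndarray:
    """New full-coordinate array with the indexed atoms rigidly perturbed."""
    out = coords.copy()
    sub = coords[idx]
    centroid = sub.mean(axis=0)
    axis = _random_unit(rng)
    angle = math.radians(params.rot_mag) * rng.random()
    R = _axis_angle(axis, angle)
    direction = _random_unit(rng)
    mag = params.trans_mag * rng.random()  # magnitude uniform in [0, trans_mag]
    out[idx] = (sub - centroid) @ R.T + centroid + mag * direction
    return out


def _backbone_kernel(
    coords: np.ndarray,
    interior_idx: np.ndarray,
    ca_first: int,
    ca_last: int,
    angle_rad: float,
) -> np.ndarray:
    """Rotate interior atoms about the axis through the two anchor C-alphas."""
    out = coords.copy()
    p0, p1 = coords[ca_first], coords[ca_last]
    R = _axis_angle(p1 - p0, angle_rad)
    out[interior_idx] = (coords[interior_idx] - p0) @ R.T + p0
    return out


# ---------------------------------------------------------------------------
# Public move/criterion operations
# ---------------------------------------------------------------------------

def randomize_orientation(
    complex: Structure,
    partition: Partition,
    rng: np.random.Generator | int,
) -> Structure:
    """Place the ligand at a random orientation and direction, surfaces touching.

    The ligand receives a uniform random rotation about its centroid and
    is moved along a uniform random direction from the receptor centroid
    until the minimum cross-partner atom distance falls in [3, 5] A
    (binary search). The receptor is untouched. Fully seeded.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    packed = _Packed(complex, partition)
    coords = _randomize_kernel(packed, packed.coords0, rng)
    return packed.structure_with(coords)


def _randomize_kernel(
    packed: _Packed, coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = coords.copy()
    lig = coords[packed.lig_atom_idx]
    centroid = lig.mean(axis=0)
    lig = (lig - centroid) @ _random_rotation(rng).T
    rec = coords[packed.rec_atom_idx]
    rec_centroid = rec.mean(axis=0)
    direction = _random_unit(rng)

    def min_dist(s: float) -> float:
        return float(cdist(rec, lig + rec_centroid + s * direction).min())

    lo, hi = 0.0, 400.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        d = min_dist(mid)
        if 3.0 < d < 5.0:
            lo = hi = mid
            break
        if d <= 3.0:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    out[packed.lig_atom_idx] = lig + rec_centroid + s * direction
    return out


def rigid_move(
    structure: Structure,
    partition: Partition,
    params: MoveParams,
    rng: np.random.Generator | int,
) -> Structure:
    """Random rigid-body perturbation of the ligand; receptor untouched.

    Translation: uniform in the ball of radius ``trans_mag``. Rotation:
    uniform axis, angle uniform in [0, rot_mag], about the ligand centroid.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    packed = _Packed(structure, partition)
    coords = _rigid_move_kernel(packed.coords0, packed.lig_atom_idx, params, rng)
    return packed.structure_with(coords)


def backbone_perturb(
    structure: Structure,
    segment: tuple[str, int, int],
    params: MoveParams,
    rng: np.random.Generator | int,
) -> Structure:
    """Backrub-style move: rotate a segment's interior about its anchor axis.

    All atoms of the residues strictly between the segment's first and
    last residue rotate rigidly about the axis through the two anchor
    C-alphas by an angle ~ Normal(0, backbone_angle_sigma), capped at
    +-backbone_angle_cap degrees. Anchors and everything outside the
    segment are untouched; the anchor CA-CA distance is exactly preserved.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    chain_id, start, end = segment
    if end - start + 1 < 3:
        raise ValueError("backbone segment must span at least 3 residues")
    packed = _Packed(structure, None)
    interior, ca_first, ca_last = _segment_indices(packed, segment)
    angle = _draw_backbone_angle(params, rng)
    coords = _backbone_kernel(packed.coords0, interior, ca_first, ca_last, angle)
    return packed.structure_with(coords)


def _segment_indices(
    packed: _Packed, segment: tuple[str, int, int]
) -> tuple[np.ndarray, int, int]:
    chain_id, start, end = segment
    try:
        ca_first = packed.res_ca_idx[(chain_id, start)]
        ca_last = packed.res_ca_idx[(chain_id, end)]
    except KeyError as e:
        raise ValueError(f"segment anchor residue missing CA: {e}") from None
    interior = []
    for pos in range(start + 1, end):
        rng_ = packed.res_atom_ranges.get((chain_id, pos))
        if rng_ is None:
            raise ValueError(f"segment residue {chain_id}{pos} absent from structure")
        interior.extend(range(rng_[0], rng_[1]))
    return np.array(interior, dtype=int), ca_first, ca_last


def _draw_backbone_angle(params: MoveParams, rng: np.random.Generator) -> float:
    angle = rng.normal(0.0, math.radians(params.backbone_angle_sigma))
    cap = math.radians(params.backbone_angle_cap)
    return float(np.clip(angle, -cap, cap))


def metropolis_accept(delta_score: float, beta: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion: accept downhill, else with exp(-beta*delta)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if delta_score <= 0:
        return True
    return bool(rng.random() < math.exp(-beta * delta_score))


def exchange_attempt(state_i: tuple, state_j: tuple, rng: np.random.Generator):
    """Attempt a temperature swap between two replica states.

    Each state is ``(configuration, score, beta)``. Temperatures swap with
    probability min(1, exp((beta_i - beta_j) * (E_i - E_j))); the
    configurations themselves never change.
    """
    (conf_i, e_i, b_i), (conf_j, e_j, b_j) = state_i, state_j
    swapped = _exchange_accept(b_i, b_j, e_i, e_j, rng)
    if swapped:
        return (conf_i, e_i, b_j), (conf_j, e_j, b_i), True
    return state_i, state_j, False


def _exchange_accept(b_i, b_j, e_i, e_j, rng) -> bool:
    log_p = (b_i - b_j) * (e_i - e_j)
    if log_p >= 0:
        return True
    return bool(rng.random() < math.exp(log_p))


# ---------------------------------------------------------------------------
# Replica-exchange driver
# ---------------------------------------------------------------------------

def _rex_trajectory(
    packed: _Packed,
    start_coords: np.ndarray,
    betas: tuple[float, ...],
    params: MoveParams,
    n_steps: int,
    rng: np.random.Generator,
    score: CoarseContactScore,
    trajectory_id: int,
    seed: int,
    segments: list[tuple[str, int, int]],
    snapshot_interval: int,
    exchange_interval: int,
    snapshot_all_replicas: bool,
) -> list[Decoy]:
    """One trajectory of replica-exchange MC; returns its snapshots."""
    n_rep = len(betas)
    configs = [start_coords.copy() for _ in range(n_rep)]
    energies = [packed.energy(start_coords, score) for _ in range(n_rep)]
    config_of_temp = list(range(n_rep))  # temperature rank -> config index
    accepted = [0] * n_rep
    decoys: list[Decoy] = []
    seg_data = [_segment_indices(packed, s) for s in segments]
    exchange_parity = 0

    for step in range(1, n_steps + 1):
        for rank in range(n_rep):
            c = config_of_temp[rank]
            use_backbone = (
                seg_data
                and params.backbone_weight > 0
                and rng.random() < params.backbone_weight
            )
            if use_backbone:
                k = int(rng.integers(len(seg_data)))
                interior, ca_f, ca_l = seg_data[k]
                angle = _draw_backbone_angle(params, rng)
                new = _backbone_kernel(configs[c], interior, ca_f, ca_l, angle)
            else:
                new = _rigid_move_kernel(configs[c], packed.lig_atom_idx, params, rng)
            e_new = packed.energy(new, score)
            if metropolis_accept(e_new - energies[c], betas[rank], rng):
                configs[c] = new
                energies[c] = e_new
                accepted[rank] += 1
                if accepted[rank] % snapshot_interval == 0 and (
                    snapshot_all_replicas or rank == 0
                ):
                    decoys.append(
                        Decoy(
                            coords=configs[c].copy(),
                            interface_score=energies[c],
                            trajectory=trajectory_id,
                            replica=rank,
                            step=step,
                            seed=seed,
                            _template=packed.template,
                        )
                    )
        if step % exchange_interval == 0:
            pairs = range(exchange_parity, n_rep - 1, 2)
            for lo in pairs:
                ci, cj = config_of_temp[lo], config_of_temp[lo + 1]
                if _exchange_accept(
                    betas[lo], betas[lo + 1], energies[ci], energies[cj], rng
                ):
                    config_of_temp[lo], config_of_temp[lo + 1] = cj, ci
            exchange_parity = 1 - exchange_parity
    return decoys


def run_global_dock(
    complex: Structure,
    partition: Partition,
    ladder: ReplicaLadder = ReplicaLadder(),
    params: MoveParams | None = None,
    n_steps: int = 2000,
    seed: int = 0,
    score_fn: CoarseContactScore | None = None,
    snapshot_interval: int = 50,
    exchange_interval: int = 10,
    snapshot_all_replicas: bool = True,
) -> DecoySet:
    """Global rigid-body replica-exchange docking from randomized orientations.

    Each of ``ladder.n_trajectories`` trajectories randomizes the ligand
    orientation, then runs ``n_steps`` rigid-move trials per replica with
    Metropolis acceptance and periodic temperature exchanges. Snapshots
    (every ``snapshot_interval`` accepted moves, all replicas by default)
    are returned as scored decoys. Bit-reproducible for a fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    params = params or MoveParams.global_defaults()
    score = score_fn or CoarseContactScore()
    packed = _Packed(complex, partition)
    decoys: list[Decoy] = []
    for t in range(ladder.n_trajectories):
        traj_seed = (seed + t) % 2**31
        rng = np.random.default_rng(traj_seed)
        start = _randomize_kernel(packed, packed.coords0, rng)
        decoys.extend(
            _rex_trajectory(
                packed,
                start,
                ladder.inverse_temperatures,
                params,
                n_steps,
                rng,
                score,
                trajectory_id=t,
                seed=traj_seed,
                segments=[],
                snapshot_interval=snapshot_interval,
                exchange_interval=exchange_interval,
                snapshot_all_replicas=snapshot_all_replicas,
            )
        )
    return DecoySet(decoys=decoys, template=packed.template, partition=partition)


def run_local_dock(
    start: Structure,
    partition: Partition,
    mobile=None,  # MobileSegments, a list of (chain, start, end), or None
    ladder: ReplicaLadder = ReplicaLadder(),
    params: MoveParams | None = None,
    n_steps: int = 1000,
    seed: int = 0,
    score_fn: CoarseContactScore | None = None,
    snapshot_interval: int = 50,
    exchange_interval: int = 10,
    snapshot_all_replicas: bool = True,
    minimize_iters: int = 50,
) -> DecoySet:
    """Flexible local docking from a putative binding orientation.

    Trials are backrub backbone moves on a uniformly chosen mobile segment
    with probability ``params.backbone_weight`` (3:1 backbone:rigid by
    default), otherwise small rigid moves. The start configuration is
    always retained as a candidate decoy; final snapshots are locally
    minimized over the 6 rigid-body degrees of freedom.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    params = params or MoveParams.local_defaults()
    score = score_fn or CoarseContactScore()
    packed = _Packed(start, partition)
    segments = list(getattr(mobile, "segments", mobile or []))
    start_energy = packed.energy(packed.coords0, score)
    decoys: list[Decoy] = [
        Decoy(
            coords=packed.coords0.copy(),
            interface_score=start_energy,
            trajectory=-1,
            replica=0,
            step=0,
            seed=seed,
            _template=packed.template,
        )
    ]
    for t in range(ladder.n_trajectories):
        traj_seed = (seed + t) % 2**31
        rng = np.random.default_rng(traj_seed)
        snaps = _rex_trajectory(
            packed,
            packed.coords0,
            ladder.inverse_temperatures,
            params,
            n_steps,
            rng,
            score,
            trajectory_id=t,
            seed=traj_seed,
            segments=segments,
            snapshot_interval=snapshot_interval,
            exchange_interval=exchange_interval,
            snapshot_all_replicas=snapshot_all_replicas,
        )
        for d in snaps:
            d.coords, d.interface_score = _minimize_rigid(
                packed, d.coords, score, max_iters=minimize_iters
            )
        decoys.extend(snaps)
    return DecoySet(decoys=decoys, template=packed.template, partition=partition)


def _minimize_rigid(
    packed: _Packed,
    coords: np.ndarray,
    score: CoarseContactScore,
    max_iters: int = 50,
) -> tuple[np.ndarray, float]:
    """Coordinate descent over the ligand's 6 rigid DOFs with step halving."""
    coords = coords.copy()
    lig = coords[packed.lig_atom_idx]
    centroid = lig.mean(axis=0)
    best_e = packed.energy(coords, score)
    t_step, r_step = 0.5, math.radians(2.0)
    axes = np.eye(3)
    for _ in range(max_iters):
        improved = False
        for k in range(3):  # translations
            for sgn in (1.0, -1.0):
                trial = coords.copy()
                trial[packed.lig_atom_idx] = lig + sgn * t_step * axes[k]
                e = packed.energy(trial, score)
                if e < best_e - 1e-12:
                    coords, best_e = trial, e
                    lig = coords[packed.lig_atom_idx]
                    centroid = lig.mean(axis=0)
                    improved = True
        for k in range(3):  # rotations about the ligand centroid
            for sgn in (1.0, -1.0):
                R = _axis_angle(axes[k], sgn * r_step)
                trial = coords.copy()
                trial[packed.lig_atom_idx] = (lig - centroid) @ R.T + centroid
                e = packed.energy(trial, score)
                if e < best_e - 1e-12:
                    coords, best_e = trial, e
                    lig = coords[packed.lig_atom_idx]
                    improved = True
        if not improved:
            t_step *= 0.5
            r_step *= 0.5
            if t_step < 1e-3:
                break
    return coords, best_e


# ---------------------------------------------------------------------------
# Clustering and ranking
# ---------------------------------------------------------------------------

def ligand_rmsd_ca(a: Structure, b: Structure, partition: Partition) -> float:
    """CA ligand RMSD between two poses after receptor CA superposition."""
    pa = _Packed(a, partition)
    pb = _Packed(b, partition)
    if len(pa.lig_ca) != len(pb.lig_ca) or len(pa.rec_ca) != len(pb.rec_ca):
        raise ValueError("structures must share residue composition")
    transform, _ = kabsch_superpose(pa.coords0[pa.rec_ca], pb.coords0[pb.rec_ca])
    moved = transform.apply(pa.coords0[pa.lig_ca])
    return float(np.sqrt(np.mean(np.sum((moved - pb.coords0[pb.lig_ca]) ** 2, axis=1))))


def rank_decoys(decoys: DecoySet) -> list[Decoy]:
    """Ascending by interface score; ties broken by (trajectory, step)."""
    if not decoys.decoys:
        raise ValueError("no decoys to rank")
    return sorted(
        decoys.decoys, key=lambda d: (d.interface_score, d.trajectory, d.step)
    )


def cluster_decoys(
    decoys: DecoySet, rmsd_cutoff: float = 5.0, k: int = 5
) -> ClusterSet:
    """Greedy score-ordered clustering by ligand RMSD.

    Decoys are visited best-score first; each joins the first existing
    center within ``rmsd_cutoff`` ligand-CA RMSD (after receptor
    superposition) or seeds a new cluster. The first ``k`` centers are
    returned; each center is by construction the lowest-score member of
    its cluster.
    """
    ranked = rank_decoys(decoys)
    tmp = _Packed(decoys.template, decoys.partition)
    # canonical ligand CA coordinates per decoy (receptor frame of the template)
    lig_cas = []
    for d in ranked:
        transform, _ = kabsch_superpose(d.coords[tmp.rec_ca], tmp.coords0[tmp.rec_ca])
        lig_cas.append(transform.apply(d.coords[tmp.lig_ca]))
    centers: list[Decoy] = []
    center_cas: list[np.ndarray] = []
    members: dict[int, int] = {}
    for i, d in enumerate(ranked):
        assigned = None
        for ci, cas in enumerate(center_cas):
            rmsd = float(np.sqrt(np.mean(np.sum((lig_cas[i] - cas) ** 2, axis=1))))
            if rmsd < rmsd_cutoff:
                assigned = ci
                break
        if assigned is None:
            centers.append(d)
            center_cas.append(lig_cas[i])
            assigned = len(centers) - 1
        members[i] = assigned
    keep = min(k, len(centers))
    members = {i: c for i, c in members.items() if c < keep}
    return ClusterSet(centers=centers[:keep], members=members, rmsd_cutoff=rmsd_cutoff)
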