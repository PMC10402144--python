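import math

import numpy as np
import pytest

from _oracles import coarse_score_brute
from alphared.redock import (
    CoarseContactScore,
    MoveParams,
    ReplicaLadder,
    backbone_perturb,
    cluster_decoys,
    default_score,
    exchange_attempt,
    interface_score,
    ligand_rmsd_ca,
    metropolis_accept,
    randomize_orientation,
    rank_decoys,
    rigid_move,
    run_global_dock,
    run_local_dock,
)
from alphared.structure_io import Partition
from conftest import two_chain_structure


PART = Partition(("A",), ("B",))


class TestCoarseScore:
    def test_far_separation_scores_zero(self):
        s = two_chain_structure([(0, 0, 0), (3, 0, 0), (6, 0, 0)], [(40, 0, 0), (43, 0, 0), (46, 0, 0)])
        assert default_score(s, PART) == 0.0

    def test_single_pair_on_plateau_scores_minus_watt(self):
        # CA-only residues: glycine surrogate rule puts the contact on CA
        s = two_chain_structure([(0, 0, 0), (0, 30, 0), (0, 60, 0)], [(5, 0, 0), (40, 30, 0), (40, 60, 0)])
        assert default_score(s, PART) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_pair_sum(self, toy):
        got = default_score(toy.bound, toy.partition)
        rec_cb = [
            (r.atom("CB") or r.ca).coords for r in toy.bound.chains["A"]
        ]
        lig_cb = [
            (r.atom("CB") or r.ca).coords for r in toy.bound.chains["B"]
        ]
        assert got == pytest.approx(coarse_score_brute(rec_cb, lig_cb), abs=1e-9)

    def test_interface_score_equals_score_for_finite_range(self, toy):
        assert interface_score(toy.bound, toy.partition) == default_score(toy.bound, toy.partition)

    def test_clash_penalized(self):
        s = two_chain_structure([(0, 0, 0), (0, 30, 0), (0, 60, 0)], [(2.0, 0, 0), (40, 30, 0), (40, 60, 0)])
        assert default_score(s, PART) == pytest.approx(10.0 * 1.5**2, abs=1e-9)


class TestRandomizeOrientation:
    def test_seeded_determinism(self, toy):
        a = randomize_orientation(toy.bound, toy.partition, 42)
        b = randomize_orientation(toy.bound, toy.partition, 42)
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_contact_distance_window(self, toy):
        from scipy.spatial.distance import cdist

        for seed in range(40):
            s = randomize_orientation(toy.bound, toy.partition, seed)
            rec = np.array([a.coords for r in s.chains["A"] for a in r.atoms])
            lig = np.array([a.coords for r in s.chains["B"] for a in r.atoms])
            assert 3.0 < cdist(rec, lig).min() < 5.0

    def test_directions_cover_octants(self, toy):
        rec_centroid = np.mean(
            [a.coords for r in toy.bound.chains["A"] for a in r.atoms], axis=0
        )
        counts = np.zeros(8)
        for seed in range(400):
            s = randomize_orientation(toy.bound, toy.partition, seed)
            lig_centroid = np.mean(
                [a.coords for r in s.chains["B"] for a in r.atoms], axis=0
            )
            d = lig_centroid - rec_centroid
            octant = (d[0] > 0) * 4 + (d[1] > 0) * 2 + (d[2] > 0)
            counts[octant] += 1
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.001


class TestRigidMove:
    def test_zero_magnitudes_identity(self, toy):
        params = MoveParams(trans_mag=1e-12, rot_mag=0.0)
        out = rigid_move(toy.bound, toy.partition, params, 1)
        np.testing.assert_allclose(out.coords(), toy.bound.coords(), atol=1e-9)

    def test_displacement_bounded_and_receptor_untouched(self, toy):
        params = MoveParams.global_defaults()
        rng = np.random.default_rng(3)
        lig0 = np.mean([a.coords for r in toy.bound.chains["B"] for a in r.atoms], axis=0)
        for _ in range(300):
            out = rigid_move(toy.bound, toy.partition, params, rng)
            lig1 = np.mean([a.coords for r in out.chains["B"] for a in r.atoms], axis=0)
            assert np.linalg.norm(lig1 - lig0) <= params.trans_mag + 1e-9
            rec0 = np.array([a.coords for r in toy.bound.chains["A"] for a in r.atoms])
            rec1 = np.array([a.coords for r in out.chains["A"] for a in r.atoms])
            np.testing.assert_array_equal(rec0, rec1)


class TestBackbonePerturb:
    def test_anchors_and_outside_bit_identical(self, toy):
        seg = toy.hinge_segment
        out = backbone_perturb(toy.bound, seg, MoveParams.local_defaults(), 7)
        for r0, r1 in zip(toy.bound.residues(), out.residues()):
            inside = (
                r0.chain_id == seg[0] and seg[1] < r0.seq_pos < seg[2]
            )
            for a0, a1 in zip(r0.atoms, r1.atoms):
                if inside:
                    continue
                np.testing.assert_array_equal(a0.coords, a1.coords)

    def test_anchor_distance_preserved(self, toy):
        seg = toy.hinge_segment
        out = backbone_perturb(toy.bound, seg, MoveParams.local_defaults(), 11)
        d0 = np.linalg.norm(
            toy.bound.residue(seg[0], seg[1]).ca.coords
            - toy.bound.residue(seg[0], seg[2]).ca.coords
        )
        d1 = np.linalg.norm(
            out.residue(seg[0], seg[1]).ca.coords - out.residue(seg[0], seg[2]).ca.coords
        )
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_matches_closed_form_rotation(self, toy):
        seg = toy.hinge_segment
        params = MoveParams.local_defaults()
        out = backbone_perturb(toy.bound, seg, params, 23)
        # replay the angle draw with the same generator sequence
        rng = np.random.default_rng(23)
        angle = float(
            np.clip(
                rng.normal(0.0, math.radians(params.backbone_angle_sigma)),
                -math.radians(params.backbone_angle_cap),
                math.radians(params.backbone_angle_cap),
            )
        )
        p0 = toy.bound.residue(seg[0], seg[1]).ca.coords
        p1 = toy.bound.residue(seg[0], seg[2]).ca.coords
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
        for pos in range(seg[1] + 1, seg[2]):
            for a0, a1 in zip(
                toy.bound.residue(seg[0], pos).atoms, out.residue(seg[0], pos).atoms
            ):
                expected = R @ (a0.coords - p0) + p0
                np.testing.assert_allclose(a1.coords, expected, atol=1e-9)

    def test_too_short_segment_raises(self, toy):
        with pytest.raises(ValueError):
            backbone_perturb(toy.bound, ("B", 3, 4), MoveParams.local_defaults(), 0)


class TestAcceptanceCriteria:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, 1.0, rng) for _ in range(100))

    def test_huge_uphill_never_accepted(self):
        rng = np.random.default_rng(0)
        assert not any(metropolis_accept(1e9, 1.0, rng) for _ in range(10_000))

    def test_uphill_frequency_matches_boltzmann(self):
        rng = np.random.default_rng(1)
        n = 20_000
        acc = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma

    def test_exchange_always_swaps_on_equal_energy(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            _, _, swapped = exchange_attempt(("x", 3.0, 1.0), ("y", 3.0, 0.5), rng)
            assert swapped

    def test_exchange_swaps_when_hot_is_deeper(self):
        rng = np.random.default_rng(3)
        # hot replica (smaller beta) holds the lower energy -> log p >= 0
        _, _, swapped = exchange_attempt(("cold", 5.0, 1.0), ("hot", -5.0, 0.2), rng)
        assert swapped

    def test_exchange_preserves_configurations(self):
        rng = np.random.default_rng(4)
        si, sj, swapped = exchange_attempt(("conf_i", 0.0, 1.0), ("conf_j", 10.0, 0.5), rng)
        assert {si[0], sj[0]} == {"conf_i", "conf_j"}
        if swapped:
            assert (si[2], sj[2]) == (0.5, 1.0)

    def test_exchange_frequency_matches_formula(self):
        rng = np.random.default_rng(5)
        # cold replica already holds the lower energy -> swap probability < 1
        b_i, b_j, e_i, e_j = 1.0, 0.5, 0.0, 2.0
        p = math.exp((b_i - b_j) * (e_i - e_j))
        n = 20_000
        acc = sum(
            exchange_attempt(("i", e_i, b_i), ("j", e_j, b_j), rng)[2] for _ in range(n)
        )
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sigma


class TestEngineRuns:
    def test_global_dock_seeded_determinism(self, toy):
        kw = dict(ladder=ReplicaLadder(n_trajectories=2), n_steps=150, seed=9)
        a = run_global_dock(toy.bound, toy.partition, **kw)
        b = run_global_dock(toy.bound, toy.partition, **kw)
        assert len(a) == len(b) > 0
        for da, db in zip(a, b):
            assert da.provenance == db.provenance
            assert da.interface_score == db.interface_score
            np.testing.assert_array_equal(da.coords, db.coords)

    def test_flat_score_accepts_everything(self, toy):
        flat = CoarseContactScore(w_rep=0.0, w_att=0.0)
        ds = run_global_dock(
            toy.bound,
            toy.partition,
            ladder=ReplicaLadder(n_trajectories=1),
            n_steps=200,
            seed=0,
            score_fn=flat,
            snapshot_interval=50,
        )
        # every trial accepted -> exactly n_steps/interval snapshots per replica
        assert len(ds) == 3 * (200 // 50)
        assert all(d.interface_score == 0.0 for d in ds)

    def test_local_dock_empty_mobile_equals_rigid_only(self, toy):
        kw = dict(ladder=ReplicaLadder(n_trajectories=1), n_steps=100, seed=5)
        a = run_local_dock(toy.unbound, toy.partition, mobile=None, **kw)
        b = run_local_dock(toy.unbound, toy.partition, mobile=[], **kw)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.coords, db.coords)

    def test_local_dock_never_worse_than_start(self, toy):
        ds = run_local_dock(
            toy.unbound,
            toy.partition,
            mobile=[toy.hinge_segment],
            ladder=ReplicaLadder(n_trajectories=2),
            n_steps=150,
            seed=3,
        )
        start_score = ds.decoys[0].interface_score
        assert rank_decoys(ds)[0].interface_score <= start_score

    def test_rank_decoys_orders_and_conserves(self, toy):
        ds = run_global_dock(
            toy.bound,
            toy.partition,
            ladder=ReplicaLadder(n_trajectories=2),
            n_steps=150,
            seed=1,
        )
        ranked = rank_decoys(ds)
        scores = [d.interface_score for d in ranked]
        assert scores == sorted(scores)
        assert sorted(d.provenance for d in ranked) == sorted(d.provenance for d in ds)


class TestClustering:
    def test_identical_decoys_single_cluster(self, toy):
        ds = run_global_dock(
            toy.bound, toy.partition, ladder=ReplicaLadder(n_trajectories=1),
            n_steps=60, seed=2, score_fn=CoarseContactScore(w_rep=0.0, w_att=0.0),
        )
        for d in ds:
            d.coords = ds.decoys[0].coords.copy()
            d.interface_score = 0.0
        cl = cluster_decoys(ds)
        assert len(cl.centers) == 1
        assert set(cl.members.values()) == {0}

    def test_two_planted_poses_two_centers(self, toy):
        ds = run_global_dock(
            toy.bound, toy.partition, ladder=ReplicaLadder(n_trajectories=1),
            n_steps=60, seed=2, score_fn=CoarseContactScore(w_rep=0.0, w_att=0.0),
        )
        base = ds.decoys[0].coords
        n_lig_atoms = sum(len(r.atoms) for r in toy.bound.chains["B"])
        packed_lig = list(range(toy.bound.n_atoms - n_lig_atoms, toy.bound.n_atoms))
        for i, d in enumerate(ds):
            d.coords = base.copy()
            if i % 2:
                d.coords[packed_lig] += np.array([40.0, 0.0, 0.0])
                d.interface_score = -1.0 - i  # far pose scores better
            else:
                d.interface_score = -float(i)
        cl = cluster_decoys(ds, rmsd_cutoff=5.0)
        assert len(cl.centers) == 2
        # each center is the lowest-score member of its pose family
        scores = sorted(d.interface_score for d in ds)
        assert cl.centers[0].interface_score == scores[0]

    def test_k_truncation(self, toy):
        ds = run_global_dock(
            toy.bound, toy.partition, ladder=ReplicaLadder(n_trajectories=2),
            n_steps=300, seed=8,
        )
        cl = cluster_decoys(ds, rmsd_cutoff=1.0, k=5)
        assert len(cl.centers) <= 5
        assert [c.interface_score for c in cl.centers] == sorted(
            c.interface_score for c in cl.centers
        )

    def test_ligand_rmsd_ca_self_zero(self, toy):
        assert ligand_rmsd_ca(toy.bound, toy.bound, toy.partition) == pytest.approx(0.0, abs=1e-12)
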