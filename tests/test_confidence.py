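import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import auc_pairwise, interface_residues_brute, mobile_runs_brute
from conftest import make_residue, two_chain_structure
from alphared.confidence import (
    ConfidenceReport,
    GateParams,
    Route,
    average_plddt,
    confidence_report,
    confusion_at_thresholds,
    fit_sigmoid,
    gate_decision,
    interface_contacts,
    interface_plddt,
    interface_residues,
    roc_auc,
    select_mobile_residues,
)
from alphared.structure_io import Partition, Structure

PART = Partition(("A",), ("B",))


class TestInterfaceGeometry:
    def test_separated_chains_have_no_interface(self):
        s = two_chain_structure([(0, 0, 0), (2, 0, 0), (4, 0, 0)], [(30, 0, 0), (32, 0, 0), (34, 0, 0)])
        iface = interface_residues(s, PART)
        assert iface["receptor"] == [] and iface["ligand"] == []
        assert interface_plddt(s, PART) is None

    def test_single_close_pair_detected(self):
        s = two_chain_structure(
            [(0, 0, 0), (0, 6, 0), (0, 12, 0)], [(7.9, 0, 0), (30, 6, 0), (30, 12, 0)]
        )
        iface = interface_residues(s, PART, cutoff=8.0)
        assert [r.seq_pos for r in iface["receptor"]] == [1]
        assert [r.seq_pos for r in iface["ligand"]] == [1]

    def test_boundary_is_strictly_within(self):
        s = two_chain_structure([(0, 0, 0), (0, 9, 0), (0, 18, 0)], [(8.0, 0, 0), (30, 9, 0), (30, 18, 0)])
        iface = interface_residues(s, PART, cutoff=8.0)
        assert iface["receptor"] == []
        inclusive = interface_residues(s, PART, cutoff=8.0, inclusive=True)
        assert [r.seq_pos for r in inclusive["receptor"]] == [1]

    def test_matches_exhaustive_scan_on_fixture(self, toy):
        iface = interface_residues(toy.bound, toy.partition, cutoff=8.0)
        rec = toy.bound.chains["A"]
        lig = toy.bound.chains["B"]
        hits_a, hits_b = interface_residues_brute(rec, lig, cutoff=8.0)
        assert {r.seq_pos for r in iface["receptor"]} == {rec[i].seq_pos for i in hits_a}
        assert {r.seq_pos for r in iface["ligand"]} == {lig[j].seq_pos for j in hits_b}

    def test_contact_count_planted_distances(self):
        # CB pairs at 4.0, 4.9 and 5.1 A -> exactly two contacts under 5 A
        ca_a = [(0, 0, 0), (0, 20, 0), (0, 40, 0)]
        ca_b = [(10, 0, 0), (10, 20, 0), (10, 40, 0)]
        s = two_chain_structure(ca_a, ca_b)
        from alphared.structure_io import Atom

        for i, d in enumerate((4.0, 4.9, 5.1)):
            s.chains["A"][i].atoms.append(
                Atom(name="CB", element="C", coords=np.array([0.0, 20.0 * i, 0.0]))
            )
            s.chains["B"][i].atoms.append(
                Atom(name="CB", element="C", coords=np.array([d, 20.0 * i, 0.0]))
            )
        assert interface_contacts(s, PART, cutoff=5.0) == 2

    def test_glycine_uses_ca_surrogate(self):
        s = two_chain_structure([(0, 0, 0), (0, 20, 0), (0, 40, 0)], [(4, 0, 0), (30, 20, 0), (30, 40, 0)])
        assert interface_contacts(s, PART, cutoff=5.0) == 1


class TestPlddtSummaries:
    def test_average_plddt_mean(self):
        s = two_chain_structure([(0, 0, 0), (3, 0, 0), (6, 0, 0)], [(20, 0, 0), (23, 0, 0), (26, 0, 0)],
                                bfactors_a=[80.0, 100.0, 90.0], bfactors_b=[90.0, 90.0, 90.0])
        assert average_plddt(s) == pytest.approx(90.0)

    def test_interface_plddt_only_over_interface(self):
        # receptor residue 1 and ligand residue 1 interact; others far away
        s = two_chain_structure(
            [(0, 0, 0), (0, 50, 0), (0, 100, 0)],
            [(5, 0, 0), (5, 50, 100), (5, 100, 100)],
            bfactors_a=[70.0, 100.0, 100.0],
            bfactors_b=[90.0, 100.0, 100.0],
        )
        assert interface_plddt(s, PART) == pytest.approx(80.0)

    def test_empty_structure_raises(self):
        with pytest.raises(Exception):
            average_plddt(Structure("empty", {}))


class TestGate:
    @pytest.mark.parametrize(
        "value,route",
        [(84.9, Route.GLOBAL_DOCK), (85.0, Route.GLOBAL_DOCK), (85.0001, Route.LOCAL_DOCK), (92.0, Route.LOCAL_DOCK)],
    )
    def test_step_exactly_at_85(self, value, route):
        rep = ConfidenceReport(
            interface_residues={"receptor": [], "ligand": []},
            n_interface_residues=1,
            n_interface_contacts=0,
            avg_plddt=90.0,
            interface_plddt=value,
            gate=Route.GLOBAL_DOCK,
        )
        assert gate_decision(rep) is route

    def test_missing_interface_routes_global(self):
        rep = ConfidenceReport(
            interface_residues={"receptor": [], "ligand": []},
            n_interface_residues=0,
            n_interface_contacts=0,
            avg_plddt=95.0,
            interface_plddt=None,
            gate=Route.GLOBAL_DOCK,
        )
        assert gate_decision(rep) is Route.GLOBAL_DOCK

    def test_report_gate_consistent(self, toy):
        rep = confidence_report(toy.model, toy.partition)
        assert rep.gate is gate_decision(rep)


class TestMobileSegments:
    def test_all_confident_no_segments(self):
        profile = [("A", i, 90.0) for i in range(1, 11)]
        assert select_mobile_residues(profile).segments == []

    def test_single_run_detected(self):
        profile = [("A", 1, 90), ("A", 2, 75), ("A", 3, 75), ("A", 4, 75), ("A", 5, 90)]
        assert select_mobile_residues(profile).segments == [("A", 2, 4)]

    def test_short_run_dropped(self):
        profile = [("A", 1, 75), ("A", 2, 75), ("A", 3, 90)]
        assert select_mobile_residues(profile).segments == []

    def test_runs_do_not_cross_chains(self):
        profile = [("A", 9, 70), ("A", 10, 70), ("B", 11, 70), ("B", 12, 70), ("B", 13, 70)]
        assert select_mobile_residues(profile).segments == [("B", 11, 13)]

    def test_runs_require_consecutive_numbering(self):
        profile = [("A", 1, 70), ("A", 2, 70), ("A", 5, 70), ("A", 6, 70), ("A", 7, 70)]
        assert select_mobile_residues(profile).segments == [("A", 5, 7)]

    @given(
        st.lists(st.floats(min_value=40, max_value=100), min_size=1, max_size=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_run_length_oracle(self, values):
        profile = [("A", i + 1, v) for i, v in enumerate(values)]
        got = select_mobile_residues(profile).segments
        assert got == mobile_runs_brute(profile)


class TestDiscriminator:
    def test_perfect_separation_auc_one(self):
        _, auc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_all_ties_auc_half(self):
        _, auc = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_one_swap_auc(self):
        _, auc = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.normal(size=n).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores.tolist(), labels.tolist())
        assert auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)

    def test_confusion_hand_tally(self):
        plddts = [90, 90, 90, 90, 80, 80, 80, 90, 80, 80]
        irmsds = [1, 2, 3, 9, 8, 9, 10, 1, 2, 11]
        # predicted + : >= 85 -> first 4 and idx 7; actual + : <= 4
        out = confusion_at_thresholds(plddts, irmsds)
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (4, 1, 1, 4)
        assert out["accuracy"] == pytest.approx(0.8)
        assert out["precision"] == pytest.approx(4 / 5)

    def test_confusion_validates_inputs(self):
        with pytest.raises(ValueError):
            confusion_at_thresholds([], [])
        with pytest.raises(ValueError):
            confusion_at_thresholds([90.0], [1.0, 2.0])


class TestSigmoidFit:
    def test_recovers_exact_parameters(self):
        x = np.linspace(50, 100, 40)
        y = 0.1 + (0.9 - 0.1) / (1 + np.exp(-0.3 * (x - 82.0)))
        fit = fit_sigmoid(x.tolist(), y.tolist())
        assert fit.converged
        assert fit.midpoint == pytest.approx(82.0, rel=1e-4)
        assert fit.slope == pytest.approx(0.3, rel=1e-4)
        assert fit.floor == pytest.approx(0.1, rel=1e-4)
        assert fit.ceiling == pytest.approx(0.9, rel=1e-4)

    def test_constant_data_degenerates_gracefully(self):
        fit = fit_sigmoid([60, 70, 80, 90], [0.5, 0.5, 0.5, 0.5])
        preds = fit.predict(np.array([60.0, 75.0, 90.0]))
        np.testing.assert_allclose(preds, 0.5, atol=1e-6)

    def test_monotone_data_monotone_curve(self):
        x = np.linspace(60, 95, 20)
        y = np.linspace(0.1, 0.9, 20)
        fit = fit_sigmoid(x.tolist(), y.tolist())
        grid = fit.predict(np.linspace(60, 95, 100))
        assert np.all(np.diff(grid) >= -1e-9)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1, 2, 3], [0.1, 0.2, 0.3])
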