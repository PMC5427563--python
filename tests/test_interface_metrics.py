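import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import chain_from_coords, dimer_from_coords
from dockppi.geometry import RigidTransform, apply_transform
from dockppi.interface_metrics import (
    MODEL_CRITERIA,
    AcceptanceCriteria,
    ConfusionCounts,
    classify_metrics,
    contact_map,
    failure_spectrum,
    interface_overlap_mcc,
    interface_residues,
    irmsd,
    pcs,
    success_rate,
)
from dockppi.decoys import perturb_native
from dockppi.structio import DimerStructure


def two_point_dimer(separation):
    """Two single-residue chains whose only atoms sit `separation` apart."""
    return dimer_from_coords([[0.0, 0, 0]], [[separation, 0, 0]])


def brute_force_interface(dimer, cutoff=10.0):
    rec, lig = dimer.receptor, dimer.ligand
    r_set, l_set = set(), set()
    for rr in rec.residues:
        for lr in lig.residues:
            d = np.linalg.norm(
                rr.coords[:, None] - lr.coords[None], axis=-1
            ).min()
            if d <= cutoff:
                r_set.add(rr.res_seq)
                l_set.add(lr.res_seq)
    return r_set, l_set


class TestInterfaceResidues:
    def test_boundary_inside(self):
        iface = interface_residues(two_point_dimer(9.9))
        assert iface.receptor_residues == {1} and iface.ligand_residues == {1}

    def test_boundary_outside(self):
        iface = interface_residues(two_point_dimer(10.1))
        assert iface.total == 0

    def test_matches_brute_force_on_toy_dimer(self, toy_dimer):
        iface = interface_residues(toy_dimer)
        r_set, l_set = brute_force_interface(toy_dimer)
        assert set(iface.receptor_residues) == r_set
        assert set(iface.ligand_residues) == l_set
        assert iface.total >= 20

    def test_nonpositive_cutoff(self, toy_dimer):
        with pytest.raises(ValueError):
            interface_residues(toy_dimer, cutoff=0.0)


class TestContactMap:
    def test_contact_within_cutoff(self):
        cm = contact_map(two_point_dimer(4.9))
        assert cm.contacts == {(1, 1)}

    def test_separated_chains_empty(self):
        assert not contact_map(two_point_dimer(20.0)).contacts

    def test_matches_brute_force(self, toy_dimer):
        cm = contact_map(toy_dimer, cutoff=5.0)
        expected = set()
        for rr in toy_dimer.receptor.residues:
            for lr in toy_dimer.ligand.residues:
                d = np.linalg.norm(rr.coords[:, None] - lr.coords[None], axis=-1).min()
                if d <= 5.0:
                    expected.add((rr.res_seq, lr.res_seq))
        assert set(cm.contacts) == expected


class TestIrmsd:
    def test_self_is_zero(self, toy_dimer):
        assert irmsd(toy_dimer, toy_dimer) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation(self, toy_dimer):
        _, decoy = perturb_native(toy_dimer, 0.0, 3.0, seed=5)
        assert irmsd(decoy, toy_dimer) == pytest.approx(3.0, abs=1e-6)

    def test_invariant_under_joint_rigid_transform(self, toy_dimer):
        t = RigidTransform(
            Rotation.from_euler("xyz", [0.4, 1.1, -0.7]).as_matrix(),
            np.array([10.0, -5.0, 2.0]),
        )
        moved = apply_transform(t, toy_dimer)
        assert irmsd(moved, toy_dimer) == pytest.approx(0.0, abs=1e-6)

    def test_empty_interface_errors(self):
        far = dimer_from_coords(
            [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], [[100.0, 0, 0], [103.8, 0, 0]]
        )
        with pytest.raises(ValueError):
            irmsd(far, far)


class TestPcs:
    def test_self_is_one(self, toy_dimer):
        assert pcs(toy_dimer, toy_dimer) == pytest.approx(1.0)

    def test_hand_enumerated_case(self):
        # universe 5x5; reference contacts = the diagonal (5); model keeps 3
        # of them and adds one spurious contact: TP=3 FP=1 FN=2 TN=19
        # -> MCC = 55/sqrt(4*5*20*21) = 55/sqrt(8400)
        def build(contacts):
            # receptors on a 20 Å-spaced line; ligand residue j sits 4 Å from
            # receptor i when (i, j) is a contact, far off in +y otherwise
            rec = [[20.0 * i, 0.0, 0.0] for i in range(1, 6)]
            lig = [[0.0, 1000.0 + 20.0 * j, 0.0] for j in range(1, 6)]
            for i, j in contacts:
                lig[j - 1] = [20.0 * i, 4.0, 0.0]
            return dimer_from_coords(rec, lig)

        reference = build({(1, 1), (2, 2), (3, 3), (4, 4), (5, 5)})
        model = build({(1, 1), (2, 2), (3, 3), (4, 5)})
        assert set(contact_map(model).contacts) == {(1, 1), (2, 2), (3, 3), (4, 5)}
        assert pcs(model, reference) == pytest.approx(55.0 / np.sqrt(8400.0))

    def test_zero_overlap_nonpositive(self, toy_dimer):
        _, far_decoy = perturb_native(toy_dimer, 180.0, 40.0, seed=9)
        assert pcs(far_decoy, toy_dimer) <= 0.0

    def test_empty_reference_contacts_error(self):
        far = dimer_from_coords(
            [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], [[100.0, 0, 0], [103.8, 0, 0]]
        )
        with pytest.raises(ValueError):
            pcs(far, far)


class TestInterfaceOverlapMcc:
    def test_self_is_one(self, toy_dimer):
        assert interface_overlap_mcc(toy_dimer, toy_dimer) == pytest.approx(1.0)

    def test_hand_built_partial_overlap(self):
        # 6-residue receptor, 4-residue ligand; two dimers whose interfaces
        # overlap in some receptor positions only
        def dimer(lig_x):
            rec = [[4.0 * i, 0.0, 0.0] for i in range(6)]
            lig = [[lig_x + 4.0 * j, 8.0, 0.0] for j in range(4)]
            return dimer_from_coords(rec, lig)

        a, b = dimer(0.0), dimer(8.0)
        mcc = interface_overlap_mcc(a, b)

        # independent confusion-count oracle over per-position membership
        def membership(d):
            r_set, l_set = brute_force_interface(d)
            out = [r.res_seq in r_set for r in d.receptor.residues]
            out += [r.res_seq in l_set for r in d.ligand.residues]
            return out

        ma, mb = membership(a), membership(b)
        tp = sum(x and y for x, y in zip(ma, mb))
        fp = sum(x and not y for x, y in zip(ma, mb))
        fn = sum(y and not x for x, y in zip(ma, mb))
        tn = len(ma) - tp - fp - fn
        expected = classify_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)).MCC
        assert mcc == pytest.approx(expected)

    def test_unpairable_chains_error(self, toy_dimer):
        other = dimer_from_coords([[0, 0, 0], [3.8, 0, 0]], [[5.0, 0, 0]])
        with pytest.raises(ValueError):
            interface_overlap_mcc(toy_dimer, other)


class TestClassifyMetrics:
    def test_hand_case(self):
        m = classify_metrics(ConfusionCounts(TP=8, FP=2, TN=8, FN=2))
        assert (m.TPR, m.FPR, m.ACC, m.MCC) == pytest.approx((0.8, 0.2, 0.8, 0.6))

    def test_perfect_classifier(self):
        m = classify_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (m.TPR, m.FPR, m.ACC, m.MCC) == (1.0, 0.0, 1.0, 1.0)

    def test_always_positive_mcc_zero(self):
        m = classify_metrics(ConfusionCounts(TP=10, FP=10, TN=0, FN=0))
        assert m.MCC == 0.0

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            classify_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)

    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    @settings(derandomize=True, max_examples=200)
    def test_metric_ranges_hold_for_any_confusion_matrix(self, tp, fp, tn, fn):
        assume(tp + fp + tn + fn > 0)
        m = classify_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert 0.0 <= m.TPR <= 1.0 or tp + fn == 0
        assert 0.0 <= m.FPR <= 1.0 or fp + tn == 0
        assert 0.0 <= m.ACC <= 1.0
        assert -1.0 <= m.MCC <= 1.0


def quality(model, reference):
    return -irmsd(model, reference)


@pytest.fixture(scope="module")
def ranked_targets(toy_dimer):
    """Three targets with controlled decoy quality.

    Target 0: near-native at rank 1. Target 1: near-native buried at rank 3
    (top_k=2 -> scoring failure). Target 2: nothing near-native (sampling
    failure at tight thresholds)."""
    def decoy(rot, trans, seed):
        return perturb_native(toy_dimer, rot, trans, seed=seed)[1]

    t0 = [decoy(0, 0.5, 1), decoy(45, 15, 2)]
    t1 = [decoy(60, 20, 3), decoy(45, 15, 4), decoy(0, 0.5, 5)]
    t2 = [decoy(90, 30, 6), decoy(120, 25, 7)]
    return [(t0, toy_dimer), (t1, toy_dimer), (t2, toy_dimer)]


class TestSuccessRate:
    def test_all_native_rank1(self, toy_dimer):
        targets = [([toy_dimer], toy_dimer)] * 3
        assert success_rate(targets, MODEL_CRITERIA) == 1.0

    def test_no_passing_models(self, toy_dimer):
        bad = perturb_native(toy_dimer, 120.0, 30.0, seed=8)[1]
        assert success_rate([([bad], toy_dimer)], MODEL_CRITERIA) == 0.0

    def test_two_of_three_targets(self, ranked_targets):
        # top_k=2 hides target 1's good model at rank 3; target 2 never passes
        assert success_rate(ranked_targets, MODEL_CRITERIA, top_k=2) == pytest.approx(1 / 3)
        assert success_rate(ranked_targets, MODEL_CRITERIA, top_k=3) == pytest.approx(2 / 3)

    def test_empty_target_list(self):
        with pytest.raises(ValueError):
            success_rate([], MODEL_CRITERIA)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            AcceptanceCriteria(irmsd_max=-1.0, pcs_min=0.3)


class TestFailureSpectrum:
    def test_fractions_sum_and_monotonicity(self, ranked_targets):
        thresholds = [-30.0, -8.5, -2.5, -0.1]
        points = failure_spectrum(ranked_targets, quality, thresholds, top_k=2, pool_k=10)
        for p in points:
            total = (
                p.success_fraction
                + p.scoring_failure_fraction
                + p.sampling_failure_fraction
            )
            assert total == pytest.approx(1.0, abs=1e-12)
        succ = [p.success_fraction for p in points]
        assert succ == sorted(succ, reverse=True)

    def test_threshold_below_everything(self, ranked_targets):
        (p,) = failure_spectrum(ranked_targets, quality, [-1000.0], top_k=2)
        assert p.success_fraction == 1.0

    def test_scoring_failure_detected(self, ranked_targets):
        # at a tight threshold only near-native decoys qualify; target 1 has
        # one but outside the top 2
        (p,) = failure_spectrum(ranked_targets, quality, [-2.0], top_k=2)
        assert p.scoring_failure_fraction == pytest.approx(1 / 3)

    def test_threshold_above_everything(self, ranked_targets):
        (p,) = failure_spectrum(ranked_targets, quality, [1.0], top_k=2)
        assert p.sampling_failure_fraction == 1.0

    def test_empty_thresholds(self, ranked_targets):
        with pytest.raises(ValueError):
            failure_spectrum(ranked_targets, quality, [])
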