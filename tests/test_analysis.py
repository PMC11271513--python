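"""Trajectory analysis: RMSD, dissociation rule, gates, clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twopocket as tp
from twopocket import analysis as ta
from twopocket.analysis import AnalysisError
from twopocket.dynamics import Trajectory
from twopocket.landscape import Ligand


def make_traj(cf3, o1, bond=None):
    cf3 = np.asarray(cf3, dtype=float)
    o1 = np.asarray(o1, dtype=float)
    if bond is None:
        bond = float(np.linalg.norm(cf3[0] - o1[0]))
    return Trajectory(
        times=np.arange(len(cf3), dtype=float) + 1.0,
        cf3=cf3,
        o1=o1,
        bond_length=bond,
        seed=0,
        config_hash="test",
    )


def rmsd_series(values):
    ref = Ligand(np.zeros(2), np.zeros(2), 0.0)
    return ta.RMSDSeries(
        times=np.arange(len(values), dtype=float),
        rmsd=np.asarray(values, dtype=float),
        reference=ref,
    )


class TestLigandRMSD:
    def test_zero_for_reference_frame(self):
        ref = Ligand(np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.hypot(2, 2))
        traj = make_traj([[1.0, 2.0]], [[3.0, 4.0]])
        out = ta.ligand_rmsd(traj, ref)
        assert out.rmsd[0] == 0.0

    def test_uniform_translation(self):
        ref = Ligand(np.zeros(2), np.array([0.0, 7.0]), 7.0)
        traj = make_traj([[3.0, 0.0]], [[3.0, 7.0]])
        assert ta.ligand_rmsd(traj, ref).rmsd[0] == pytest.approx(3.0)

    def test_mixed_probe_displacements(self):
        # probe displacements 3 and 4 -> sqrt((9+16)/2)
        ref = Ligand(np.zeros(2), np.array([0.0, 7.0]), 7.0)
        traj = make_traj([[3.0, 0.0]], [[4.0, 7.0]], bond=np.hypot(1, 7))
        assert ta.ligand_rmsd(traj, ref).rmsd[0] == pytest.approx(np.sqrt(12.5))

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(0)
        n = 30
        cf3 = rng.normal(size=(n, 2))
        o1 = cf3 + np.array([7.0, 0.0])
        traj = make_traj(cf3, o1)
        ref = Ligand(np.array([0.5, -0.5]), np.array([7.5, -0.5]), 7.0)
        out = ta.ligand_rmsd(traj, ref)
        for i in range(n):
            expected = np.sqrt(
                0.5
                * (
                    np.sum((cf3[i] - ref.probe_cf3) ** 2)
                    + np.sum((o1[i] - ref.probe_o1) ** 2)
                )
            )
            assert out.rmsd[i] == pytest.approx(expected)


class TestDissociation:
    def test_subthreshold_series_has_no_event(self):
        assert ta.detect_dissociation(rmsd_series([0.0, 10.0, 29.9])) is None

    def test_first_crossing_index(self):
        assert ta.detect_dissociation(rmsd_series([0.0, 31.0, 35.0])) == 1

    def test_persistence_requires_consecutive_frames(self):
        crit = ta.DissociationCriterion(threshold=30.0, persistence=2)
        assert ta.detect_dissociation(rmsd_series([0, 31, 5, 31, 32]), crit) == 3

    def test_constant_zero_series(self):
        assert ta.detect_dissociation(rmsd_series([0.0] * 5)) is None

    @given(
        values=st.lists(st.floats(0.0, 60.0), min_size=1, max_size=50),
        t1=st.floats(5.0, 25.0),
        dt=st.floats(0.1, 20.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_never_gives_earlier_event(self, values, t1, dt):
        lo = ta.detect_dissociation(rmsd_series(values), ta.DissociationCriterion(t1))
        hi = ta.detect_dissociation(rmsd_series(values), ta.DissociationCriterion(t1 + dt))
        if hi is not None:
            assert lo is not None and lo <= hi

    def test_count_dissociations_seven_of_ten(self):
        events = [1, None, 2, 3, None, 0, 4, None, 5, 6]
        assert ta.count_dissociations(events) == {"k": 7, "n": 10}

    def test_count_edge_cases(self):
        assert ta.count_dissociations([None] * 4) == {"k": 0, "n": 4}
        assert ta.count_dissociations([0, 1, 2]) == {"k": 3, "n": 3}
        with pytest.raises(AnalysisError):
            ta.count_dissociations([])


class TestPairDistances:
    def test_pythagorean_pairs(self):
        traj = make_traj([[6.0, 8.0]], [[5.0, 12.0]])
        d_cf3, d_o1 = ta.pair_distances(traj, np.zeros(2))
        assert d_cf3[0] == pytest.approx(10.0)
        assert d_o1[0] == pytest.approx(13.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cf3 = rng.normal(size=(10, 2))
        o1 = cf3 + np.array([0.0, 7.0])
        anchor = np.array([2.0, -1.0])
        d_cf3, d_o1 = ta.pair_distances(make_traj(cf3, o1), anchor)
        for i in range(10):
            assert d_cf3[i] == pytest.approx(np.linalg.norm(cf3[i] - anchor))
            assert d_o1[i] == pytest.approx(np.linalg.norm(o1[i] - anchor))

    def test_dimension_mismatch(self):
        with pytest.raises(AnalysisError):
            ta.pair_distances(make_traj([[0.0, 0.0]], [[7.0, 0.0]]), np.zeros(3))


class TestGateClassification:
    def test_deep_pocket_median_pose_is_gate_a(self):
        out = ta.classify_gates([9.42], [9.97])
        assert out.labels[0] == ta.GATE_A

    def test_met_pocket_median_pose_is_gate_b(self):
        out = ta.classify_gates([6.27], [12.95])
        assert out.labels[0] == ta.GATE_B

    def test_far_pair_is_unbound(self):
        out = ta.classify_gates([40.0], [41.0])
        assert out.labels[0] == ta.UNBOUND

    def test_window_bounds_closed_low_open_high(self):
        w = ta.GateWindows()
        assert ta.classify_gates([w.gateA_cf3[0]], [9.0]).labels[0] == ta.GATE_A
        assert ta.classify_gates([w.gateA_cf3[1]], [9.0]).labels[0] == ta.OTHER

    @given(
        d1=st.floats(0.0, 60.0, allow_nan=False),
        d2=st.floats(0.0, 60.0, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_partition_is_total_and_exclusive(self, d1, d2):
        out = ta.classify_gates([d1], [d2])
        assert out.labels[0] in ta.LABELS

    def test_overlapping_windows_rejected(self):
        with pytest.raises(AnalysisError):
            ta.GateWindows(gateB_cf3=(7.0, 13.0), gateB_o1=(8.0, 13.0))


class TestSubsampleAndStats:
    def test_stride_keeps_every_kth_frame_from_zero(self):
        cf3 = np.arange(2000, dtype=float).reshape(1000, 2)
        traj = make_traj(cf3, cf3 + np.array([7.0, 0.0]))
        sub = ta.subsample_snapshots(traj, 10)
        assert sub.n_frames == 100
        assert np.array_equal(sub.cf3[:, 0], cf3[::10, 0])

    def test_stride_equal_to_length_keeps_first_frame(self):
        traj = make_traj(np.zeros((5, 2)), np.full((5, 2), [7.0, 0.0]))
        sub = ta.subsample_snapshots(traj, 5)
        assert sub.n_frames == 1

    def test_stride_larger_than_length_rejected(self):
        traj = make_traj(np.zeros((5, 2)), np.full((5, 2), [7.0, 0.0]))
        with pytest.raises(AnalysisError):
            ta.subsample_snapshots(traj, 6)

    def test_frequencies_sum_to_one_and_counts(self):
        labels = ta.classify_gates(
            [9.42, 9.42, 6.27, 40.0], [9.97, 9.97, 12.95, 41.0]
        )
        stats = ta.gate_occupancy_stats(labels)
        assert sum(stats["frequencies"].values()) == pytest.approx(1.0)
        assert stats["frequencies"][ta.GATE_A] == pytest.approx(0.5)
        assert stats["frequencies"][ta.GATE_B] == pytest.approx(0.25)
        assert stats["frequencies"][ta.UNBOUND] == pytest.approx(0.25)

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        d1 = rng.uniform(8.0, 12.0, size=11)   # all inside gate A CF3 window
        d2 = rng.uniform(8.0, 12.0, size=11)
        stats = ta.gate_occupancy_stats(ta.classify_gates(d1, d2))
        med = stats["medians"][ta.GATE_A]
        assert med["d_cf3"] == pytest.approx(np.sort(d1)[5])
        assert med["d_o1"] == pytest.approx(np.sort(d2)[5])

    def test_even_count_median_is_central_pair_average(self):
        d1 = np.array([9.0, 10.0, 11.0, 12.0])
        d2 = np.array([9.0, 9.5, 10.0, 10.5])
        med = ta.gate_occupancy_stats(ta.classify_gates(d1, d2))["medians"][ta.GATE_A]
        assert med["d_cf3"] == pytest.approx(10.5)


def exhaustive_two_partition_cost(dmat):
    """Oracle: best 2-partition by exhaustive search of medoid objective."""
    n = dmat.shape[0]
    best_cost, best_assign = np.inf, None
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or (~mask).all():
            continue
        cost = 0.0
        for members in (np.where(mask)[0], np.where(~mask)[0]):
            sub = dmat[np.ix_(members, members)]
            cost += sub.sum(axis=1).min()
        if cost < best_cost:
            best_cost, best_assign = cost, mask.copy()
    return best_cost, best_assign


class TestClusterPoses:
    def _two_cluster_traj(self, rng, n1=6, n2=6, sep=20.0, spread=0.5):
        a = rng.normal(scale=spread, size=(n1, 2))
        b = rng.normal(scale=spread, size=(n2, 2)) + np.array([sep, 0.0])
        cf3 = np.vstack([a, b])
        return make_traj(cf3, cf3 + np.array([7.0, 0.0]))

    def test_recovers_ground_truth_up_to_label_swap(self):
        rng = np.random.default_rng(3)
        traj = self._two_cluster_traj(rng)
        out = ta.cluster_poses(traj, k=2, seed=0)
        lab = out["assignments"]
        assert len(set(lab[:6])) == 1 and len(set(lab[6:])) == 1
        assert lab[0] != lab[-1]

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(4)
        traj = self._two_cluster_traj(rng, n1=5, n2=5, sep=15.0)
        from twopocket.analysis import _frame_rmsd_matrix

        dmat = _frame_rmsd_matrix(traj.cf3, traj.o1)
        oracle_cost, oracle_assign = exhaustive_two_partition_cost(dmat)
        out = ta.cluster_poses(traj, k=2, seed=1)
        assert out["within_cost"] == pytest.approx(oracle_cost)
        same = np.array_equal(out["assignments"].astype(bool), oracle_assign)
        swapped = np.array_equal(~out["assignments"].astype(bool), oracle_assign)
        assert same or swapped

    def test_two_distinct_frames_become_singletons(self):
        traj = make_traj([[0.0, 0.0], [10.0, 0.0]], [[7.0, 0.0], [17.0, 0.0]])
        out = ta.cluster_poses(traj, k=2, seed=0)
        assert sorted(out["assignments"].tolist()) == [0, 1]

    def test_identical_frames_zero_dispersion(self):
        cf3 = np.zeros((6, 2))
        traj = make_traj(cf3, cf3 + np.array([7.0, 0.0]))
        out = ta.cluster_poses(traj, k=2, seed=0)
        assert out["within_cost"] == pytest.approx(0.0)

    def test_too_few_snapshots_rejected(self):
        traj = make_traj([[0.0, 0.0]], [[7.0, 0.0]])
        with pytest.raises(AnalysisError):
            ta.cluster_poses(traj, k=2, seed=0)
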