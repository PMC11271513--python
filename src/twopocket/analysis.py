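"""Trajectory post-processing: RMSD, dissociation, gates, clustering.

Mirrors the analysis chain applied to ligand-unbinding trajectories:
ligand RMSD from the docking-like reference pose (no superposition — the
receptor frame is fixed), a >30-unit dissociation rule with k-of-n
counting across independent runs, gatekeeper-anchor distance pairs,
rectangular gate-A/gate-B pose classification, snapshot subsampling,
occupancy statistics, and two-group pose clustering on the pairwise
frame-RMSD matrix.

Default gate windows are oriented so that the canonical deep-pocket pose
(CF3 ≈ 9.4, O1 ≈ 10.0 from the gatekeeper) falls in gate A and the
metastable Met-pocket pose (CF3 ≈ 6.3, O1 ≈ 13.0) in gate B.  Windows
are closed on the lower bound, open on the upper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import Trajectory
from .landscape import Ligand


class AnalysisError(ValueError):
    pass


GATE_A = "gateA_deep"
GATE_B = "gateB_met"
OTHER = "other_bound"
UNBOUND = "unbound"
LABELS = (GATE_A, GATE_B, OTHER, UNBOUND)


@dataclass
class RMSDSeries:
    times: np.ndarray
    rmsd: np.ndarray
    reference: Ligand


@dataclass(frozen=True)
class DissociationCriterion:
    threshold: float = 30.0
    persistence: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise AnalysisError("threshold must be positive")
        if self.persistence < 1:
            raise AnalysisError("persistence must be >= 1")


@dataclass(frozen=True)
class GateWindows:
    """Rectangular (CF3-distance, O1-distance) windows for the two gates."""

    gateA_cf3: tuple[float, float] = (7.8, 12.5)
    gateA_o1: tuple[float, float] = (7.5, 12.5)
    gateB_cf3: tuple[float, float] = (2.5, 7.8)
    gateB_o1: tuple[float, float] = (10.0, 15.0)
    unbound_cutoff: float = 25.0

    def __post_init__(self) -> None:
        for lo, hi in (self.gateA_cf3, self.gateA_o1, self.gateB_cf3, self.gateB_o1):
            if not lo < hi:
                raise AnalysisError("window bounds must be increasing")
        ax, ay = self.gateA_cf3, self.gateA_o1
        bx, by = self.gateB_cf3, self.gateB_o1
        overlap_x = max(ax[0], bx[0]) < min(ax[1], bx[1])
        overlap_y = max(ay[0], by[0]) < min(ay[1], by[1])
        if overlap_x and overlap_y:
            raise AnalysisError("gate A and gate B rectangles must be disjoint")


@dataclass
class PoseLabelSeries:
    times: np.ndarray
    labels: np.ndarray          # dtype=object/str, one of LABELS
    d_cf3: np.ndarray
    d_o1: np.ndarray


def ligand_rmsd(trajectory: Trajectory, reference: Ligand) -> RMSDSeries:
    """Per-frame probe RMSD from the reference pose in the fixed frame."""
    if trajectory.cf3.shape[1] != reference.probe_cf3.size:
        raise AnalysisError("reference dimensionality does not match trajectory")
    dc = trajectory.cf3 - reference.probe_cf3
    do = trajectory.o1 - reference.probe_o1
    msd = 0.5 * (np.sum(dc * dc, axis=1) + np.sum(do * do, axis=1))
    return RMSDSeries(times=trajectory.times.copy(), rmsd=np.sqrt(msd), reference=reference)


def detect_dissociation(
    series: RMSDSeries, criterion: DissociationCriterion = DissociationCriterion()
) -> Optional[int]:
    """First index where RMSD > threshold for `persistence` consecutive frames."""
    if series.rmsd.size == 0:
        raise AnalysisError("empty RMSD series")
    above = series.rmsd > criterion.threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= criterion.persistence:
            return i - criterion.persistence + 1
    return None


def count_dissociations(run_events: Sequence[Optional[int]]) -> dict:
    """k-of-n tally of runs with a dissociation event."""
    if len(run_events) == 0:
        raise AnalysisError("no runs supplied")
    k = sum(1 for e in run_events if e is not None)
    return {"k": k, "n": len(run_events)}


def pair_distances(trajectory: Trajectory, met_anchor) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distances from the gatekeeper anchor to each probe."""
    anchor = np.asarray(met_anchor, dtype=float)
    if anchor.size != trajectory.cf3.shape[1]:
        raise AnalysisError("anchor dimensionality does not match trajectory")
    d_cf3 = np.linalg.norm(trajectory.cf3 - anchor, axis=1)
    d_o1 = np.linalg.norm(trajectory.o1 - anchor, axis=1)
    return d_cf3, d_o1


def _in_window(x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (x >= window[0]) & (x < window[1])


def classify_gates(
    d_cf3,
    d_o1,
    windows: GateWindows = GateWindows(),
    times=None,
) -> PoseLabelSeries:
    """Assign each (CF3, O1) distance pair to exactly one pose label."""
    d_cf3 = np.atleast_1d(np.asarray(d_cf3, dtype=float))
    d_o1 = np.atleast_1d(np.asarray(d_o1, dtype=float))
    if d_cf3.shape != d_o1.shape:
        raise AnalysisError("distance arrays must have equal length")
    labels = np.full(d_cf3.shape, OTHER, dtype=object)
    in_a = _in_window(d_cf3, windows.gateA_cf3) & _in_window(d_o1, windows.gateA_o1)
    in_b = _in_window(d_cf3, windows.gateB_cf3) & _in_window(d_o1, windows.gateB_o1)
    unbound = (d_cf3 > windows.unbound_cutoff) & (d_o1 > windows.unbound_cutoff)
    labels[unbound] = UNBOUND
    labels[in_a] = GATE_A
    labels[in_b] = GATE_B
    if times is None:
        times = np.arange(d_cf3.size, dtype=float)
    return PoseLabelSeries(
        times=np.asarray(times, dtype=float), labels=labels, d_cf3=d_cf3, d_o1=d_o1
    )


def subsample_snapshots(
    trajectory: Trajectory,
    stride: Optional[int] = None,
    target_count: Optional[int] = None,
) -> Trajectory:
    """Equally spaced frames starting at frame 0 (indices 0, stride, ...).

    Give either ``stride`` or ``target_count`` (the stride is then the
    largest one yielding at least ``target_count`` snapshots).
    """
    if (stride is None) == (target_count is None):
        raise AnalysisError("give exactly one of stride or target_count")
    if stride is None:
        if target_count < 1 or target_count > trajectory.n_frames:
            raise AnalysisError("target_count out of range")
        stride = trajectory.n_frames // target_count
    if stride < 1:
        raise AnalysisError("stride must be >= 1")
    if stride > trajectory.n_frames:
        raise AnalysisError("stride exceeds trajectory length")
    idx = np.arange(0, trajectory.n_frames, stride)
    return Trajectory(
        times=trajectory.times[idx],
        cf3=trajectory.cf3[idx],
        o1=trajectory.o1[idx],
        bond_length=trajectory.bond_length,
        seed=trajectory.seed,
        config_hash=trajectory.config_hash + f"|stride{stride}",
    )


def _median(values: np.ndarray) -> float:
    """Midpoint median: average of the central pair for even counts."""
    v = np.sort(values)
    n = v.size
    if n == 0:
        return float("nan")
    mid = n // 2
    return float(v[mid]) if n % 2 else float(0.5 * (v[mid - 1] + v[mid]))


def gate_occupancy_stats(labels: PoseLabelSeries) -> dict:
    """Per-label frequencies and per-gate median distance pairs."""
    n = labels.labels.size
    if n == 0:
        raise AnalysisError("empty label series")
    out = {"n": n, "frequencies": {}, "medians": {}}
    for lab in LABELS:
        mask = labels.labels == lab
        out["frequencies"][lab] = float(mask.sum()) / n
        if lab in (GATE_A, GATE_B) and mask.any():
            out["medians"][lab] = {
                "d_cf3": _median(labels.d_cf3[mask]),
                "d_o1": _median(labels.d_o1[mask]),
            }
    return out


def _frame_rmsd_matrix(cf3: np.ndarray, o1: np.ndarray) -> np.ndarray:
    """Pairwise probe-RMSD between all frames (no superposition)."""
    dc = cf3[:, None, :] - cf3[None, :, :]
    do = o1[:, None, :] - o1[None, :, :]
    return np.sqrt(0.5 * (np.sum(dc * dc, axis=2) + np.sum(do * do, axis=2)))


def cluster_poses(snapshots: Trajectory, k: int = 2, seed: int = 0) -> dict:
    """k-medoids (PAM-style) clustering on the pairwise frame-RMSD matrix.

    Returns assignments, medoid frame indices, per-cluster mean probe
    positions, and the total within-cluster distance.
    """
    n = snapshots.n_frames
    if n < k:
        raise AnalysisError(f"need at least k={k} snapshots, got {n}")
    dmat = _frame_rmsd_matrix(snapshots.cf3, snapshots.o1)
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)

    def assign(meds):
        return np.argmin(dmat[:, meds], axis=1)

    for _ in range(200):
        labels = assign(medoids)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(labels == j)[0]
            if members.size == 0:
                # re-seed an empty cluster on the point farthest from its medoid
                far = int(np.argmax(dmat[np.arange(n), medoids[labels]]))
                new_medoids[j] = far
                continue
            costs = dmat[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(costs))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = assign(medoids)
    cost = float(dmat[np.arange(n), medoids[labels]].sum())
    means = {
        int(j): {
            "cf3": snapshots.cf3[labels == j].mean(axis=0).tolist(),
            "o1": snapshots.o1[labels == j].mean(axis=0).tolist(),
            "size": int((labels == j).sum()),
        }
        for j in range(k)
        if (labels == j).any()
    }
    return {
        "assignments": labels,
        "medoid_indices": medoids,
        "cluster_means": means,
        "within_cost": cost,
    }
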