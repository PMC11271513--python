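"""Residue interaction fingerprints and the comparative Qb statistic.

Each trajectory snapshot is reduced to a boolean fingerprint over
labelled residue anchors (toy detector: surface contact, i.e. any probe
within a cutoff of the anchor; the schema also carries H-bond/ionic bit
types for completeness, without toy detectors).  For two ligands A and B
the per-bit statistic is

    Qb = (Cb/C0) · 2·(Pb − 1/2),      Pb = pA / (pA + pB),

where pX = Cb_X/C0_X is the bit frequency over ligand X's snapshot set,
Cb/C0 is taken over ligand A's set (the statistic scores A against B),
and Pb = 1/2 when both frequencies are zero.  Qb lies in [−1, 1]; large
positive values flag residues contacted far more often by ligand A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import Trajectory

BIT_TYPES = ("surface_contact", "hbond_donor", "hbond_acceptor", "ionic")


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueBit:
    residue: str
    interaction: str = "surface_contact"

    def __post_init__(self) -> None:
        if self.interaction not in BIT_TYPES:
            raise FingerprintError(f"unknown interaction type {self.interaction!r}")

    @property
    def key(self) -> str:
        return f"{self.residue}:{self.interaction}"


@dataclass
class FingerprintMatrix:
    ligand_id: str
    bits: np.ndarray                       # (n_snapshots, n_bits) bool
    residue_bits: tuple[ResidueBit, ...]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.shape[1] != len(self.residue_bits):
            raise FingerprintError("bit matrix shape does not match residue_bits")
        keys = [rb.key for rb in self.residue_bits]
        if len(set(keys)) != len(keys):
            raise FingerprintError("residue_bits must be unique")


@dataclass
class BitCounts:
    residue_bits: tuple[ResidueBit, ...]
    cb: np.ndarray      # per-bit set-snapshot counts
    c0: int             # total snapshots

    def __post_init__(self) -> None:
        self.cb = np.asarray(self.cb, dtype=int)
        if self.c0 <= 0:
            raise FingerprintError("C0 must be positive")
        if np.any(self.cb < 0) or np.any(self.cb > self.c0):
            raise FingerprintError("Cb must lie in [0, C0]")


@dataclass
class QbTable:
    residue_bits: tuple[ResidueBit, ...]
    p_a: np.ndarray
    p_b: np.ndarray
    pb: np.ndarray
    qb: np.ndarray


def compute_bits(
    frame_cf3: np.ndarray,
    frame_o1: np.ndarray,
    residue_anchors: dict[str, Sequence[float]],
    contact_cutoff: float = 4.5,
) -> np.ndarray:
    """Surface-contact bit vector for one snapshot.

    A residue's bit is set iff the nearer of the two probes lies within
    ``contact_cutoff`` of that residue's anchor point.
    """
    if contact_cutoff <= 0:
        raise FingerprintError("contact_cutoff must be positive")
    cf3 = np.asarray(frame_cf3, dtype=float)
    o1 = np.asarray(frame_o1, dtype=float)
    out = np.zeros(len(residue_anchors), dtype=bool)
    for i, (label, anchor) in enumerate(residue_anchors.items()):
        a = np.asarray(anchor, dtype=float)
        if a.size != cf3.size:
            raise FingerprintError(f"anchor {label!r} dimensionality mismatch")
        dmin = min(np.linalg.norm(cf3 - a), np.linalg.norm(o1 - a))
        out[i] = dmin < contact_cutoff
    return out


def fingerprint_trajectory(
    trajectories: Sequence[Trajectory],
    residue_anchors: dict[str, Sequence[float]],
    ligand_id: str,
    contact_cutoff: float = 4.5,
) -> FingerprintMatrix:
    """Stack per-snapshot contact bits over one or more trajectories."""
    rows = []
    for traj in trajectories:
        for i in range(traj.n_frames):
            rows.append(
                compute_bits(traj.cf3[i], traj.o1[i], residue_anchors, contact_cutoff)
            )
    if not rows:
        raise FingerprintError("no snapshots supplied")
    residue_bits = tuple(ResidueBit(label) for label in residue_anchors)
    return FingerprintMatrix(
        ligand_id=ligand_id, bits=np.array(rows), residue_bits=residue_bits
    )


def tally_bits(matrix: FingerprintMatrix) -> BitCounts:
    """Per-bit set-snapshot counts Cb and the shared snapshot total C0."""
    if matrix.bits.shape[0] == 0:
        raise FingerprintError("empty fingerprint matrix")
    return BitCounts(
        residue_bits=matrix.residue_bits,
        cb=matrix.bits.sum(axis=0),
        c0=matrix.bits.shape[0],
    )


def qb_from_probabilities(p_a, p_b):
    """Qb from per-ligand bit frequencies (vectorized)."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    total = p_a + p_b
    pb = np.where(total > 0, np.divide(p_a, np.where(total > 0, total, 1.0)), 0.5)
    qb = p_a * 2.0 * (pb - 0.5)
    return pb, qb


def qb_score(counts_a: BitCounts, counts_b: BitCounts) -> QbTable:
    """Comparative statistic scoring ligand A's contacts against ligand B's."""
    if tuple(rb.key for rb in counts_a.residue_bits) != tuple(
        rb.key for rb in counts_b.residue_bits
    ):
        raise FingerprintError("residue_bits of the two ligands do not match")
    p_a = counts_a.cb / counts_a.c0
    p_b = counts_b.cb / counts_b.c0
    pb, qb = qb_from_probabilities(p_a, p_b)
    return QbTable(residue_bits=counts_a.residue_bits, p_a=p_a, p_b=p_b, pb=pb, qb=qb)


def rank_residues(table: QbTable, top_n: int | None = None) -> list[tuple[str, float]]:
    """Residue bits sorted by Qb descending; ties broken lexicographically."""
    if len(table.residue_bits) == 0:
        raise FingerprintError("empty Qb table")
    entries = sorted(
        zip((rb.key for rb in table.residue_bits), table.qb),
        key=lambda kv: (-kv[1], kv[0]),
    )
    entries = [(k, float(v)) for k, v in entries]
    return entries[:top_n] if top_n is not None else entries
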