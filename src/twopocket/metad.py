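"""Gaussian-hill metadynamics on a distance collective variable.

The collective variable (CV) is the Euclidean distance between the
ligand probe centroid and the centroid of an anchor set (at toy scale,
the two pocket centers stand in for the binding-site residue set).
Repulsive Gaussian hills deposited along the CV progressively flood the
bound basins; the negative accumulated bias (rescaled by γ/(γ−1) in the
well-tempered variant) estimates the free-energy profile along the CV.

The default hill height is 0.3 energy units; both standard and
well-tempered deposition are provided since either is a reasonable
reading of a bare "initial hill height" prescription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import LangevinConfig, Trajectory, run_langevin
from .landscape import Ligand


class MetadError(ValueError):
    pass


@dataclass(frozen=True)
class HillParams:
    initial_height: float = 0.3     # energy units (kBT)
    width: float = 0.5              # CV (length) units
    deposition_interval: int = 200  # steps between hills
    tempered: bool = True
    bias_factor: float = 10.0       # γ; used iff tempered

    def __post_init__(self) -> None:
        # height 0 is allowed and disables deposition (unbiased control runs)
        if self.initial_height < 0:
            raise MetadError("initial_height must be non-negative")
        if self.width <= 0:
            raise MetadError("width must be positive")
        if self.deposition_interval < 1:
            raise MetadError("deposition_interval must be >= 1")
        if self.tempered and self.bias_factor <= 1:
            raise MetadError("bias_factor must exceed 1 for tempered runs")


@dataclass
class BiasState:
    """Accumulated Gaussian hills: V(s) = Σ h_i exp(−(s−c_i)²/(2 w_i²))."""

    cv_definition: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    widths: list = field(default_factory=list)
    times: list = field(default_factory=list)

    @property
    def n_hills(self) -> int:
        return len(self.centers)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.centers, dtype=float),
            np.asarray(self.heights, dtype=float),
            np.asarray(self.widths, dtype=float),
            np.asarray(self.times, dtype=float),
        )


def cv_distance(frame: Ligand, anchor_set) -> float:
    """Distance between the ligand probe centroid and the anchor centroid."""
    anchors = np.atleast_2d(np.asarray(anchor_set, dtype=float))
    if anchors.shape[0] == 0:
        raise MetadError("anchor_set must be non-empty")
    if anchors.shape[1] != frame.probe_cf3.size:
        raise MetadError("anchor dimensionality does not match the ligand")
    centroid = anchors.mean(axis=0)
    return float(np.linalg.norm(frame.com - centroid))


def bias_potential(bias: BiasState, cv) -> np.ndarray | float:
    """Total bias energy at one or many CV values (≥ 0 by construction)."""
    cv_arr = np.asarray(cv, dtype=float)
    if bias.n_hills == 0:
        out = np.zeros_like(cv_arr, dtype=float)
        return float(out) if cv_arr.ndim == 0 else out
    c, h, w, _ = bias.as_arrays()
    d = cv_arr[..., None] - c
    v = np.sum(h * np.exp(-(d * d) / (2.0 * w * w)), axis=-1)
    return float(v) if cv_arr.ndim == 0 else v


def bias_gradient(bias: BiasState, cv) -> np.ndarray | float:
    """Analytic dV/d(cv)."""
    cv_arr = np.asarray(cv, dtype=float)
    if bias.n_hills == 0:
        out = np.zeros_like(cv_arr, dtype=float)
        return float(out) if cv_arr.ndim == 0 else out
    c, h, w, _ = bias.as_arrays()
    d = cv_arr[..., None] - c
    g = np.sum(-h * d / (w * w) * np.exp(-(d * d) / (2.0 * w * w)), axis=-1)
    return float(g) if cv_arr.ndim == 0 else g


def deposit_hill(
    bias: BiasState,
    cv: float,
    params: HillParams,
    step_time: float,
    kBT: float = 1.0,
) -> BiasState:
    """Append one hill at ``cv`` (well-tempered height scaling if enabled)."""
    height = params.initial_height
    if height == 0.0:
        return bias
    if params.tempered:
        v_here = bias_potential(bias, cv)
        height *= math.exp(-v_here / ((params.bias_factor - 1.0) * max(kBT, 1e-12)))
    bias.centers.append(float(cv))
    bias.heights.append(float(height))
    bias.widths.append(float(params.width))
    bias.times.append(float(step_time))
    return bias


@dataclass
class FreeEnergyProfile:
    grid: np.ndarray
    f: np.ndarray
    offset_convention: str = "minimum-anchored"

    def delta_f(self, window_a: tuple[float, float], window_b: tuple[float, float]) -> float:
        """F(min in window_b) − F(min in window_a)."""
        in_a = (self.grid >= window_a[0]) & (self.grid <= window_a[1])
        in_b = (self.grid >= window_b[0]) & (self.grid <= window_b[1])
        if not in_a.any() or not in_b.any():
            raise MetadError("window contains no grid points")
        return float(self.f[in_b].min() - self.f[in_a].min())


def estimate_free_energy(
    bias: BiasState,
    grid: Sequence[float],
    tempered: bool = True,
    bias_factor: float = 10.0,
    kBT: float = 1.0,
) -> FreeEnergyProfile:
    """Free energy along the CV from the accumulated bias.

    Standard metadynamics: F = −V_bias.  Well-tempered: F =
    −γ/(γ−1)·V_bias.  The profile is shifted so its minimum is 0.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0):
        raise MetadError("grid must be non-empty and increasing")
    v = np.asarray(bias_potential(bias, grid), dtype=float)
    scale = bias_factor / (bias_factor - 1.0) if tempered else 1.0
    f = -scale * v
    f = f - f.min()
    return FreeEnergyProfile(grid=grid, f=f)


def run_metad(
    U,
    config: LangevinConfig,
    hill_params: HillParams,
    anchor_set,
    start: Ligand,
    seed: int,
    bias: Optional[BiasState] = None,
) -> tuple[Trajectory, BiasState]:
    """Langevin dynamics under U + V_bias(cv), depositing hills on the fly.

    Hills are deposited every ``deposition_interval`` steps beginning at
    step 0.  Deterministic for fixed (config, hill_params, seed).
    """
    anchors = np.atleast_2d(np.asarray(anchor_set, dtype=float))
    if anchors.shape[1] != start.probe_cf3.size:
        raise MetadError("anchor dimensionality does not match the ligand")
    centroid = anchors.mean(axis=0)
    if bias is None:
        bias = BiasState(cv_definition=anchors.copy())
    kBT = config.temperature
    dt = config.timestep
    interval = hill_params.deposition_interval
    # chain-rule factor: d(com)/d(bead) = 1/2 for a two-bead ligand, 1 for a point
    bead_factor = 1.0 if start.bond_length == 0.0 else 0.5

    def hook(step: int, c: np.ndarray, o: np.ndarray):
        com = c if bead_factor == 1.0 else 0.5 * (c + o)
        delta = com - centroid
        cv = math.sqrt(float(delta @ delta))
        if step % interval == 0:
            deposit_hill(bias, cv, hill_params, step * dt, kBT=kBT)
        if cv == 0.0:
            return np.zeros_like(c), np.zeros_like(o)
        dvdcv = bias_gradient(bias, cv)
        f = (-dvdcv * bead_factor / cv) * delta
        return f, f

    traj = run_langevin(U, config, start, seed, force_hook=hook)
    return traj, bias
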