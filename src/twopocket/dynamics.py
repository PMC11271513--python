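"""Overdamped Langevin dynamics of the rigid two-probe ligand.

Euler–Maruyama integration with a rigid-bond projection applied every
step (the single-constraint analogue of SHAKE: probe separation is
rescaled about the midpoint, so bond drift is zero to round-off).  A
ligand with bond length 0 is integrated as a single point particle.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np

from .landscape import Ligand, as_two_bead_potential


class IntegrationError(RuntimeError):
    """Raised when coordinates become non-finite; carries the step index."""

    def __init__(self, step: int):
        super().__init__(f"non-finite coordinates at step {step}")
        self.step = step


@dataclass(frozen=True)
class LangevinConfig:
    """Integrator settings (reduced units: energy kBT, time arbitrary).

    ``temperature`` is in kBT units (1.0 = thermal), ``friction`` is the
    drag coefficient per bead, so the per-bead diffusion constant is
    temperature/friction.
    """

    temperature: float = 1.0
    friction: float = 0.5
    timestep: float = 0.02
    n_steps: int = 10_000
    save_stride: int = 10

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered ligand states in the fixed receptor frame."""

    times: np.ndarray          # (n,)
    cf3: np.ndarray            # (n, d)
    o1: np.ndarray             # (n, d)
    bond_length: float
    seed: int
    config_hash: str

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Ligand:
        return Ligand(self.cf3[i], self.o1[i], self.bond_length)

    def com(self) -> np.ndarray:
        return 0.5 * (self.cf3 + self.o1)


def config_fingerprint(config: LangevinConfig, extra: Optional[dict] = None) -> str:
    payload = {"config": asdict(config), "extra": extra or {}}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _project_bond(c: np.ndarray, o: np.ndarray, bond: float) -> tuple[np.ndarray, np.ndarray]:
    mid = 0.5 * (c + o)
    d = c - o
    norm = math.sqrt(float(d @ d))
    if norm == 0.0:
        # degenerate overlap: restore along the first axis
        d = np.zeros_like(c)
        d[0] = 1.0
        norm = 1.0
    half = (0.5 * bond / norm) * d
    return mid + half, mid - half


def run_langevin(
    U,
    config: LangevinConfig,
    start: Ligand,
    seed: int,
    force_hook: Optional[Callable] = None,
) -> Trajectory:
    """Integrate the ligand in potential ``U``.

    ``U`` may be a :class:`~twopocket.landscape.TwoPocketPotential`, any
    object with ``ligand_gradient``, or a plain scalar potential (wrapped
    per bead).  ``force_hook(step, cf3, o1) -> (f_cf3, f_o1)`` adds an
    extra force each step (used by the metadynamics driver).  Fixed
    (config, seed) pairs give bit-identical trajectories.
    """
    pot = as_two_bead_potential(U)
    dt = config.timestep
    mob = dt / config.friction
    sigma = math.sqrt(2.0 * config.temperature * dt / config.friction)
    point_mode = start.bond_length == 0.0

    c = np.array(start.probe_cf3, dtype=float)
    o = np.array(start.probe_o1, dtype=float)
    dim = c.size

    n_saved = config.n_steps // config.save_stride + 1
    times = np.empty(n_saved)
    cf3_out = np.empty((n_saved, dim))
    o1_out = np.empty((n_saved, dim))
    times[0] = 0.0
    cf3_out[0] = c
    o1_out[0] = o

    rng = np.random.default_rng(seed)
    save_i = 1
    chunk = 65536
    step = 0
    while step < config.n_steps:
        block = min(chunk, config.n_steps - step)
        if point_mode:
            noise = rng.standard_normal((block, dim)) if sigma > 0 else None
        else:
            noise = rng.standard_normal((block, 2, dim)) if sigma > 0 else None
        for j in range(block):
            if point_mode:
                g = pot.point_gradient(c)
                if force_hook is not None:
                    fc, _ = force_hook(step, c, o)
                    g = g - fc
                c = c - mob * g
                if sigma > 0:
                    c = c + sigma * noise[j]
                o = c
            else:
                g_c, g_o = pot.ligand_gradient(c, o)
                if force_hook is not None:
                    fc, fo = force_hook(step, c, o)
                    g_c = g_c - fc
                    g_o = g_o - fo
                c = c - mob * g_c
                o = o - mob * g_o
                if sigma > 0:
                    c = c + sigma * noise[j, 0]
                    o = o + sigma * noise[j, 1]
                c, o = _project_bond(c, o, start.bond_length)
            step += 1
            if step % config.save_stride == 0:
                if not (np.all(np.isfinite(c)) and np.all(np.isfinite(o))):
                    raise IntegrationError(step)
                times[save_i] = step * dt
                cf3_out[save_i] = c
                o1_out[save_i] = o
                save_i += 1

    return Trajectory(
        times=times[:save_i],
        cf3=cf3_out[:save_i],
        o1=o1_out[:save_i],
        bond_length=start.bond_length,
        seed=seed,
        config_hash=config_fingerprint(config),
    )
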