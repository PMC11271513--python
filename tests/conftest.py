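"""Shared fixtures.

The expensive simulation ensembles (1-D double-well metadynamics, the
20-seed WT/M124V gate ensembles, and the default pipeline run) are
session-scoped so the several tests that consume them pay for them once.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

import twopocket as tp
from twopocket import analysis as ta
from twopocket.landscape import Ligand, PointField
from twopocket.metad import estimate_free_energy


# ---------------------------------------------------------------------------
# 1-D tilted double well: the oracle-validated metadynamics benchmark
# ---------------------------------------------------------------------------

DW_A, DW_B = 3.0, 1.0          # quartic stiffness and tilt
DW_ANCHOR = -8.0               # CV anchor; cv = x + 8 on the support
DW_BIAS_FACTOR = 8.0
# CV windows around the two basins (wells near x = ±1, i.e. cv near 7 / 9)
DW_WIN_LEFT = (6.2, 7.6)
DW_WIN_RIGHT = (8.4, 9.8)


def dw_potential() -> PointField:
    def u(x):
        xx = float(x[0])
        return DW_A * (xx * xx - 1.0) ** 2 + DW_B * xx

    def grad(x):
        xx = float(x[0])
        return np.array([4.0 * DW_A * xx * (xx * xx - 1.0) + DW_B])

    return PointField(u, grad=grad)


@pytest.fixture(scope="session")
def dw_delta_f_true() -> float:
    """Quadrature oracle: F(right basin) − F(left basin) in kBT."""
    xs = np.linspace(-0.5, 0.5, 2001)
    barrier = xs[np.argmax(DW_A * (xs * xs - 1) ** 2 + DW_B * xs)]

    def boltz(x):
        return math.exp(-(DW_A * (x * x - 1) ** 2 + DW_B * x))

    z_left = quad(boltz, -3.0, barrier)[0]
    z_right = quad(boltz, barrier, 3.0)[0]
    return -math.log(z_right / z_left)


def dw_metad_delta_f(seed: int, n_steps: int) -> float:
    """Well-tempered metadynamics estimate of the double-well ΔF."""
    pot = dw_potential()
    conf = tp.LangevinConfig(
        temperature=1.0, friction=1.0, timestep=0.003,
        n_steps=n_steps, save_stride=200,
    )
    hp = tp.HillParams(
        initial_height=0.3, width=0.2, deposition_interval=200,
        tempered=True, bias_factor=DW_BIAS_FACTOR,
    )
    start = Ligand(np.array([-1.0]), np.array([-1.0]), 0.0)
    _, bias = tp.run_metad(pot, conf, hp, np.array([[DW_ANCHOR]]), start, seed=seed)
    prof = estimate_free_energy(
        bias, np.linspace(5.0, 11.0, 601), tempered=True, bias_factor=DW_BIAS_FACTOR
    )
    return prof.delta_f(DW_WIN_LEFT, DW_WIN_RIGHT)


@pytest.fixture(scope="session")
def dw_errors_long(dw_delta_f_true) -> list[float]:
    return [dw_metad_delta_f(s, 120_000) - dw_delta_f_true for s in range(10)]


@pytest.fixture(scope="session")
def dw_errors_short(dw_delta_f_true) -> list[float]:
    return [dw_metad_delta_f(s, 30_000) - dw_delta_f_true for s in range(10)]


# ---------------------------------------------------------------------------
# matched-seed WT / M124V metadynamics ensembles (20 runs each)
# ---------------------------------------------------------------------------

GATE_SEEDS = list(range(1, 21))


def _genotype_ensemble(genotype: str) -> dict:
    spec = tp.LandscapeSpec(genotype=genotype)
    pot = tp.build_landscape(spec)
    sim = tp.PipelineConfig().simulation
    hp_cfg = tp.PipelineConfig().metad
    conf = tp.LangevinConfig(
        temperature=sim.temperature, friction=sim.friction,
        timestep=sim.timestep, n_steps=sim.n_steps, save_stride=sim.save_stride,
    )
    hp = tp.HillParams(
        initial_height=hp_cfg.initial_height, width=hp_cfg.width,
        deposition_interval=hp_cfg.deposition_interval,
        tempered=hp_cfg.tempered, bias_factor=hp_cfg.bias_factor,
    )
    start = pot.bound_pose("deep")
    ref = pot.bound_pose("deep")
    met = np.asarray(spec.met_anchor)
    events, d_cf3_all, d_o1_all = [], [], []
    for seed in GATE_SEEDS:
        traj, _ = tp.run_metad(pot, conf, hp, pot.binding_site_anchors, start, seed)
        events.append(ta.detect_dissociation(ta.ligand_rmsd(traj, ref)))
        dc, do = ta.pair_distances(traj, met)
        d_cf3_all.append(dc)
        d_o1_all.append(do)
    labels = ta.classify_gates(np.concatenate(d_cf3_all), np.concatenate(d_o1_all))
    stats = ta.gate_occupancy_stats(labels)
    return {"events": events, "stats": stats}


@pytest.fixture(scope="session")
def gate_ensembles() -> dict:
    return {g: _genotype_ensemble(g) for g in ("WT", "M124V")}


# ---------------------------------------------------------------------------
# default pipeline run
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pipeline_bundle() -> dict:
    return tp.run_pipeline(tp.PipelineConfig(seed=1))


@pytest.fixture()
def small_config() -> tp.PipelineConfig:
    """Cheap configuration for determinism / I-O round-trip checks."""
    return tp.PipelineConfig(
        seed=7,
        simulation={"n_runs": 2, "n_steps": 3000, "save_stride": 20},
        analysis={"snapshot_stride": 5},
    )
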