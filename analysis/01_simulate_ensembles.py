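#!/usr/bin/env python
"""Simulate the matched-seed metadynamics ensembles.

Runs 10 well-tempered metadynamics trajectories per system — wild-type,
the Val-gatekeeper mutant, and the reference ligand that cannot use the
Met pocket (met well removed) — from the deep-pocket pose, and writes
trajectories and hill lists under results/simulations/.

Usage: python analysis/01_simulate_ensembles.py [--seed 1]
"""

import argparse
import time
from pathlib import Path

import twopocket as tp
from twopocket import tpio
from twopocket.config import substream_seeds
from twopocket.pipeline import run_ensemble

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/simulations"))
args = parser.parse_args()

config = tp.PipelineConfig(seed=args.seed)
run_seeds = substream_seeds(config.seed, config.simulation.n_runs, "metad")

systems = {
    "WT": config.wt_landscape,
    "M124V": config.mutant_landscape,
    "ligandB_nomet": config.wt_landscape.model_copy(
        update={"genotype": "M124V", "mutant_met_scale": 0.0}
    ),
}

for name, spec in systems.items():
    t0 = time.perf_counter()
    pot = tp.build_landscape(spec)
    trajs, biases = run_ensemble(pot, config, run_seeds)
    outdir = args.out / name
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (traj, bias) in enumerate(zip(trajs, biases)):
        tpio.write_trajectory(traj, outdir / f"run_{i:02d}.csv")
        tpio.write_hills(bias, outdir / f"hills_{i:02d}.csv")
    print(
        f"{name}: {len(trajs)} runs x {trajs[0].n_frames} frames, "
        f"{sum(b.n_hills for b in biases)} hills total "
        f"({time.perf_counter() - t0:.1f}s) -> {outdir}"
    )

print(f"done; seed {args.seed}, matched run seeds shared across systems")
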