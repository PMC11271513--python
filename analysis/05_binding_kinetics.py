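#!/usr/bin/env python
"""Pharmacology stage: assay fits, insurmountability, PK-PD occupancy.

Generates the three synthetic assay datasets (washout recovery, IV-bolus
plasma decay, concentration–response), fits each with the matching
model, simulates the functional-reversibility protocol for the
pseudoirreversible and surmountable presets, and integrates the
residence-time occupancy model at matched pharmacokinetics.

Usage: python analysis/05_binding_kinetics.py [--seed 1]
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

import twopocket as tp
from twopocket import kinetics, tpio
from twopocket.config import substream_seeds

LN2 = math.log(2.0)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/kinetics"))
args = parser.parse_args()

config = tp.PipelineConfig(seed=args.seed)
kin = config.kinetics
seeds = substream_seeds(config.seed, 3, "assays")
args.out.mkdir(parents=True, exist_ok=True)

# --- assay fits ------------------------------------------------------------
washout = tp.generate_washout_dataset(
    kin.washout_t_half, kin.washout_times, noise_sd=kin.washout_noise_sd, seed=seeds[0]
)
pk = tp.generate_pk_dataset(
    kin.pk_c0, kin.pk_t_half, kin.pk_times, noise_sd=kin.pk_noise_sd,
    seed=seeds[1], multiplicative_noise=True,
)
dr = tp.generate_dose_response(
    kin.ic50, kin.hill, 100.0, 0.0, kin.dr_concs, noise_sd=kin.dr_noise_sd, seed=seeds[2]
)
for name, ds in (("washout", washout), ("pk", pk), ("dose_response", dr)):
    tpio.write_assay(ds, args.out / f"assay_{name}.csv")

fit_w = kinetics.fit_one_phase_decay(washout.x, washout.y)
fit_p = kinetics.fit_log_linear_pk(pk.x, pk.y)
fit_d = kinetics.fit_4pl(dr.x, dr.y)
print(f"washout complex t1/2: fitted {fit_w.t_half:.2f} h (generated {kin.washout_t_half})")
print(f"plasma terminal t1/2: fitted {fit_p.t_half:.2f} h (generated {kin.pk_t_half})")
print(f"IC50:                 fitted {fit_d.ic50:.2f} nM (generated {kin.ic50})")

# --- functional reversibility ----------------------------------------------
pseudo = kinetics.emax_vs_pretreatment(kinetics.KSI_LIKE, kin.pretreat_grid)
surm = kinetics.emax_vs_pretreatment(kinetics.W146_LIKE, kin.pretreat_grid, readout_time=6.0)
emax_df = pd.DataFrame(
    {
        "pretreat_conc_nM": list(kin.pretreat_grid),
        "emax_pseudoirreversible": [r["emax"] for r in pseudo],
        "emax_surmountable": [r["emax"] for r in surm],
    }
)
emax_df.to_csv(args.out / "emax_vs_pretreatment.csv", index=False)
print("\nEmax vs pretreatment (% of control):")
print(emax_df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

# --- residence-time PK-PD ---------------------------------------------------
pk_params = {"c0": kin.pkpd_c0, "kel": LN2 / kin.pk_t_half}
tc_slow = kinetics.simulate_receptor_occupancy_pk(
    pk_params, kin.pkpd_kon, LN2 / kin.slow_t_half, kin.pkpd_duration
)
tc_fast = kinetics.simulate_receptor_occupancy_pk(
    pk_params, kin.pkpd_kon, LN2 / kin.fast_t_half, kin.pkpd_duration
)
pd.DataFrame(
    {
        "time_h": tc_slow.times,
        "plasma_nM": tc_slow.plasma_conc,
        "occupancy_slow": tc_slow.occupancy,
        "occupancy_fast": tc_fast.occupancy,
    }
).to_csv(args.out / "occupancy_timecourses.csv", index=False)

occ32_slow = float(np.interp(32.0, tc_slow.times, tc_slow.occupancy))
occ32_fast = float(np.interp(32.0, tc_fast.times, tc_fast.occupancy))
report = {
    "washout_t_half_fit_h": fit_w.t_half,
    "pk_t_half_fit_h": fit_p.t_half,
    "ic50_fit_nM": fit_d.ic50,
    "occupancy_at_32h": {"slow_9.41h": occ32_slow, "fast_0.98h": occ32_fast},
    "occupancy_terminal_t_half_h": {
        "slow": kinetics.occupancy_terminal_half_life(tc_slow),
        "fast": kinetics.occupancy_terminal_half_life(tc_fast),
    },
}
(args.out / "summary.json").write_text(json.dumps(report, indent=1))
print(
    f"\noccupancy at 32 h: {occ32_slow:.2f} (t1/2 diss {kin.slow_t_half} h) vs "
    f"{occ32_fast:.2f} (t1/2 diss {kin.fast_t_half} h) at matched PK — "
    "slow dissociation sustains target engagement after exposure has fallen"
)
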