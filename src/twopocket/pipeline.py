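"""End-to-end pipeline: simulate → analyze → fingerprint → kinetics.

Runs a WT-vs-M124V comparison at toy scale: matched-seed metadynamics
ensembles on the two landscapes, dissociation counting, gate occupancy,
a comparative fingerprint of a Met-pocket-using ligand against one that
cannot use the Met pocket, a free-energy profile, and the pharmacology
stage (assay fits, insurmountability, PK-PD occupancy).  Everything is
reproducible from (config, seed).
"""

from __future__ import annotations

import logging
import time
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis as ta
from . import assays, fingerprint, kinetics
from .config import PipelineConfig, substream_seeds
from .dynamics import LangevinConfig, Trajectory
from .landscape import LandscapeSpec, TwoPocketPotential, build_landscape
from .metad import BiasState, HillParams, estimate_free_energy, run_metad

log = logging.getLogger("twopocket.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def residue_anchors(spec: LandscapeSpec) -> dict[str, tuple[float, float]]:
    """Toy residue anchor points: a handful of deep-pocket residues, the
    gatekeeper (Met analogue), and one exit-path residue."""
    d = np.asarray(spec.deep_pocket_center)
    m = np.asarray(spec.met_anchor)
    return {
        "ARG120": tuple(d + (-1.5, 1.5)),
        "GLU121": tuple(d + (1.5, -1.5)),
        "TRP269": tuple(d + (-2.0, -1.0)),
        "PHE125": tuple(d + (2.0, 1.0)),
        "MET124": tuple(m),
    }


def run_ensemble(
    potential: TwoPocketPotential,
    config: PipelineConfig,
    run_seeds: Sequence[int],
) -> tuple[list[Trajectory], list[BiasState]]:
    """Matched-seed metadynamics ensemble started from the deep-pocket pose."""
    sim = config.simulation
    lconf = LangevinConfig(
        temperature=sim.temperature,
        friction=sim.friction,
        timestep=sim.timestep,
        n_steps=sim.n_steps,
        save_stride=sim.save_stride,
    )
    hp = HillParams(
        initial_height=config.metad.initial_height,
        width=config.metad.width,
        deposition_interval=config.metad.deposition_interval,
        tempered=config.metad.tempered,
        bias_factor=config.metad.bias_factor,
    )
    anchors = potential.binding_site_anchors
    start = potential.bound_pose("deep")
    trajs, biases = [], []
    for seed in run_seeds:
        traj, bias = run_metad(potential, lconf, hp, anchors, start, seed)
        trajs.append(traj)
        biases.append(bias)
    return trajs, biases


def analyze_ensemble(
    trajs: Sequence[Trajectory],
    potential: TwoPocketPotential,
    config: PipelineConfig,
) -> dict:
    """RMSD/dissociation, gate classification and occupancy for one genotype."""
    ana = config.analysis
    crit = ta.DissociationCriterion(
        threshold=ana.dissociation_threshold, persistence=ana.dissociation_persistence
    )
    ref = potential.bound_pose("deep")
    events = [ta.detect_dissociation(ta.ligand_rmsd(t, ref), crit) for t in trajs]
    kn = ta.count_dissociations(events)

    met = np.asarray(potential.spec.met_anchor)
    all_cf3, all_o1, all_t = [], [], []
    for t in trajs:
        snap = ta.subsample_snapshots(t, ana.snapshot_stride)
        d_cf3, d_o1 = ta.pair_distances(snap, met)
        all_cf3.append(d_cf3)
        all_o1.append(d_o1)
        all_t.append(snap.times)
    labels = ta.classify_gates(
        np.concatenate(all_cf3), np.concatenate(all_o1), times=np.concatenate(all_t)
    )
    stats = ta.gate_occupancy_stats(labels)
    return {
        "events": events,
        "k_of_n": kn,
        "labels": labels,
        "gate_stats": stats,
    }


def _kinetics_stage(config: PipelineConfig) -> tuple[dict, dict]:
    kin = config.kinetics
    seeds = substream_seeds(config.seed, 3, "assays")
    washout = assays.generate_washout_dataset(
        kin.washout_t_half, kin.washout_times, noise_sd=kin.washout_noise_sd,
        seed=seeds[0],
    )
    pk = assays.generate_pk_dataset(
        kin.pk_c0, kin.pk_t_half, kin.pk_times, noise_sd=kin.pk_noise_sd,
        seed=seeds[1], multiplicative_noise=True,
    )
    dr = assays.generate_dose_response(
        kin.ic50, kin.hill, 100.0, 0.0, kin.dr_concs, noise_sd=kin.dr_noise_sd,
        seed=seeds[2],
    )
    fit_washout = kinetics.fit_one_phase_decay(washout.x, washout.y)
    fit_pk = kinetics.fit_log_linear_pk(pk.x, pk.y)
    fit_dr = kinetics.fit_4pl(dr.x, dr.y)

    emax_pseudo = kinetics.emax_vs_pretreatment(kinetics.KSI_LIKE, kin.pretreat_grid)
    emax_surm = kinetics.emax_vs_pretreatment(kinetics.W146_LIKE, kin.pretreat_grid)

    pk_params = {"c0": kin.pkpd_c0, "kel": assays.LN2 / kin.pk_t_half}
    tc_slow = kinetics.simulate_receptor_occupancy_pk(
        pk_params, kin.pkpd_kon, assays.LN2 / kin.slow_t_half, kin.pkpd_duration
    )
    tc_fast = kinetics.simulate_receptor_occupancy_pk(
        pk_params, kin.pkpd_kon, assays.LN2 / kin.fast_t_half, kin.pkpd_duration
    )

    def occ_at(tc, t):
        return float(np.interp(t, tc.times, tc.occupancy))

    summary = {
        "washout_t_half_fit": fit_washout.t_half,
        "washout_t_half_true": kin.washout_t_half,
        "pk_t_half_fit": fit_pk.t_half,
        "pk_t_half_true": kin.pk_t_half,
        "ic50_fit": fit_dr.ic50,
        "ic50_true": kin.ic50,
        "emax_pseudoirreversible": [e["emax"] for e in emax_pseudo],
        "emax_surmountable": [e["emax"] for e in emax_surm],
        "pretreat_grid": list(kin.pretreat_grid),
        "occupancy_at_32h_slow": occ_at(tc_slow, 32.0),
        "occupancy_at_32h_fast": occ_at(tc_fast, 32.0),
        "half_persistence_slow_h": kinetics.half_persistence_time(tc_slow),
        "half_persistence_fast_h": kinetics.half_persistence_time(tc_fast),
        "occupancy_terminal_t_half_slow_h": kinetics.occupancy_terminal_half_life(tc_slow),
        "occupancy_terminal_t_half_fast_h": kinetics.occupancy_terminal_half_life(tc_fast),
    }
    tables = {
        "assay_washout": pd.DataFrame({"x": washout.x, "y": washout.y}),
        "assay_pk": pd.DataFrame({"x": pk.x, "y": pk.y}),
        "assay_dose_response": pd.DataFrame({"x": dr.x, "y": dr.y}),
        "emax_vs_pretreatment": pd.DataFrame(
            {
                "pretreat_conc": list(kin.pretreat_grid),
                "emax_pseudoirreversible": [e["emax"] for e in emax_pseudo],
                "emax_surmountable": [e["emax"] for e in emax_surm],
            }
        ),
        "occupancy_timecourses": pd.DataFrame(
            {
                "time": tc_slow.times,
                "conc": tc_slow.plasma_conc,
                "occupancy_slow": tc_slow.occupancy,
                "occupancy_fast": tc_fast.occupancy,
            }
        ),
    }
    return summary, tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle (summary + tables)."""
    if config.simulation.n_runs < 1:
        raise PipelineError("validate", ValueError("n_runs must be >= 1"))
    summary: dict = {"seed": config.seed}
    tables: dict[str, pd.DataFrame] = {}
    run_seeds = substream_seeds(config.seed, config.simulation.n_runs, "metad")

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        wt_pot = build_landscape(config.wt_landscape)
        mut_pot = build_landscape(config.mutant_landscape)
        ensembles = {}
        for name, pot in (("WT", wt_pot), ("M124V", mut_pot)):
            ensembles[name] = run_ensemble(pot, config, run_seeds)
        log.info("stage %s done in %.1fs (seed %d)", stage, time.perf_counter() - t0, config.seed)

        stage = "analyze"
        t0 = time.perf_counter()
        gate_freq = {}
        for name, pot in (("WT", wt_pot), ("M124V", mut_pot)):
            res = analyze_ensemble(ensembles[name][0], pot, config)
            gate_freq[name] = res["gate_stats"]["frequencies"]
            summary[f"dissociation_{name}"] = res["k_of_n"]
            summary[f"gate_frequencies_{name}"] = res["gate_stats"]["frequencies"]
            summary[f"gate_medians_{name}"] = res["gate_stats"]["medians"]
            lab = res["labels"]
            tables[f"labels_{name}"] = pd.DataFrame(
                {
                    "time": lab.times,
                    "d_cf3": lab.d_cf3,
                    "d_o1": lab.d_o1,
                    "label": lab.labels.astype(str),
                }
            )
        summary["gateB_wt_minus_mutant"] = (
            gate_freq["WT"][ta.GATE_B] - gate_freq["M124V"][ta.GATE_B]
        )
        # free-energy profile from the first WT run's accumulated bias
        grid = np.linspace(0.0, config.wt_landscape.bulk_radius + 5.0, 351)
        prof = estimate_free_energy(
            ensembles["WT"][1][0], grid,
            tempered=config.metad.tempered, bias_factor=config.metad.bias_factor,
            kBT=config.simulation.temperature,
        )
        tables["free_energy_WT_run0"] = pd.DataFrame({"cv": prof.grid, "f": prof.f})
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "fingerprint"
        t0 = time.perf_counter()
        # ligand B: identical ligand on a landscape whose Met well is removed
        nomet_spec = config.wt_landscape.model_copy(
            update={"genotype": "M124V", "mutant_met_scale": 0.0}
        )
        nomet_pot = build_landscape(nomet_spec)
        trajs_b, _ = run_ensemble(nomet_pot, config, run_seeds)
        anchors = residue_anchors(config.wt_landscape)
        cutoff = config.analysis.contact_cutoff
        stride = config.analysis.snapshot_stride
        snaps_a = [ta.subsample_snapshots(t, stride) for t in ensembles["WT"][0]]
        snaps_b = [ta.subsample_snapshots(t, stride) for t in trajs_b]
        fp_a = fingerprint.fingerprint_trajectory(snaps_a, anchors, "ligand_A", cutoff)
        fp_b = fingerprint.fingerprint_trajectory(snaps_b, anchors, "ligand_B", cutoff)
        qb = fingerprint.qb_score(
            fingerprint.tally_bits(fp_a), fingerprint.tally_bits(fp_b)
        )
        ranking = fingerprint.rank_residues(qb)
        summary["qb_ranking"] = ranking
        summary["qb_top_residue"] = ranking[0][0]
        tables["qb_table"] = pd.DataFrame(
            {
                "residue": [rb.residue for rb in qb.residue_bits],
                "type": [rb.interaction for rb in qb.residue_bits],
                "p_A": qb.p_a,
                "p_B": qb.p_b,
                "Pb": qb.pb,
                "Qb": qb.qb,
            }
        ).sort_values("Qb", ascending=False, kind="mergesort")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "kinetics"
        t0 = time.perf_counter()
        kin_summary, kin_tables = _kinetics_stage(config)
        summary["kinetics"] = kin_summary
        tables.update(kin_tables)
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineError(stage, exc) from exc

    return {"seed": config.seed, "summary": summary, "tables": tables}
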