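# twopocket

Desk-scale models of how a metastable secondary binding pocket turns a
receptor antagonist into a *pseudoirreversible* one — and what that slow
dissociation buys pharmacologically.

The motivating system is a GPCR antagonist that pauses, on its way out
of the orthosteric "deep" pocket, in a shallower "Met pocket" beside a
methionine gatekeeper residue.  Mutating the gatekeeper to valine
removes the pause, speeds dissociation, and abolishes insurmountable
antagonism.  `twopocket` packages that whole story as testable,
seed-reproducible computation:

* **`landscape` / `dynamics`** — a coarse-grained two-pocket energy
  landscape (rigid two-probe ligand: a CF3-like and a carboxylate-O1
  probe, in a funnel-confined 2-D receptor frame) with overdamped
  Langevin dynamics.  Units: kBT and Å-like lengths.
* **`metad`** — well-tempered (or standard) Gaussian-hill metadynamics
  on the ligand–binding-site distance, with free-energy reconstruction
  F(s) = −γ/(γ−1)·V_bias(s).
* **`analysis`** — ligand RMSD, the RMSD > 30 dissociation rule with
  k-of-n counting, gate-A/gate-B pose classification in the
  (CF3–gatekeeper, O1–gatekeeper) distance plane, occupancy medians,
  and k-medoids pose clustering.
* **`fingerprint`** — per-snapshot residue contact bits and the
  comparative statistic **Qb = (Cb/C0)·2(Pb − ½)** with
  Pb = pA/(pA+pB), ranking residues by differential contact between two
  ligands.
* **`kinetics`** — one-phase-decay dissociation half-life fitting,
  log-linear terminal-phase PK, 4PL IC50 fitting, a two-step induced-fit
  ODE model of insurmountable antagonism (R + I ⇌ R·I ⇌ R·I*, solved by
  matrix exponential), and a residence-time PK-PD occupancy model
  dOcc/dt = kon·C(t)(1−Occ) − koff·Occ.
* **`config` / `pipeline` / `tpio`** — strict YAML configuration, the
  end-to-end WT-vs-mutant pipeline, and lossless CSV/JSON artifact I/O.

The scientific claims are directional and are tested as such: the
wild-type landscape populates the Met-pocket gate far more than the
mutant and unbinds later under matched noise; a tight-binding
isomerized state makes Emax fall with antagonist pretreatment while a
surmountable antagonist recovers fully; and occupancy outlasts plasma
exposure exactly when the dissociation half-life (9.41 h) exceeds the
pharmacokinetic half-life (6.65 h).  See `docs/methods.md` for the
model details and their limits.

## Worked example

The numbered scripts under `analysis/` run the study end to end and
write their tables under `results/`:

```bash
python analysis/01_simulate_ensembles.py --seed 1   # 3 ensembles x 10 metadynamics runs
python analysis/02_free_energy_profiles.py
python analysis/03_gate_and_dissociation.py
python analysis/04_fingerprint_comparison.py
python analysis/05_binding_kinetics.py --seed 1
```

With seed 1 this prints (abridged):

```
WT: dissociated 3/10 runs; gate A 0.236, gate B 0.197
M124V: dissociated 4/10 runs; gate A 0.260, gate B 0.029
gate-B frequency difference (WT - M124V): +0.168

residue            type   p_A   p_B    Pb     Qb
 MET124 surface_contact 0.545 0.484 0.529  0.032
 TRP269 surface_contact 0.542 0.575 0.485 -0.016
 ...
top-ranked residue: MET124 (Qb = 0.032)

washout complex t1/2: fitted 8.50 h (generated 9.41)
plasma terminal t1/2: fitted 6.56 h (generated 6.65)
IC50:                 fitted 5.87 nM (generated 6.4)

 pretreat_conc_nM  emax_pseudoirreversible  emax_surmountable
              1.0                     99.1              100.0
             30.0                     76.2              100.0
           1000.0                     15.0              100.0

occupancy at 32 h: 0.49 (t1/2 diss 9.41 h) vs 0.06 (t1/2 diss 0.98 h)
```

Reading it: the wild-type ligand both lingers in the Met-pocket gate
(0.197 vs 0.029 of snapshots) and dissociates in fewer runs (3/10 vs
4/10) than the gatekeeper mutant; the gatekeeper analogue is the
largest differential contact between a ligand that can use the Met
pocket and one that cannot; the kinetic fitters recover the generating
half-lives from noisy synthetic assays; Emax collapses with
pretreatment only for the preset that has a tight isomerized state; and
at matched pharmacokinetics only the slow-dissociating compound still
occupies half its receptors 32 h after dosing.

A single call does all of this in memory and returns one bundle:

```python
import twopocket as tp
bundle = tp.run_pipeline(tp.PipelineConfig(seed=1))
tp.write_results(bundle, "results/pipeline")
```

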