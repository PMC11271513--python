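# Methods

## The model system

`twopocket` studies, at desk scale, how a metastable secondary binding
pocket shapes antagonist unbinding and downstream pharmacology.  The
motivating system is a GPCR antagonist whose slow, pseudoirreversible
dissociation depends on a methionine gatekeeper residue: on its way out
of the orthosteric ("deep") pocket the ligand pauses in a shallower
"Met pocket" beside the gatekeeper, and mutating the gatekeeper to
valine removes the pause.  The package contains a coarse-grained
simulator of that landscape, the analysis chain used on unbinding
trajectories (metadynamics free-energy reconstruction, RMSD dissociation
counting, gate classification, pose clustering, interaction-fingerprint
comparison), and the pharmacology models that connect slow dissociation
to insurmountable antagonism and persistent in-vivo occupancy.

## Reduced units

Energies are in kBT and lengths in Å-like units, so the 30-unit
dissociation threshold mirrors a 30 Å RMSD cutoff and the printed
gate-window distances (2.5–7.8, 7.5–12.5, 10–15 units) read as
ångströms.  Time in the simulator is arbitrary (overdamped dynamics);
the pharmacology stage uses hours and nM throughout.

## The two-pocket landscape

The receptor is a fixed 2-D frame.  The ligand is a rigid pair of probe
beads, a CF3-like hydrophobic probe and a carboxylate-oxygen (O1) polar
probe, 7 units apart, so pocket-specific pose *orientation* is
resolvable.  Each pocket is a Gaussian well in the joint (CF3, O1)
coordinates centred on that pocket's bound pose:

* **Deep pocket** (depth 6 kBT, width 2; orientation width 6): pose A
  sites placed exactly at CF3–gatekeeper 9.42 and O1–gatekeeper 9.97
  units — the canonical docking-like geometry.
* **Met pocket** (depth 6 kBT wild-type, scaled by 0.1 for the
  Val-gatekeeper mutant; width 3): pose B sites at CF3–gatekeeper 6.27
  and O1–gatekeeper 12.95 units, i.e. the hydrophobic end turned toward
  the gatekeeper and the polar end pointing out of the cavity.

Dissociation is confined to an exit corridor by a funnel restraint
(soft harmonic side walls 4.5 units either side of the exit axis and a
cavity back wall 2.5 units behind the deep pocket), the toy analogue of
the egress channel between two helices through which these ligands
leave.  Without the funnel a 2-D ligand exits in arbitrary directions
and essentially never samples the Met pocket.  A radial wall at 42
units bounds the bulk; the potential is flat beyond 30 units (before
confinement).

The Met-pocket pose sits 10° off the exit axis, close enough to the
corridor that a dissociating ligand must pass through the well's basin
of attraction.  With these defaults, matched-noise metadynamics
ensembles show both qualitative signatures of the gatekeeper mechanism:
the wild-type ligand dwells in the Met-pocket gate roughly five-fold
more than the mutant, and its first passage to the dissociated state is
systematically delayed.

A *point* view of the same landscape (Gaussian wells at the deep-pocket
center and the CF3 Met-pocket site) is exposed for 1-D cuts, Boltzmann
quadrature checks and the double-well benchmarks; the two-bead view
drives the ligand dynamics.

## Dynamics

Overdamped Langevin (Euler–Maruyama), timestep 0.02, friction 0.5 per
bead, kBT = 1.  The rigid bond is restored every step by rescaling the
probe separation about the midpoint (the single-constraint analogue of
SHAKE), so bond drift is zero to round-off.  All randomness flows from
`numpy` PCG64 generators; fixed (config, seed) pairs give bit-identical
trajectories, and the pipeline derives per-stage substreams from one
global seed so wild-type/mutant comparisons share noise.

## Metadynamics

The collective variable is the distance between the ligand probe
centroid and the centroid of the binding-site anchors (deep-pocket
center and gatekeeper site).  Anchoring the CV centroid *inside* the
cavity on the exit axis keeps the CV nearly monotone along the
dissociation corridor; with a centroid between the two pockets the
cavity's back corner aliases onto the forward corridor in CV value, and
hills deposited there block the exit — an instructive failure mode of
distance CVs that we avoid by construction.

Gaussian hills (initial height 0.3, width 0.75 CV units) are deposited
every 300 steps.  Well-tempered deposition (bias factor 10) is the
default; standard (non-tempered) deposition is available since a bare
"initial hill height" prescription does not pin down the variant.  The
free-energy profile is F = −V_bias (standard) or −γ/(γ−1)·V_bias
(well-tempered), shifted so min F = 0.

Ensemble defaults mirror the source protocol's shape: 10 independent
runs per system, 1001 saved frames per run, snapshots taken every 10th
frame (≈100 per run, ≈1000 per ensemble).  The 20 000-step budget is
sized so that the fast-dissociating system (no functional Met pocket)
unbinds in a majority of runs while the wild-type unbinds in a
minority — the regime in which a k-of-n dissociation count is
informative.

On a 1-D tilted quartic double well the reconstructed basin ΔF agrees
with numerical Boltzmann integration to a median |error| of ≈0.3 kBT
over 10 seeds (well within the 0.5 kBT acceptance bound), and the
median error shrinks when the run length is quadrupled.

## Trajectory analysis

* **RMSD** over the two probes in the fixed receptor frame (no
  superposition — the toy receptor is rigid), dissociation = first frame
  with RMSD > 30 (persistence 1 frame by default), k-of-n counting over
  runs.
* **Gate classification**: rectangular windows in the (CF3–gatekeeper,
  O1–gatekeeper) distance plane.  Defaults: gate A (deep pocket) CF3
  7.8–12.5, O1 7.5–12.5; gate B (Met pocket) CF3 2.5–7.8, O1 10–15;
  unbound when both distances exceed 25.  The orientation is chosen so
  the canonical pose medians (9.42, 9.97) and (6.27, 12.95) each fall in
  their own gate; published legends for such windows can carry swapped
  labels, so the windows are fully configurable.  Windows are closed on
  the lower bound, open on the upper; every snapshot receives exactly
  one of four labels.  Medians use the midpoint convention (average of
  the central pair for even counts).
* **Pose clustering**: PAM-style k-medoids on the pairwise frame-RMSD
  matrix with seeded initialization (k = 2 recovers the deep-pocket and
  Met-pocket groups).  Written in-package because no installed library
  provides k-medoids.

## Interaction fingerprints and Qb

Each snapshot is reduced to surface-contact bits over labelled residue
anchors: a bit is set when the nearer probe is within the contact
cutoff (7 units — generous because a bead stands in for a whole
substituent).  For ligand A (Met-pocket user) versus ligand B (Met well
removed), per-bit frequencies pA, pB give

    Pb = pA / (pA + pB)   (Pb = 1/2 when both are zero)
    Qb = pA · 2·(Pb − 1/2) = pA·(pA − pB)/(pA + pB)

Qb is bounded by [−1, 1]; the maximum 1 is attained (exclusive contact
by ligand A), while the attained minimum is 2√2 − 3 ≈ −0.17 — the
statistic is deliberately asymmetric, scoring ligand A against B.  It
is zero exactly when pA = 0 or pA = pB, and monotone in pA wherever
pA ≥ pB (for pA < (√2−1)·pB it dips slightly negative; that is the
analytic behaviour of the formula, not an artifact).  Residues are
ranked by Qb descending with lexicographic tie-breaks; in the toy
pipeline the gatekeeper analogue tops the ranking.

## Binding kinetics

**Fitters.**  One-phase decay y = plateau − span·e^(−kt) (complex
half-life ln2/k), initialized from a deterministic log-linear pre-fit;
terminal-phase PK by log-linear regression; 4PL concentration–response
initialized from data quartiles.  All three recover generating
parameters to < 1e−6 relative error on noiseless data, and their RMSE
shrinks with the noise level on seeded noisy replicates.  Constant or
flat inputs raise a degenerate-data error rather than returning a fit.

**Two-step induced-fit antagonism.**  Species R, R·A, R·I (encounter),
R·I* (tight), with mass-action rates and constant free-ligand
concentrations within a phase; each phase is a linear ODE solved exactly
with the matrix exponential, so receptor conservation holds to
round-off.  The functional-reversibility protocol is pretreat (1 h) →
wash (free inhibitor → 0) → agonist phase (2 h) → response = agonist-
occupied fraction as % of the inhibitor-free control at the same
agonist concentration; Emax is the fitted plateau over the agonist
grid (the high-dose level when the curve is flat).  Presets anchor the
measured quantities: the pseudoirreversible preset has encounter Kd 30
nM, isomerization ratio k2/k−2 = 4 (apparent Kd 6 nM) and apparent
complex half-life 9.41 h (k−1 = 0.368 h⁻¹, k1 = 0.0123 nM⁻¹h⁻¹, k2 =
2 h⁻¹, k−2 = 0.5 h⁻¹); the surmountable presets have no tight state
(k2 = 0) and complex half-lives 0.20 h and 0.98 h.  The model
reproduces the assay phenomenology in direction: Emax falls strictly
with pretreatment concentration only when a tight state exists.

**Residence-time PK-PD.**  dOcc/dt = kon·C(t)·(1−Occ) − koff·Occ with
C(t) = c0·e^(−kel·t), solved by an exponential integrator (exact for
frozen exposure per step; 2001 grid points over 48 h).  Defaults kon =
0.01 nM⁻¹h⁻¹, c0 = 100 nM, plasma half-life 6.65 h.  With dissociation
half-life 9.41 h occupancy decays at koff once exposure has fallen
(terminal occupancy half-life ≈ 9.4 h > plasma 6.65 h) and remains ≈0.5
at 32 h; with 0.98 h it tracks the plasma half-life and is nearly gone
at 32 h.  `persistence_metric` reports total time above an occupancy
threshold and is monotone in residence time.

## Synthetic assay generators

Washout recovery (one-phase decay toward 100 % of control, default
half-life 9.41 h sampled at 0–24 h, additive Gaussian noise sd 2 %),
IV-bolus PK (c0 1000, half-life 6.65 h, multiplicative log-normal noise
sd 0.02), and 4PL concentration–response (IC50 6.4 nM, Hill 1, noise
sd 2 %).  The generators record their true parameters and seed, so
fitters are always validated against ground truth.  What they do *not*
emulate: replicate structure, plate effects, heteroscedastic detection
noise, or absorption/distribution phases — so passing fits here
demonstrate estimator correctness, not robustness to real assay
pathology.

## What the toy does and does not show

The simulator reproduces *mechanistic directions*: a metastable
gatekeeper pocket produces dwell in a second bound pose, delays
unbinding, and creates a differential contact signature at the
gatekeeper; removing it reverses all three.  Absolute free energies,
rates and frequencies are artifacts of the toy scale (2-D, rigid
receptor, single distance CV, kBT units) and are not calibrated to the
all-atom system.  Statements that survive the reduction are the ones
tested: directional contrasts under matched noise, exact classification
of the canonical poses, oracle agreement of the free-energy estimator,
and exact parameter recovery in the pharmacology stage.

## Numerical choices and degenerate inputs

Euler–Maruyama steps are stable for the default curvatures (max |U″|·dt/γ
≈ 0.1); divergence raises an integration error naming the step.  The
bias sum is evaluated analytically over all hills (vectorized), so hill
lists round-trip bit-exactly through CSV (17 significant digits).
cv = 0 has zero bias force (gradient singularity removed).  Empty bias
gives a flat zero profile.  k-medoids re-seeds empty clusters on the
farthest point and accepts any valid partition when all frames are
identical.  Flat Emax curves return the high-dose plateau directly.
Zero hill height disables deposition and reduces metadynamics to plain
Langevin dynamics bit-for-bit.
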