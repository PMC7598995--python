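# Methods

This note documents the models, surrogates and numerical choices behind
`htsumd`: a desk-scale implementation of supervised-molecular-dynamics (SuMD)
fragment screening — binding-pathway sampling, pose clustering, consensus hit
ranking — together with the NMR screening calculus used to cross-validate such
screens.

## The supervised sampling loop

Fragment binding is sampled as a sequence of short dynamics segments
("steps"). During each step the distance between the fragment's mass-weighted
centroid and the binding-site center, `d_cm`, is recorded at a small number of
evenly spaced checkpoints (default 5). A tabu-like rule accepts the step iff
the least-squares slope of `d_cm` versus checkpoint index is below a threshold
(default 0, i.e. the fragment approached); otherwise the step is discarded and
re-simulated from the previous coordinates with a fresh noise stream. The
accepted steps concatenate into the binding trajectory. Once `d_cm` falls
below the supervision-off distance (default 5 Å) supervision is disabled and
plain dynamics continues to the step budget, sampling the bound state. A run
ends `bound` (the threshold was reached), `unbound` (the maximum number of
consecutive rejections, default 20, was hit) or `budget-exhausted`.

Design choices where the protocol itself leaves room:

* **Acceptance statistic.** A least-squares slope over the intra-step
  checkpoints rather than an endpoint comparison: it is robust to
  single-checkpoint noise and reduces to the same decision for monotone
  series. Strict `<` at the threshold.
* **Re-simulation reseeding.** A rejected step must not repeat its noise
  stream verbatim (it would be rejected forever); every attempt draws its
  seed deterministically from `(base seed, system seed, replica, step,
  attempt)` via `numpy.random.SeedSequence`, so whole screens are
  byte-reproducible.
* **Termination.** The consecutive-rejection cap is the explicit stop rule;
  runs that never reach the site within the step budget are reported as
  `budget-exhausted`, and accepted/attempted step counts are reported
  separately.
* **Step duration.** The nominal step length (300 ps) is bookkeeping for real
  MD adapters; the built-in toy backend maps one step to
  `checkpoints × substeps` integrator substeps (default 5 × 12).

## The toy Brownian backend

The built-in backend propagates the fragment's atoms by overdamped
(Euler–Maruyama) Langevin dynamics on the gradient of the interaction-energy
surrogate plus harmonic bonds; the receptor is rigid. Per substep each atom
moves by `drift · F + noise_sigma · η` with `η` standard normal, a per-atom
displacement clamp (0.5 Å) guarding the steep Lennard-Jones wall. Defaults
`drift = 0.06 Å²·mol/kcal`, `noise_sigma = 0.45 Å` give an effective
temperature `kT = noise_sigma²/(2·drift) ≈ 1.7 kcal/mol` — chosen so that
designed binders (well depth ≳ 10 kcal/mol) stay bound while weak decoys
(≈ 3–6 kcal/mol) exchange between sites, which is the kinetic contrast the
cluster analysis feeds on. Chain fragments carry 1–3 harmonic restraints
between heavy atoms (an angle-term proxy) so poses do not fold, while
hydroxyl hydrogens stay orientable for hydrogen bonding. The integrator core
is a numba kernel seeded per segment; identical `(coords, seed)` give
bit-identical output. Any object with `segment(coords, substeps, seed) ->
coords` can replace it, e.g. an adapter around a real MD engine.

## The interaction-energy surrogate

A published-tier end-point rescoring method (MM/GBSA) cannot be reproduced
from a text description, so scoring goes through an interface whose built-in
implementation is a documented surrogate; downstream analysis only consumes
*rankings*, which is what the surrogate is designed to preserve. It sums:

* screened Coulomb with distance-dependent dielectric ε(r) = 4r:
  `E = 332.0637·q_i·q_j/(4 r²)` kcal/mol;
* 12-6 Lennard-Jones with Lorentz–Berthelot combination over a per-element
  (σ, ε) table. Polar radii are deliberately compact (σ_O = 2.4 Å,
  σ_H = 1.2 Å, ε_H = 0.005) so that donor–acceptor contacts can reach the
  hydrogen-bond distance criterion, as polar hydrogens do in real force
  fields where their LJ radius is nearly zero;
* a nonpolar solvation reward `−γ·A`, with the contact area A proxied by
  12 Å² per apolar–apolar contact weighted by the same switch function as the
  HYD score, γ = 0.02 kcal/mol/Å².

All pair terms truncate at the electrostatic cutoff (default 9 Å). Receptor–
fragment pairs closer than 0.5 Å are steric clashes: the frame is flagged
(energy NaN) and excluded from cluster averages rather than scored.

## Geometric descriptors

* **Hydrogen bonds**: donor–acceptor heavy-atom distance < 3.0 Å and
  donor–H–acceptor angle at the hydrogen > 120° (strict inequalities; 180° =
  linear). Both directions are searched. Typing is rule-based: N/O with an
  attached H donate, N/O without accept. Per cluster, each (donor, acceptor)
  pair is reported with its occupancy, the percentage of member frames in
  which it is present, and the receptor residue label involved.
* **HYD score**: Σ over apolar–apolar (C, S; hydrogens excluded) receptor–
  fragment pairs of a linear switch S(r) = 1 for r ≤ 4.5 Å, falling to 0 at
  6.0 Å. Dimensionless, higher is better. The exact functional form of the
  original hydrophobic-contact script is not public; this switch-sum is a
  stand-in with the same monotone-contact semantics.

## Cluster analysis

Per replica: the n_f × n_f matrix of fragment-coordinate RMSDs is computed in
the receptor-fixed frame *without* rotational superposition — the pose
location is the signal that separates binding modes. DBSCAN
(scikit-learn, `metric="precomputed"`) clusters the frames with ε = 1.5 Å and
min_samples = 10 (the point itself counted; variants differ, so this is
stated). Border points reachable from two clusters go to the cluster formed
earliest (lowest-index core), making labels deterministic given frame order;
the test suite checks exact label equality against an explicit
neighbor-graph/BFS reference. Each cluster carries SIZE (count and % of the
parent trajectory), ΔG_best/ΔG_ave, HYD_best/HYD_ave, hydrogen-bond
occupancy records, and its best-energy representative frame (ties to the
lowest frame index).

## Consensus ranking

1. **Gate**: keep clusters with at least one hydrogen-bond record at
   occupancy ≥ 10 %.
2. **Ranks**: three independent orderings of the survivors — SIZE and HYD
   descending, mean interaction energy ascending — each truncated to the top
   decile, `k = max(1, round(0.10·n))` (rounding and the n < 10 guard are
   unstated upstream; `round` is Python's banker's rounding). Ties break by
   better mean energy, then lower cluster uid.
3. **Venn classes**: each cluster is classified by which retained rank sets
   contain it (three-way, the three pairwise intersections, single, none); a
   fragment inherits the best class among its clusters and only its
   highest-score cluster (best mean energy) is retained within that class.
4. **Hit list**: policy `first_choice` returns three-way-convergent
   fragments; `extended` (default) adds the HYD∩SIZE and HYD∩MMGBSA classes —
   the HYD-containing intersections are the regions that agree best with
   orthogonal experiments, whereas MMGBSA∩SIZE converges poorly, so it is
   excluded by default (configurable).

`confusion_metrics` compares a hit list against ground truth over a stated
universe, with accuracy = (TP+TN)/total.

## NMR screening calculus

* **CSP**: `Δδ_NH = sqrt(((Δδ_H)² + (Δδ_N/5)²)/2)` — the standard amide form
  with the ¹⁵N dimension down-weighted five-fold and averaged over the two
  dimensions. Mixtures are classed by the mean over the monitored peak
  panel: first class > 0.35 ppm, second class in (0.25, 0.35], discard
  ≤ 0.25 (the published wording leaves exactly 0.25 ambiguous; it is
  discarded here, and exactly 0.35 is second class).
* **Mixture design**: fragments are partitioned into tubes of five by a
  seeded greedy assignment plus pairwise-swap hill climbing that minimises
  the count of 1D ¹H peak pairs closer than 0.03 ppm within a tube (the
  overlap window of the original design tool is not public). The cost is
  non-increasing across sweeps; any remainder forms one smaller final tube.
* **STD**: `fSTD = (I_STD^prot − I_STD^0)/I_0 · [L]_tot/[P]_tot · 100`,
  binder iff fSTD ≥ 50 (boundary inclusive, "at least 50").
* **WaterLOGSY**: binder when ≥ 1 ligand peak flips positive → negative upon
  adding protein; any negative control peak voids the call (ambiguous). Only
  fragments positive in both ligand-observed experiments are potential
  binders; disagreement (including an ambiguous WaterLOGSY) is
  "controversial" and triggers individual re-testing.
* **Kd fit**: a single-site model with the exact quadratic bound fraction
  `f_b = ([P]+[L]+K_d − sqrt(([P]+[L]+K_d)² − 4[P][L]))/(2[P])` (the
  ligand-excess approximation is avoided because the titration spans only
  0–57× the protein concentration). The search grids K_d log-spaced over
  1 µM–100 mM (200 points); for each grid point the saturated shift has a
  closed-form least-squares profile, which replaces a second explicit grid
  dimension — same search semantics, better conditioning — followed by one
  nested linear refinement around the best cell. Results are reported as
  mean ± sd over ≥ 3 monitored peaks (fewer requires an explicit override).
  Flat titrations raise an unidentifiability error; grid-edge solutions
  warn.
* **Additivity**: a mixture's CSP should be explained by the sum of its
  identified singles; compatible iff the residual is within
  `max(tolerance·mixture, noise_floor)` with tolerance 0.25 and an absolute
  floor of 0.05 ppm covering near-empty mixtures. Unexplained residuals
  flag probable false negatives of the ligand-observed step (reported, not
  automated).

## The synthetic study system

The generators define the conditions under which the pipeline is validated.

**Toy receptor** (~190 beads): a hollow shell (radius 10 Å) with a 60°
conical cleft leading to a floor at z = 3.5 Å that carries six sub-pockets
(acceptor anchor beads at ring radius 3.6 Å) plus six weaker polar "surface
sites" interleaved on the floor periphery. Pockets are deliberately
heterogeneous — anchor charge scales from −0.8 e down to −0.52 e and the
apolar groove rails from three bead pairs down to one as pocket index grows.
This heterogeneity matters: it makes a cluster's energy, hydrophobic score
and residence time co-vary with genuine pocket quality, so the three
consensus ranks select the same clusters rather than decorrelated noise, the
way real sub-pockets of a protein–protein-interaction groove differ. The
groove rails also pin the azimuth of a bound fragment's tail so bound poses
collapse into one tight cluster instead of a rotational fan. The site
definition is the mass-weighted centroid of the anchor residues; fragments
start 50 Å from it (configurable, never below the 9 Å cutoff), in a box
sized by extent + 2 × 13 Å with Na⁺/Cl⁻ counts that neutralise and then
realise 0.1 M.

**Planted library** (default 40 fragments, binder fraction 0.125, fixed
before any pipeline stage runs): binders are C₃–O–H chains with a strongly
polar donor tip (O −0.35, H +0.45) and an apolar tail sized to the groove;
decoys split 5 : 1 : 1 into weak-polar (C–O–H with O −0.20, H +0.35 — genuine
but weak binders that populate the post-gate cluster universe the way real
screens' near-misses do), fully apolar (no hydrogen bond possible; removed
by the gate), and acceptor-only (polarity-mismatched against an all-acceptor
cleft). The 12.5 % binder fraction is the enriched-library regime of a
focused fragment screen; classic diverse libraries run 2–3 %.

**Titrations**: forward-simulated from the exact quadratic model at Kd
1500 µM (a typical weak fragment), 90 µM protein, 8 points over 0–5100 µM,
three monitored peaks with saturated shift changes of 0.25/−0.18/0.30 ppm
and Gaussian shift noise of 0.005 ppm; the generating truth is returned
beside the data so recovery tests never re-derive it from the fit.

What the toy system does *not* emulate: solvent, conformational flexibility
of the receptor, rotameric fragment chemistry, competing binding
stoichiometries, and spectral artefacts (overlap beyond a scalar window,
baseline, exchange broadening). Passing tests therefore demonstrate that the
pipeline's logic — supervision, clustering, descriptor aggregation,
consensus, and the NMR arithmetic — behaves correctly and discriminates
designed signal from designed background; they do not certify force-field
accuracy on real proteins.

## Problem sizes and performance

The default validation screen is 40 fragments × 3 replicas with a 200-step
budget (1000 frames/replica); a five-library screen (600 runs) completes in
a few minutes on one CPU thanks to the numba integrator core. Supervision
efficacy is measured over 20 placement seeds against an always-accept
control under the same budget; Kd recovery over 50 noise seeds.

## Known limitations

* The energy surrogate's absolute values are not comparable to physical
  binding free energies; only orderings are meaningful.
* DBSCAN on a continuously sampled trajectory chains consecutive frames: a
  fragment roaming a broad basin yields one wide cluster with diluted
  hydrogen-bond occupancy rather than several residences. Cluster
  granularity therefore reflects kinetics (hop rates vs. the step budget) as
  much as geometry.
* The consensus's top-decile cut needs a reasonably populated post-gate
  universe; screens much smaller than ~40 fragments retain so few clusters
  per rank that fragment coverage degrades (visible in the examples).
* Single-chain receptors only; no PBC, thermostats or solvent in the toy
  backend.
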