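# Methods

This note documents the models, conventions and defaults behind each stage
of the pipeline, the design choices made where the underlying procedure is
genuinely open, and what the synthetic generators do and do not emulate.

## Charge classes and complement patterns

Residues are classed as positive {H, R, K}, negative {D, E},
small-hydrophobic {V, A, L, I}, or *other* (the remaining standard
residues). Histidine is placed in the positive class because its imidazole
carries a partial positive charge near physiological pH and can be fully
protonated in suitable microenvironments; treating it as positive is what
makes His–Glu pairing the backbone of charge-complementary interfaces.
Complements: positive ↔ negative, small-hydrophobic ↔ itself. A parallel
complement pattern complements the query position-wise; the antiparallel
pattern complements the reversed query, so the antiparallel pattern always
equals the reversed parallel pattern.

Residues of class *other* have no chemical complement. The default policy
keeps the residue itself in the pattern (with a warning); a strict mode
refuses. Renderings use the fixed spellings `[HRK]`, `[VALI]`, `[DE]` so
pattern text is byte-comparable across runs.

Scanning is a direct per-offset set-membership test (sequences here are a
few hundred to a few thousand residues; no index structure is warranted).
Coordinates are 1-based inclusive in every report. Overlapping matches are
returned by default; a flag switches to greedy non-overlapping matching.
Windows covering non-standard residues (X, B, Z, …) never match, with one
logged warning per sequence.

## Structure I/O

Docking poses and trajectory frames are both consumed as multi-model PDB
(one MODEL per pose/frame). Parsing is backed by Biopython with a
fixed-column pre-scan that reports malformed ATOM/HETATM records by line
number. Conventions: altloc keeps the highest-occupancy conformer (ties →
'A'); insertion codes are rejected (no input this pipeline touches uses
them); elements missing from the element column are inferred from the atom
name; the side-chain flag is set from the standard backbone atom names
(N, CA, C, O, OXT and backbone hydrogens). Writing is fixed-column with
3-decimal coordinates, so a write→read round trip is exact at the format's
precision.

## Hydrogen-bond detection

No single H-bond definition is canonical for inspecting docking output, so
the detector uses conventional geometric criteria, fully configurable:

- donor–acceptor heavy-atom distance ≤ **3.5 Å** (inclusive);
- with explicit hydrogens: D–H···A angle ≥ **120°** (the hydrogen is any H
  of the donor residue within 1.25 Å of the donor heavy atom);
- without hydrogens (typical of docking output): a heavy-atom proxy —
  antecedent–D···A angle ≥ **90°**, where the antecedent is the donor's
  covalent neighbour from a fixed residue-template table. If the antecedent
  is absent the distance criterion alone applies.

Donor/acceptor capability comes from a fixed template (backbone N donates,
backbone O/OXT accepts; side-chain O/N per residue type). Histidine ring
nitrogens are both donor- and acceptor-capable because protonation states
are unknown outside a force-field context. Sulfur is excluded (weak,
geometry-ambiguous). Both site directions are searched, so the bond set is
symmetric under exchanging the sites.

## Pose triage

The model-selection filter keeps a pose when it has at least **3**
site–site hydrogen bonds through at least **3 distinct side-chain atoms**
(unique (chain, residue, atom-name) triples with the side-chain flag).
Distinct atoms are counted across both interface sides by default; whether
one or both sides should count is genuinely ambiguous, so a one-side mode
(`count_side="siteA"|"siteB"`) is exposed.

Orientation labels come from the Cα end-to-end vectors **u**, **v** of the
two sites: cos θ ≥ +0.5 → parallel, ≤ −0.5 → antiparallel, otherwise
crosswise (a ±60° parallel band; threshold configurable). The label is
invariant under rigid motion of the whole model.

## Atomic contacts

A contact is a heavy-atom pair, one atom from each partner, within
**4.0 Å** (inclusive; hydrogens excluded by default since docking outputs
vary in hydrogen presence). The threshold is a conventional atomic-contact
radius and is exposed in the config so profiles can be regenerated under
alternatives. Contact profiles attribute each pair to the profiled-chain
residue and sum over poses; the top-site search scans contiguous windows
and breaks ties toward the smallest start, which makes the reported site
deterministic when two clusters tie.

## Trajectory statistics

A bond timeline evaluates each residue-level bond spec per frame with one
fixed criteria set; persistence is the per-bond mean presence. A bond is
**stable** when persistence ≥ `min_persistence` (default 0.9) *and* it is
present in every frame of the final window (default 10 frames) — a bond
that breaks at the end is broken regardless of earlier occupancy. All
statistics are frame-based; physical times, when known, belong to the
upstream simulation, not to this analysis.

Rebinding events: site–site "contact" in a frame means ≥ 1 hydrogen bond or
(by default) ≥ 1 atomic contact at the contact cutoff — contact-based
detection is robust to H-bond flicker, and an H-bond-only mode exists. An
event is a maximal run of ≥ `gap_min` (default 5) contact-absent frames
preceded by at least one contact frame and followed by regained contact;
the default suppresses single-frame flicker and is exposed because no
standard event definition exists. The participation fraction of a tracked-
site residue is the share of events whose regained-contact window involves
it, reported to 3 decimals (`n/a` when no events occur). A trailing
detachment without regained contact is not an event.

## SPR kinetics

The 1:1 Langmuir surface-binding model
dR/dt = k_on·C·(R_max − R) − k_off·R has the closed-form solution given in
the README; the implementation uses it directly (no integration error), and
the test suite verifies it against high-accuracy numerical integration to
better than 1e−8 relative to R_max over a 10 × 10 × 3 parameter grid.

The global fit shares (k_on, k_off, R_max) across all concentrations and
minimizes the summed squared residuals with bounded least squares in
log-parameter space (k_on ∈ [1e−4, 1e8] M⁻¹s⁻¹, k_off ∈ [1e−7, 1] s⁻¹,
R_max ∈ (0, 1e5] RU). Log-space makes the parameter scales comparable and
the confidence intervals symmetric. Starting values come from a linearized
analysis: per-curve observed rates k_obs regressed against concentration
(k_obs = k_on·C + k_off) plus a log-linear dissociation-decay estimate of
k_off. A constant baseline offset is fitted when a zero-concentration curve
is present (that curve anchors it); reference-cell subtraction is assumed
done upstream, and injection-boundary spikes can be excluded with time-window
masks. Standard errors are propagated from the log-space covariance.
Non-convergence sets a flag and warns, returning best-found parameters —
never silently. Mass-transport limitation is not modelled.

Study conditions for simulation: analyte dilution series 0, 50, 100, 200,
500, 1000, 1500, 2000 µM; association 300 s; dissociation 120 s; reference
rate constants k_on = 0.37 M⁻¹s⁻¹, k_off = 4 × 10⁻⁵ s⁻¹,
R_max = 1000 RU. Noise is i.i.d. Gaussian — the simplest generator
consistent with least-squares fitting; 0.5 RU is used as a realistic
baseline noise for reference-subtracted Biacore-class data.

**Identifiability caveat.** With k_off ≈ 4 × 10⁻⁵ s⁻¹ the response decays
only ~0.5% over a 120 s dissociation window, so k_off (and hence
K_d = k_off/k_on) is weakly identified: at 0.5 RU noise the median relative
K_d error over 50 seeded runs is ≈ 5%, but it grows roughly linearly with
noise (≈ 19% at 2 RU), while k_on stays sharp (≈ 2%). The fitted standard
errors report this honestly, and the recovery tests check k_off by
confidence-interval containment rather than a fixed relative error. The
quotient of the reference constants themselves is
K_d = 4 × 10⁻⁵ / 0.37 ≈ 1.08 × 10⁻⁴ M.

## Synthetic data: what it emulates, and what it does not

The generators stand in for sequence databases, docking servers, MD engines
and the SPR instrument. Structures use idealized geometry — extended
backbones at 3.8 Å Cα spacing, schematic side chains from fixed templates,
side chains staggered ±0.8 Å by residue parity to keep adjacent functional
groups apart, and the two chains separated by 20 Å except where
interactions are planted explicitly (H-bonds at 2.9 Å donor–acceptor
distance with the antecedent aligned for a wide proxy angle; contacts at
3.7 Å through inert carbons so contact-planted poses stay H-bond-free).
Every generator is byte-deterministic under a fixed seed, writes a
`.truth.json` sidecar sufficient to predict every downstream output, and
self-validates by running the relevant detector immediately after
generation — excessive coordinate jitter therefore fails loudly at
generation time rather than corrupting ground truth.

Because downstream code consumes only distances and angles, chemical
realism (torsional preferences, sterics, solvent) is deliberately absent.
Passing tests therefore demonstrate that the *analysis* is correct on
inputs with known truth; they say nothing about docking accuracy, force
fields, or how often real interfaces satisfy the filters. The ligand chain
is the amyloid-β 1–16 fragment (EVHH at residues 11–14); the receptor chain
is a 16-residue fragment numbered 30–45 with HAEE at 35–38, so planted
interfaces reproduce the His–Glu pair combinations of interest
(Glu11–His35, His13–Glu38, His14–Glu38). The receptor-subunit *sequence*
stand-in is likewise synthetic: a 627-mer with HAEE planted at 35–38 and
KAED at 579–582 and a background resampled until the complement pattern
matches nowhere else — it reproduces the motif coordinates, not the real
subunit sequence.

## Problem sizes

Defaults keep every analysis interactive: oracle sweeps use hundreds of
random sequences and ≤ 200-atom contact instances; filter recovery uses
50 six-pose ensembles; trajectory recovery 20 × 50-frame schedules;
fit recovery 50 seeded noisy runs of the 8-curve dilution series. All sizes
are arguments, not constants.

## Known limitations

- The H-bond proxy angle without hydrogens is a coarse substitute for a
  D–H···A criterion; borderline bonds near 90° may be called differently
  than by a hydrogen-aware tool.
- Contact and H-bond thresholds are conventions; absolute counts (though
  not the located site) shift with the cutoff.
- The rebinding-event definition (gap length, contact mode) is a modelling
  choice; event counts are only comparable under identical settings.
- The kinetic model is strictly 1:1 Langmuir: no mass transport,
  heterogeneous ligand, bivalency, or drift.
- mmCIF, binary trajectory formats (XTC/DCD) and insertion-coded PDBs are
  out of scope; convert upstream.
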