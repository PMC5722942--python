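# Methods

This package analyses the conformational state of insulin monomers from
coordinate files.  Its scientific core is small and explicit: a
hydrogen-bond-based two-way classification of the A-chain N-terminal
helix, geometry extraction for the three covalent bridges, helix-axis
azimuths for the A1–A5 segment, and ensemble statistics over multi-model
files.  A synthetic-structure generator provides ground-truth inputs for
every stage.

## The classification model

Insulin is a two-chain hormone (A chain, 21 residues; B chain, 30) held
together by the cystine bridges A6–A11 (intra-chain), A7–B7 and A20–B19
(inter-chain).  Two layers of classification are applied to each monomer:

**T/R state.**  The R (and R^f) states extend the central B-helix toward
the B-chain N-terminus.  We assign per-residue helix types (below) and
call a monomer R when at least 3 residues among B1–B7 are typed H or G;
otherwise T.  The threshold is a package decision, exposed as a parameter
(`helical_min`, default 3) and echoed into every output header.  Only
T-state monomers receive the A-chain class label, because the A-chain
N-terminal helix classes are defined on the T-state fold.

**Class 1 / Class 2.**  The discriminating observable is the
hydrogen-bond acceptor of the Thr A8 backbone amide:

| best acceptor of A8 NH | pattern | label |
|---|---|---|
| Glu A4 carbonyl | i,i+4 (α) | CLASS1 |
| Val A3 carbonyl | i,i+5 (π-like) | CLASS2 |
| Gln A5 carbonyl | i,i+3 (3₁₀) | THREE_TEN |
| none | — | UNCLASSIFIED |

Class 2 is the receptor-compatible geometry: its wider helix shortens the
A6–A11 Cα–Cα distance and rotates the A2–A4 side chains.

## Hydrogen bonds and helix typing

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
model, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, and
recorded when E < −0.5 kcal/mol.  One criterion serves detection, helix
typing, and both classifiers, so borderline geometries cannot be assigned
inconsistently between stages.  Amide hydrogens present in the file are
trusted; otherwise H is rebuilt at 1.01 Å from N in the peptide plane,
opposing the bisector of the C(prev)→N and CA→N directions (prolines and
chain starts donate nothing).  Bifurcated A8 bonds are resolved by
energy; exact ties break toward the smaller sequence separation, then the
lower residue number.

Helix types follow the DSSP convention: two consecutive i→i+4 turns open
an H run, else i→i+3 gives G, else i→i+5 gives I; isolated turns are T,
the rest C.  On ideal helix fixtures the assignment matches mdtraj's DSSP
for all interior residues (the test suite asserts ≥95%).

## Geometry

Superposition uses the Kabsch SVD solution with determinant correction
(no reflections); the test suite cross-checks the minimal RMSD against an
independent quaternion-eigenvalue implementation at 1e-9.  Fit-then-measure
RMSDs (e.g. "all atoms of A1–A4 after fitting Cα B9–B19") keep fit and
measure selections separate.

Helix axes come from a least-squares line through local helix centres; the
centre for residue i is the closest-approach midpoint of the two inward
bisector rays of the Cα quadruple (i−1…i+2).  This bisector construction
is stable for helices as short as the 8-residue A-chain N-terminal helix,
where cylinder regression is not.  Rise is the mean axial step, twist the
mean signed angular step about the axis.  Azimuths are measured in the
plane normal to the axis from a reference direction; by package
convention the zero direction is the perpendicular component of
(Cα A6 − axis point).  When two structures are compared, the mobile
monomer is first superposed on the reference over Cα B8–B20 and both are
measured in the reference's helix frame, so azimuth differences express
rotation of the A1–A8 helix relative to the hormone core.  This
convention is fixed and documented rather than matched to any external
implementation; cross-structure *differences* are well-defined under it.

## Bridges

Bridge chemistry is typed from atoms, never residue names: two Sγ within
2.5 Å form a disulfide; a bonded Cβ–Cγ=Cγ′–Cβ′ path (steps < 1.75 Å)
forms a dicarba bridge.  χ dihedrals are listed from the lower-numbered
residue; dicarba cis/trans is decided by the central C=C torsion
(|τ| < 90° → cis).  Disulfide conformers get a deterministic sign-bin
label from (χ1, χ3, χ1′) — 0° bins as "+" — plus χ3 binned to the nearest
30°, so left- and right-handed bridges are distinct.  The binning scheme
is a documented package convention.

## Curation

The survey filters mirror how a curated T-state set is assembled from
the PDB: resolution strictly better than 2.8 Å; for disulfide-bridged
monomers an A6–A11 Sγ–Sγ bond length within [1.95, 2.05] Å (outside this
window the disulfide was poorly modelled); dicarba bridges are exempt
from the bond-length filter and flagged; entries complexed with the
insulin-degrading enzyme are excluded via a caller-supplied accession
list.  Missing resolution counts as a resolution failure (it cannot be
verified).  Altlocs resolve to the highest-occupancy conformer, ties to
altloc 'A'.

## Ensemble statistics

Multi-model files are treated as conformational ensembles (e.g. MD
frames).  Per frame we compute the heavy-atom RMSD of residues A1–A4
against a representative Class 2 reference after fitting on Cα B9–B19
(the conserved B helix; the fit selection is configurable because any
reasonable choice of the conserved core is defensible), the Thr A8
partner occupancies over {A3, A4, A5, none}, and per-residue helicity.
Frames with RMSD < 1.5 Å count as Class 2 for occupancy purposes; the
threshold is exposed as a flag.  Frames are treated as independent
samples — no statistical-inefficiency correction is applied, and the
per-segment breakdown exists so separate runs can be summarised
separately.  RMSDs are unweighted over heavy atoms; hydrogens are
excluded by default.

## The synthetic-structure generator

The generator exists so every pipeline stage can be tested against known
truth without downloading crystal structures.  It builds backbones from
torsions by NeRF (natural-extension reference frames) with canonical
geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°), so
recomputing (φ, ψ, ω) from the coordinates reproduces the inputs to
numerical precision.  Side chains are reduced to Cβ (idealised from the
backbone frame) plus the bridge atoms; classification never uses more.

A toy monomer is assembled in stages: (1) the A chain with the
class-defining torsions — Class 1 uses (φ,ψ) = (−54.5°, −56.5°) for
A1–A9, Class 2 an α turn for A1–A3 then (−57°, −70°) π-type torsions for
A4–A9.  These values were chosen, within the α/π basins, to maximise the
energy margin of the defining Thr A8 bond over competing acceptors so the
classification survives coordinate noise; they are construction choices,
not measurements of any deposited structure.  (2) Torsions of A9–A11 are
solved by least squares (seeded from a coarse scan, deterministic) so the
A6–A11 Cα–Cα distance hits the class target and the Cβ separation is
spannable by the bridge chemistry.  Cα targets: 4.78 Å (Class 1) and
4.55 Å (Class 2) for disulfide toys — the survey class means — 5.17 Å for
the trans-dicarba Class 1 toy (the trans-isomer crystal value), 4.05 Å
for the cis-dicarba Class 2 toy (cis bridges permit the short active-state
distance), and nearest-feasible analogues for the remaining combinations.
(3) The B chain (extended B1–B8, α-helical B9–B19 for the T state; α
throughout B1–B19 for R) is placed rigidly to close A7–B7 and A20–B19
with a clash penalty.  (4) Bridge atoms are solved from ideal bond
lengths/angles: Sγ–Sγ 2.04 Å with Cβ–Sγ 1.81 Å and 104° angles (the free
χ3 defaults to −85° where the span allows), or Cγ=Cγ′ 1.33 Å with the
C=C torsion locked at 0° (cis) or 180° (trans).  (5) Explicit backbone
amide hydrogens are attached — ensembles emulate MD frames, which carry
hydrogens, and the classifier's trusted-H path uses them; the
reconstruction path is exercised separately on hydrogen-free fixtures.

Gaussian noise is i.i.d. per coordinate; after noising, bridge covalent
geometry is re-idealised from the perturbed Cβ positions, emulating the
covalent restraints of crystallographic refinement (uncorrelated noise
would otherwise stretch the Sγ–Sγ bond and trip the curation filter on
nearly every monomer — real refined structures do not behave that way).
If a perturbation makes the bridge span infeasible the noisy coordinates
are kept, producing exactly the "poorly modelled disulfide" the curation
filter is designed to reject.

What the generator does *not* emulate: real side chains and their
packing, solvent, correlated thermal motion, lattice contacts,
sequence variation among insulin analogues, and genuine conformational
exchange along a trajectory (ensemble frames are i.i.d. draws from a
class mixture, not dynamics).  Tests passing on toys therefore establish
the correctness of the measurement and classification machinery — not
that real deposited structures will partition with any particular
counts.

## Synthetic cohort and ensemble study conditions

The survey drivers and the acceptance script analyse a synthetic cohort
of 30 Class 1 + 93 Class 2 monomers (the size and composition of the
curated T-state crystal survey) with σ = 0.08 Å coordinate noise — chosen
so the within-class spread of the A6–A11 distance (≈0.11 Å) is comparable
to the ~0.13 Å observed across real Class 1 structures.  Ensemble
analyses use 1000-frame mixtures (30% Class 2 for the mixture-recovery
condition; 4% Class 2 for the low-occupancy condition mirroring the rare
Thr A8–Val A3 bond in simulation) at σ = 0.1 and 0.08 Å respectively.
The classification-robustness suite uses 500 fixed seeds at σ = 0.15 Å.
These problem sizes keep the default test run and the acceptance script
to a few minutes on one CPU.

## Numerical choices and degenerate inputs

* Torsions are IUPAC-signed, reported in (−180°, 180°]; collinear
  reference points raise a typed error rather than returning garbage.
* Superposition requires ≥3 points of rank ≥2 after centring; weights, if
  given, must be non-negative with positive sum.
* The helix fit requires ≥5 Cα; nearly straight traces (< 5°/residue mean
  twist) are flagged low-confidence rather than rejected.
* Loop and placement solves are multi-start least squares with fixed
  internal seeds; identical inputs give identical structures bit-for-bit.
* Closure tolerances are 2×10⁻³ Å — far below the 0.01 Å at which
  distances are reported.
* Exact 0° torsions bin as "+" in conformer labels; the cis/trans
  boundary sits at |τ| = 90°.

## Known limitations

* The azimuth zero convention is package-defined; absolute azimuths are
  not comparable with other software, only differences computed under the
  same convention are.
* The Class rule uses a single best acceptor; genuinely bifurcated A8
  amides near the −0.5 kcal/mol cutoff can flip label with small
  coordinate changes, which is inherent to any threshold rule.
* R-state monomers are surveyed but not class-labelled.
* Real-data checks (the trans-isomer crystal structure, PDB 5T7R, and the
  curated survey set) require the user to download the entries; the
  repository ships no coordinate data.
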