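# Methods

This note records the models and rules the toolkit implements, the defaults
and why they were chosen, what the synthetic-data generators emulate, and
the numerical decisions a maintainer would want to know.

## Molecular model and perception

A `Molecule` is an atom table (element, Å coordinates, formal charge,
implicit-H count, aromatic flag) plus an undirected bond table (order 1–3,
aromatic flag). One type serves ligands and proteins; `ProteinStructure`
adds per-atom residue annotations and flagged metal centres (Zn, Mg, Ca,
Fe, Mn, Cu, Ni, Co, Na, K). Indices are 0-based in memory, 1-based only
inside file formats.

**Bond inference.** PDB carries no connectivity, so bonds are inferred:
atoms i, j are bonded iff both are non-metal and
d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å, with a Cordero-style covalent radius
table (C 0.76, N 0.71, O 0.66, …) and the conventional 0.4 Å slack. The
rule is deterministic and symmetric; a k-d tree accelerates it but the
contract is the O(n²) pair rule, which tests check literally.

**Rings and aromaticity.** Ring perception returns a minimum cycle basis
(SSSR-equivalent) as ordered atom cycles, sorted for determinism.
Aromaticity trusts input flags (SDF type-4 bonds, lowercase SMILES);
otherwise a ring is aromatic iff every member is C/N/O/S with ≤ 3 heavy
neighbors, every member is conjugated, and the π count (ring-double-bond
atom → 1, pyrrole-type N/O/S lone pair → 2) satisfies Hückel 4n+2. This is
deliberately a heuristic stand-in — which full aromaticity model a
structure-based pipeline should assume is genuinely open, and the choice is
isolated behind `perceive_aromaticity`.

**SMILES.** The grammar subset covers organic-subset atoms, aromatic
lowercase forms, bonds `- = # :`, branches, ring closures (digits, `%nn`),
and bracket atoms with charge and explicit H counts. Implicit hydrogens
are standard valence (B3 C4 N3 O2 P3/5 S2/4/6, halogens 1), charge-adjusted
(effective valence = default + formal charge), with aromatic bonds counting
3/2. Stereo markers and isotopes raise a parse error with the character
offset: failing fast was preferred over silently discarding information.

**Pharmacophoric features.** Donors are N/O/S with ≥ 1 hydrogen (explicit
or implicit); acceptors are N/O with an available lone pair (quaternary or
positively charged N and pyrrole-type ring N excluded); hydrophobes are
uncharged C/S with no N/O or charged neighbor; halogen-bond donors are
F/Cl/Br/I bonded to carbon; ring features are built for aromatic rings only
(centroid + best-fit-plane unit normal). Charge perception is rule-based at
an implied physiological pH: formal charges plus carboxylate / phosphate /
sulfonate terminal oxygens (all symmetric oxygens labelled identically) and
guanidinium/amidinium carbons. In protein mode, standard residues type
their side chains by atom name — Lys NZ and Arg CZ cationic, Asp/Glu
carboxylate O anionic, His ND1/NE2 both donor *and* acceptor (the neutral
tautomer is ambiguous; the superset is the conservative choice). Unknown
residues fall back to the element rules. No pKa model is attempted.

## Interaction detection

Eight interaction types are detected between the two feature sets.
Directional kinds carry a strict flag; strict always implies the crude
(distance-only) criterion. Defaults, all user-overridable through
`GeometricCriteria`:

| kind | distance (Å) | angle window |
|---|---|---|
| hydrogen bond | D⋯A ≤ 3.5 | D–H⋯A ≥ 120°; without explicit H: every X–D⋯A ≥ 90° |
| salt bridge | ≤ 4.0 | — |
| hydrophobic | ≤ 4.0 | — |
| halogen bond | X⋯A ≤ 4.0 | C–X⋯A ≥ 150° |
| π-stack (f2f / e2f) | centroids ≤ 5.5 | inter-normal ≤ 30° / 60–90° |
| π–cation | ≤ 5.5 | off-normal ≤ 30° |
| π–metal | ≤ 5.0 | off-normal ≤ 30° |
| metal coordination | ≤ 3.0 | — |

These are literature-consistent conventions, not fitted values; the
distance criterion for crude hydrogen bonds is donor–acceptor (not
H–acceptor), a documented choice. Donors whose hydrogens are implicit have
no H geometry, so the strict test falls back to heavy-neighbor angles.
Angles are computed as arccos of dot products clamped to [−1, 1] (no NaN at
collinearity); π-angles are folded to [0°, 90°] so normals are orientation-
free. Symmetric kinds are reported once, protein participant first, and
records are sorted by (kind, protein, ligand) for determinism. A crude
stacking record is assigned to the nearer angle class (threshold at the
midpoint, 45°).

`interaction_profile` fixes the 18-component order: for each kind in the
canonical list, the crude count then the strict count. Strict records are
included in the crude count (strict ⊆ crude).

## Properties and filters

MW sums standard atomic weights including implicit H. The logP is a
*reduced* atomic-contribution model (aromatic C 0.29, aliphatic C 0.14,
N −0.60, O −0.40, S 0.26, F 0.22, Cl 0.65, Br 0.86, I 1.12, C-attached H
0.12, polar H 0.0): the filters treat this table as definitional, and no
claim is made that it reproduces any particular literature logP estimator.
Rotatable bonds are acyclic single bonds between heavy atoms of heavy-degree
≥ 2, excluding amide C–N. Rule-of-Five allows one violation (its original
formulation); Rule-of-Three allows none.

The PAINS screen ships a representative subset (≥ 10 patterns: quinones,
catechol, rhodanine, enones, azo, hydrazones, thiourea, aryl-nitro,
acrylamide) encoded as explicit graph patterns — element / aromaticity /
minimum-degree constraints on nodes, order constraints on edges — matched
by subgraph monomorphism. The full 480-pattern catalogue would require a
complete SMARTS engine, which is out of scope.

## Descriptors

Contact counts use element pairing — 9 ligand × 4 protein elements, 12 Å
cutoff — following the original close-contact formulation; both the element
sets and the cutoff are parameters. Fingerprints hash with a fixed 64-bit
mix (splitmix64 finalizer), never the language's builtin hash, so bitsets
are identical across platforms and sessions. The circular fingerprint seeds
each atom with (element, heavy degree, charge, aromaticity, total H) and
iteratively rehashes with sorted neighbor codes; the path fingerprint
enumerates simple paths up to a length and canonicalizes each label as the
lexicographic minimum of its two directions. Order-invariance is by
construction and tested over random atom permutations. Bit-for-bit
compatibility with FP2/MACCS/RDKit bitsets is explicitly not promised.
Tanimoto of two empty fingerprints is defined as 1.0.

## Scoring models

Six model kinds share one interface: `mlr` (exact least squares; minimum-
norm solution with a warning on rank deficiency; classic standard errors
from σ̂²(XᵀX)⁻¹), `pls`, `rf`, `svm`, `nn_single`, `nn_multi`. The SVM and
neural-network kinds standardize inputs internally (contact counts have
mean ≈ 20; bits are 0/1) and the networks train with the full-batch
quasi-Newton solver — the right regime for the n ≈ 10²–10³ datasets this
toolkit targets, and deterministic given the mandatory seed. Stochastic
kinds refuse to train without a seed; identical inputs + seed give
identical predictions, which the tests assert bit-for-bit.

Persisted models use a versioned container: magic bytes, format version, a
schema-checked JSON header (model spec, descriptor generator id, feature
count, training metadata) and a SHA-256-checksummed payload. Corrupt or
truncated files raise an integrity error and never yield a partial model; a
newer format version raises a version error. Prediction refuses descriptor
matrices whose width or generator id mismatch the training metadata.

**Metrics.** ROC AUC is computed from midranks (Mann–Whitney form), exact
under ties. The semi-log AUC interpolates the empirical ROC at λ = 10⁻³ and
integrates TPR over log₁₀ FPR on [λ, 1], normalized by −log₁₀ λ; a random
scorer's expectation is (1−λ)/(3 ln 10) ≈ 0.1448, which acceptance checks
recover. EF@x uses a top set of ⌈xn⌉ with ties broken by stable input
order — the frozen, documented tie policy. k-fold CV shuffles once with the
seed, uses folds differing in size by ≤ 1, predicts each row exactly once,
and reports per-fold Pearson r mean ± sd; degenerate folds (single row or
constant values) report r = 0 rather than NaN. k = n is leave-one-out.

## Docking

The engine contract is deliberately thin: engines that cannot take multiple
ligands are driven one at a time; per-ligand failures are recorded and never
abort a screen; the ligand→result map is assembled in input order so it is
identical for every worker count (the central contract, tested at 1000
ligands). `n_workers = 0` means all CPUs. The Vina adapter builds an
explicit argument list (no shell), forwards seed and exhaustiveness, writes
receptor/ligand PDBQT to a per-run scratch directory (removed on success,
kept on failure for debugging) and enforces a per-ligand timeout (600 s
default). Receptors are written without partial charges — charge assignment
is a documented gap, acceptable for rescoring workflows. The deterministic
mock engine (score = −heavy atoms/10, a name containing "FAIL" simulates an
engine error) makes the whole stack testable with no external binary.

## Synthetic data: what it emulates, and what not

The generators define the toolkit's test conditions:

- **Planted complexes** compose idealized fragments — donor/acceptor pairs
  with the D–H⋯A angle solved exactly, ion pairs, benzene rings, metal
  sites — at requested geometries, ≥ 15 Å apart (20 Å used), plus seeded
  decoy carbons kept ≥ 8 Å from everything. Preset geometries are chosen so
  each fragment triggers *only* its planted interaction (e.g. face-to-face
  rings at 4.5 Å so no carbon pair enters the 4.0 Å hydrophobic window);
  the manifest is therefore pure bookkeeping, never a second detection
  path. The fragments are not force-field geometries and do not pretend to
  be: geometric detectors care about geometry alone.
- **Affinity datasets** draw contact counts as Poisson(20) — the scale of
  real close-contact descriptors — and set y = X·w + N(0, σ).
  `default_contact_weights` puts 4 dominant weights (|w| 0.4–1.0) over a
  ±0.05 background, mirroring the consistent finding that a few element
  pairs dominate contact-count affinity models. This matters for model
  class, not just realism: tree ensembles cannot represent a *dense*
  36-term additive signal and plateau near r ≈ 0.85 on uniformly drawn
  weights however many trees are grown, while the sparse-dominant structure
  is learnable by forests, networks and linear models alike.
- **Screening sets** draw actives ~ N(δ, 1) and decoys ~ N(0, 1), giving
  the closed-form population AUC Φ(δ/√2) used as an external truth.
- **Libraries** plant Rule-of-Five violation counts by construction:
  compliant short alkanes, hexaols (6 donors → 1 violation, still passing),
  undecaols (11 donors and 11 acceptors → 2 violations, failing).

Passing tests on these fixtures demonstrates geometric, statistical and
bookkeeping correctness — not performance on experimental protein–ligand
data, which varies in protonation, tautomers, coordinate error and
interaction density that the fixtures deliberately exclude.

## Problem sizes

The validation suite runs 100 planted complexes against a brute-force
all-pairs reference, 200 random rigid motions, 200 random metric sets plus
10⁵-point AUC recoveries and 10⁴ random rankings, n = 1000 affinity fits
with 300 held-out rows, a 100-molecule filter library, 100-molecule format
round trips and a 1000-ligand screening invariance check — sizes at which
every statistical tolerance (3 Monte-Carlo SEs) is meaningful while the
whole suite stays interactive.

## Known limitations

No protonation/tautomer model; aromaticity is heuristic; logP is
definitional, not calibrated; PAINS is a subset; PDBQT output is rigid and
chargeless; no GOLD/AutoDock4 adapters (the engine registry is the
extension point); cross-validation assumes exchangeable rows (no
scaffold-aware splitting).
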