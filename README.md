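# oddkit

A self-contained, open structure-based drug-discovery toolkit for
cheminformatics developers and virtual-screening practitioners. It covers
the computational stack a screening pipeline needs end to end:

- **Molecular IO** — SDF V2000 (read/write), PDB (read), AutoDock/Vina
  PDBQT (read/write), an organic-subset SMILES grammar; distance-based bond
  inference, SSSR-equivalent ring perception, and a Hückel-style
  aromaticity model.
- **Interaction fingerprints** — detection of the eight classical
  protein–ligand interaction types (hydrogen bonds, salt bridges,
  hydrophobic contacts, halogen bonds, face-to-face and edge-to-face
  π-stacking, π–cation, π–metal, metal coordination), each with a *strict*
  term (distance **and** angle criteria pass) and a *crude* term (distance
  only), summarized as an 18-component count vector usable as rescoring
  features.
- **Drug-likeness filters** — MW, atomic-contribution logP, H-bond
  donors/acceptors, rotatable bonds; Lipinski Rule-of-Five and Rule-of-Three
  presets, custom rule sets, and a representative PAINS substructure subset
  via a small graph-pattern matcher.
- **Descriptors** — element-pair close-contact counts in the style of the
  RF-Score scoring function (36 ligand×protein element pairs within 12 Å),
  plus circular (Morgan-style) and path fingerprints with a fixed,
  platform-independent hash.
- **ML scoring functions** — multiple linear regression, PLS, random
  forests, SVMs and single/multi-layer neural networks behind one seeded,
  fully reproducible train/predict/persist interface; ROC AUC, semi-log ROC
  AUC, enrichment factors and k-fold/LOO cross-validation for evaluation.
- **Docking API** — a common engine contract with an AutoDock Vina adapter
  and a deterministic mock engine, docking boxes derived from crystal
  ligands, and order-invariant multi-worker virtual screening.

## The core quantities

A detected contact is **strict** when both its distance and angular windows
pass, e.g. a hydrogen bond requires d(D,A) ≤ 3.5 Å and ∠(D–H⋯A) ≥ 120°;
with only the distance criterion met the contact is recorded as **crude**.
All cutoffs live in `GeometricCriteria` and are overridable per call.

The contact descriptor counts typed atom pairs,

    x_ij = |{ (a, b) : elem(a)=i in ligand, elem(b)=j in protein, d(a,b) <= 12 A }|

over i ∈ {C,N,O,F,P,S,Cl,Br,I} and j ∈ {C,N,O,S}, giving the 36-vector fed
to affinity regressors ŷ = f(x).

Screening quality is measured by ROC AUC (the rank statistic
P(s⁺ > s⁻) + ½P(tie)), by the semi-log AUC ∫ TPR d log₁₀FPR over
[λ, 1] / (−log₁₀ λ) with λ = 10⁻³ (early-recognition weighted; a perfect
ranking scores 1), and by the enrichment factor
EF@x = (actives in top ⌈xn⌉ / ⌈xn⌉) ÷ (actives / n).

## Worked example

Build a synthetic complex with three planted contacts and profile it:

```python
from oddkit.interactions import detect_all, interaction_profile
from oddkit.perception import perceive_features
from oddkit.synthetic import make_planted_complex

protein, ligand, manifest = make_planted_complex(
    [("hbond", (2.9, 180.0)), ("salt_bridge", (3.5,)),
     ("pi_stack_f2f", (4.5, 0.0))], seed=0)
pf = perceive_features(protein, as_protein=True)
lf = perceive_features(ligand)
records = detect_all(pf, lf)
for r in records:
    angles = ", ".join(f"{k}={v:.1f} deg" for k, v in r.angles.items())
    print(f"{r.kind:14s} d={r.distance:.2f} A  strict={r.strict}  {angles}")
```

prints

```
hbond          d=2.90 A  strict=True  DHA=180.0 deg
pi_stack_f2f   d=4.50 A  strict=True  normal=0.0 deg
salt_bridge    d=3.50 A  strict=True
```

— the hydrogen bond is strict because the donor–acceptor distance (2.90 Å)
is inside the 3.5 Å window *and* the D–H⋯A angle (180°) clears 120°; the
stacking pair is face-to-face strict because the ring normals are parallel
(0° ≤ 30°); the salt bridge has no angle term, so strict equals crude.
`interaction_profile(records)` returns the corresponding count vector
(`hbond_crude=1, hbond_strict=1, salt_bridge_crude=1, ...`), ready to use
as rescoring features.

The same workflows are scriptable from the shell:

```sh
oddkit filter --in library.sdf --rule ro5 --pains --out pass.sdf --report report.csv
oddkit screen --engine mock --ligands pass.sdf --workers 0 --scores scores.csv
oddkit train  --desc X.csv --y y.csv --model rf --seed 42 --out sf.model
oddkit eval   --scores scores.csv --labels labels.csv --ef 0.01,0.1
```

## Limitations

Geometric cutoffs are literature-consistent defaults, not values fitted to
data. The SMILES subset excludes stereochemistry and isotopes (rejected
loudly, never dropped silently). PDBQT is written rigid (single ROOT, no
torsion tree) and without partial charges — sufficient for rescoring
workflows, not flexible docking input preparation. See `docs/methods.md`
for the full model description and the synthetic-data scope.
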