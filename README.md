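# tkisense

Predicting the sensitivity of EGFR kinase-domain mutants to the reversible
tyrosine kinase inhibitors (TKIs) gefitinib and erlotinib, from the
structural interaction fingerprints of mutant–inhibitor complexes.

Activating EGFR mutations in non-small cell lung cancer respond very
differently to first-generation TKIs: exon 19 deletions and L858R are highly
sensitive (IC50 < 100 nM), G719X or L861Q only moderately (100–999 nM), and
most exon 20 insertions and T790M-bearing mutants are resistant
(≥ 1000 nM).  `tkisense` implements a pipeline that classifies a mutant's
sensitivity from the *binding mode* of its inhibitor complex:

1. **catalog** — parse the clinical mutation nomenclature
   (`delE746_A750`, `V769_D770insASV`, `T790M_L858R`, …) into explicit
   residue edits against wild-type numbering (UniProt P00533), with the
   30-mutant cohort and its high/moderate/low labels packaged.
2. **ifp** — for every frame of an MD trajectory (multi-model PDB) compute a
   7-bit-per-residue structural interaction fingerprint against the ligand
   (MOL2/SDF): apolar contact, aromatic face-to-face, aromatic edge-to-face,
   H-bond (protein donor), H-bond (protein acceptor), electrostatic
   (protein +), electrostatic (protein −).  A trajectory yields a binary
   F × 7R matrix — the binding mode.
3. **tensorize** — mutants with indels have different residue counts, so
   fingerprints are length-normalized by positional zero-padding into a
   cohort-wide master index (7 zeros per missing residue slot), stacked into
   a samples × frames × bits tensor and centered.
4. **mpca** — Multilinear PCA finds per-mode orthonormal projections
   U⁽¹⁾ (frames) and U⁽²⁾ (fingerprint) maximizing the total tensor scatter
   Σₘ‖𝒴ₘ‖²_F of the projected samples 𝒴ₘ = U⁽¹⁾ᵀ Xₘ U⁽²⁾, by alternating
   eigendecompositions.  Projected entries are then ranked by the class
   discriminability Γ = Σ_c N_c(ȳ_c − ȳ)² / Σₘ(yₘ − ȳ_{cₘ})² and the top H
   entries form each complex's feature vector.
5. **evaluate** — five classifiers (naive Bayes, logistic regression,
   random forest with 500 trees, RBF SVM, 5-NN) under stratified 10-fold
   cross-validation, swept over H, plus 2-D scatter views of the selected
   features.

A synthetic-data module generates cohorts with the same statistical
structure (temporally persistent contact bits, class-dependent contact
probabilities, indel-bearing mutants) plus analytic single-interaction
geometry fixtures, so the whole pipeline is testable at desk scale.

## Worked example

Pad the three-mutant worked cohort and check the zero counts:

```python
>>> from tkisense import parse_mutation_name, build_master_index
>>> specs = [parse_mutation_name(n) for n in
...          ("delE746_A750", "V769_D770insASV", "A763_Y764insFQEA")]
>>> master = build_master_index(specs, list(range(740, 781)))
>>> len(master.slots)          # 41 WT residues + 4 FQEA + 3 ASV slots
48
```

For `delE746_A750`, padding inserts 35 zeros (5 residues × 7 bits) between
K745 and T751 for its own deletion, 28 between A763/Y764 (the FQEA slots it
lacks) and 21 between V769/D770 (the ASV slots) — run
`tkisense catalog parse delE746_A750` to see the edits.

Run the full pipeline on the default synthetic cohort (30 samples, classes
12/10/8, 100 frames) and classify:

```python
from tkisense import SimScenario
from tkisense.pipeline import run_synthetic_experiment

curve, projected, labels, names = run_synthetic_experiment(
    SimScenario(seed=17), H_values=[3, 10], seed=17
)
print(curve.to_frame().pivot(index="H", columns="classifier",
                             values="accuracy").round(3))
```

```
classifier    knn  logistic  naive_bayes  random_forest    svm
H
3           0.900       1.0          1.0          1.000  0.933
10          0.833       1.0          1.0          0.967  0.733
```

Each number is the fraction of the 30 synthetic complexes classified into
the correct sensitivity class under stratified 10-fold cross-validation
using the top-H discriminative tensor features; the probabilistic
classifiers hold ≥ 0.97 at H = 10 while the distance-based ones decline as
weakly informative features enter, the same qualitative behaviour the
method shows on real cohorts.

The same stages are exposed as a CLI for file-based workflows:

```bash
tkisense simulate fixtures --out fixtures/
tkisense ifp compute --frames fixtures/stack_face.pdb \
    --ligand fixtures/stack_face.mol2 --out stack_face.csv
tkisense run --config run.yaml          # full pipeline with manifest
```

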