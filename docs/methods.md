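# Methods

## Problem setting

The package classifies EGFR kinase-domain mutants into three
gefitinib/erlotinib sensitivity classes — high (IC50 < 100 nM), moderate
(100–999 nM), low (≥ 1000 nM) — from the dynamic interaction pattern of the
mutant–inhibitor complex.  The cohort is the 30 most common kinase-domain
variants (12 high, 10 moderate, 8 low).  IC50 values in the open interval
(999, 1000) nM are assigned to the moderate band so the mapping is total
with cut-offs exactly at 100 and 1000 nM.

The modeled domain is residues 696–988 (UniProt P00533 numbering).  The
wild-type sequence for that span is packaged as FASTA; deletion contents
(e.g. ELREA for the 746–750 deletion) are always taken from it, and a
mismatch between a residue letter written in a mutation name and the
packaged sequence is reported as a warning rather than an error, since
published names occasionally carry typos.

## Interaction fingerprints

For each residue of the binding site and each trajectory frame, seven
independent bits record: apolar (van der Waals) contact, aromatic
face-to-face, aromatic edge-to-face, hydrogen bond with the protein as
donor, hydrogen bond with the protein as acceptor, electrostatic contact
with the protein positive, and with the protein negative.  Bits within a
residue word follow exactly that order.

Geometric criteria (all configurable through `GeometryParams`; defaults are
standard values from the SIFt/IFP literature):

| interaction | rule | default |
|---|---|---|
| apolar | min distance between apolar heavy atoms | ≤ 4.5 Å |
| face-to-face | ring-centroid distance, inter-plane angle | ≤ 4.0 Å, ≤ 30° |
| edge-to-face | ring-centroid distance, inter-plane angle | ≤ 5.0 Å, 60–90° |
| H-bond | donor–acceptor heavy-atom distance; D–H···A angle when an explicit H exists | ≤ 3.5 Å, ≥ 135° |
| electrostatic | opposite formal charges, heavy-atom distance | ≤ 4.0 Å |

Ligand chemistry is perceived once from a MOL2/SDF file via RDKit: apolar =
C/S atoms not bonded to N/O plus halogens; donors = N/O bearing hydrogen;
acceptors = N/O with an available lone pair (formal charge ≤ 0, nitrogen
with at most three connections and not a pyrrole-type ring NH); aromatic
rings from perceived aromaticity.  Protein atom types come from
residue/atom-name template tables (backbone N donor except proline,
backbone O acceptor, Lys NZ and Arg NE/NH1/NH2 positive, Asp/Glu
carboxylates negative, His treated as a neutral donor+acceptor); no
protonation-state engine is run.  When hydrogens are absent from the PDB
frames the H-bond criterion degrades to the distance rule alone.

The binding site is the set of residues with any heavy atom within 6.0 Å of
any ligand heavy atom in the first frame, frozen for the whole trajectory so
fingerprint columns remain comparable across frames.

## Length normalization and tensor assembly

Mutants with indels have different residue counts.  A cohort-wide *master
index* is built as the ordered union of wild-type residues and one slot per
inserted residue of every insertion present in the cohort; distinct
insertions between the same flanking pair receive disjoint slot blocks
ordered alphabetically by inserted sequence, which makes the index
deterministic and independent of cohort order.  Each mutant's fingerprint
matrix is then padded: its own columns are copied into the slots it owns and
every other slot contributes seven zero columns.  Deletion–insertion
variants (e.g. `delL747_P753insS`) place their inserted residues in the
leftmost slots of the deleted span and zero-fill the remainder — the rule
that degenerates correctly to pure deletions and pure insertions.
Substitutions occupy their wild-type slot directly.  Padding is
information-preserving: dropping the un-owned slots recovers the input
bit-exactly.

Padded matrices are stacked in cohort order into a samples × frames × bits
tensor and centered by subtracting the sample-mean matrix.

## Multilinear PCA and feature selection

Given centered matrix samples Xₘ (frames I₁ × bits I₂), MPCA seeks
orthonormal U⁽¹⁾ (I₁ × P₁) and U⁽²⁾ (I₂ × P₂) maximizing the total scatter
Σₘ‖U⁽¹⁾ᵀ Xₘ U⁽²⁾‖²_F.  The solver alternates: U⁽¹⁾ ← top-P₁ eigenvectors of
Σₘ Xₘ U⁽²⁾U⁽²⁾ᵀ Xₘᵀ, then U⁽²⁾ ← top-P₂ eigenvectors of Σₘ Xₘᵀ U⁽¹⁾U⁽¹⁾ᵀ Xₘ,
until the relative scatter change falls below `tol` (default 1e-6, maximum
20 iterations; convergence is typically reached in 2–3).  Initialization is
the full-projection truncation — eigenvectors of the per-mode total scatter
matrices — which is deterministic and seed-free.  When mode dimensions are
not given, P_n is the smallest dimension whose mode-n eigenvalue mass
reaches `var_kept` (default 0.97) at initialization.  Mode 1 is always the
frame axis, mode 2 the fingerprint axis.  The projected scatter is
non-decreasing across iterations and, at full projection, exactly equals the
input scatter; with I₁ = 1 the method reduces to classical PCA.

Projected entries are ranked by the class discriminability
Γ(p) = Σ_c N_c (ȳ_c(p) − ȳ(p))² / Σₘ (yₘ(p) − ȳ_{cₘ}(p))²,
a per-entry between/within scatter ratio.  Degenerate entries: zero within-
class scatter with nonzero between-class scatter ranks first (Γ = +∞); an
entry constant over all samples gets Γ = 0 and ranks last; ties break by
ascending (p₁, p₂) position.  The top H entries form each sample's feature
vector.

Both steps are scikit-learn–style transformers (`MultilinearPCA`,
`DiscriminantFeatureSelector`) with `fit`/`transform`,
`get_params`/`set_params` and trailing-underscore fitted attributes, so they
compose with sklearn tooling; module-level functions wrap them.

## Classification protocol

Five classifiers are evaluated: Gaussian naive Bayes, logistic regression,
random forest (500 trees, seeded from the run seed), RBF SVM (C = 1,
γ = 1/H, standardized features) and 5-nearest-neighbours (standardized
features).  With 30 samples in classes of 12/10/8, exact 10-fold
stratification is impossible; folds are built by dealing each class's
shuffled indices round-robin across folds with a continuing cursor, so
per-class fold counts differ by at most one and every sample appears in
exactly one test fold.  If the requested fold count exceeds the sample
count the split degrades to leave-one-out with a warning.

Feature *selection is treated as preprocessing*: in the accuracy-versus-H
curve the Γ ranking is fitted inside each training fold only (one ranking
per fold, shared across all H), exactly like the feature scaling.  Fitting
the ranking on all samples before cross-validation inflates accuracy
substantially when many candidate entries exist — on a no-signal cohort it
yields ~0.85 apparent accuracy against a true chance level of ~0.33 — so
the in-fold protocol is the default.  The exported per-cohort feature table
and the 2-D scatter views, which describe the cohort rather than estimate
generalization, use the full-cohort ranking.

Accuracy is reported as the fraction correct pooled over one stratified
k-fold pass, one number per (H, classifier).

## Synthetic data

`SimScenario` emulates the statistical structure the pipeline assumes, at
desk scale.  Defaults mirror the real study cohort: M = 30 samples in
classes 12/10/8; F = 100 frames; a 30-residue binding-site window (wild-type
residues 746–775); three samples carry real indel specs (`delE746_A750`,
`A763_Y764insFQEA`, `V769_D770insASV`) so zero-padding is always exercised.
Each residue-bit evolves as a two-state Markov chain over frames with
stationary on-probability p and off-switch hazard `flip_rate` (default
0.02/frame; the on-switch hazard is scaled to preserve p, and the initial
state is drawn from the stationary law, so every frame has marginal p).
Persistence is deliberate: MD contacts are temporally correlated, which is
what makes the frame mode compressible.

Six discriminative residues (751, 754, 758, 762, 766, 771 — positions
present in every default mutant) carry class-dependent probabilities from
the ladder 0.9 / 0.5 / 0.1 over a 0.05 background.  The ladder is assigned
to classes in cyclic rotation across the discriminative residues (residue d
uses rotation d mod 3), so no single residue separates all three classes
and the between-class structure is genuinely two-dimensional — mirroring
real cohorts, where different residues distinguish different mutant groups.
A null preset sets all classes to the same probability; under it the
cross-validated accuracy of every classifier sits at chance, which is the
package's leakage check.

What the generator does *not* emulate: real geometry (bits are sampled, not
computed from coordinates), correlations between bits of one residue,
drug-specific differences, or within-class heterogeneity beyond sampling
noise.  Passing tests therefore demonstrate that the pipeline recovers
planted class structure of realistic shape and strength — not that real
MD trajectories carry such structure.

The geometry fixtures are single-residue/ligand pairs with analytically
constructed coordinates placing one targeted interaction inside its default
threshold, with ground-truth bits recorded at generation time from the
construction, never by running the fingerprint code.  Two caveats are
inherent to the rules: stacked aromatic rings always also register an
apolar contact (ring-atom distances are below the 4.5 Å cutoff whenever
centroids are close enough to stack), so the stacking fixtures record both
bits; and the salt-bridge fixtures place the charged pair at 3.8 Å —
inside the 4.0 Å electrostatic cutoff but outside the 3.5 Å H-bond
distance — because a closer salt bridge is simultaneously a hydrogen bond.

## Numerical and design notes

- Problem sizes: the default synthetic experiments use 30 × 100 × ~260
  tensors; MPCA fits in under a second and a full five-classifier sweep
  over two H values takes a few seconds per replicate.
- Eigendecompositions use `scipy.linalg.eigh` on symmetric scatter
  matrices; eigenvalues are clipped at zero before cumulative-mass
  dimension selection.
- Non-centered input to `MultilinearPCA.fit` triggers a warning and
  auto-centering; `transform` re-applies the stored mean.
- All stochastic components (fold assignment, random-forest trees,
  synthetic chains) derive from explicit integer seeds; reruns with the
  same seed are byte-identical, which the pipeline manifest (SHA-256 per
  output file) makes checkable.
- Known limitations: no water-mediated or halogen-bond interaction types;
  no protonation engine (template-based typing only); ligand/PDB atom
  names must correspond for per-frame ligand coordinates; trajectories are
  consumed as multi-model PDB, not binary MD formats.
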