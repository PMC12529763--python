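# Methods

## Data model and curation

Bioactivities are stored on the negative-log molar scale (pActivity =
−log10 M); readers convert from nM/µM units when a unit column is present.
The curation workflow applies, in order:

1. **Assay-type filter** — keep Ki, Kd, EC50, IC50 (the four types with noise
   levels consistent enough for activity-cliff analysis; "potency" is accepted
   by the source-specific stage but excluded from the benchmark types).
2. **Relation filter** — keep "=" and "≤" records; "<", ">" and missing
   annotations are counted into named drop buckets.
3. **Replicate-consistency filter** — records carrying a replicate standard
   deviation pass only if std < 0.1 (strict); records without one are exempt.
4. **Target-id mapping** — an injected lookup table (e.g. gene symbol →
   accession); unmapped records drop with reason "no UniProt ID".
5. **Molecule standardization** — RDKit: cleanup (functional-group
   normalization + reionization), metal disconnection, largest-fragment
   (salt/solvent) selection, charge neutralization, tautomer canonicalization,
   stereochemistry reassignment. Unparseable molecules become rejection
   records, never batch-aborting exceptions. The contract is determinism
   within one RDKit build, not bit-exactness across toolkits.
6. **Conflict resolution** — grouping key (canonical SMILES, target, assay
   type): groups whose value range exceeds 1 log unit (a 10-fold disagreement)
   are dropped whole; smaller conflicts collapse to the arithmetic mean.
   Grouping is per assay type — the conservative reading; grouping across
   types would silently average Ki against IC50.

Every input record ends in the output or in exactly one drop bucket
(conservation is asserted in the report object itself).

## Activity cliffs

Similarity of a standardized pair is the maximum of: Tanimoto on 2048-bit
radius-2 Morgan fingerprints; Tanimoto on the same fingerprint of the
Bemis–Murcko scaffolds; and 1 − d/max(|a|,|b|) where d is the Levenshtein
distance between canonical SMILES (max-length normalisation, the MoleculeACE
convention; computed on canonical rather than raw SMILES — raw strings would
make the measure depend on input formatting). Both thresholds are strict:
similar means max similarity > 0.9, and a similar pair is a cliff when
|Δ pActivity| > 2 (a 100-fold potency gap). A compound is AC-labeled iff it
participates in at least one cliff pair; cliffs are computed after conflict
resolution, so each molecule has one value per (target, type) group.

Two corner conventions worth knowing: two ring-free molecules both have empty
scaffold fingerprints and are assigned scaffold similarity 1 (self-similarity
must be 1; congeneric acyclic pairs are in fact close analogues), and cliff
pairs are computed within (target, assay type) groups.

## AC-stratified splitting

Per target, molecules are clustered by spectral clustering
(scikit-learn, precomputed affinity = pairwise ECFP Tanimoto, discretize
assignment) and each cluster is split 80/20 by stratified random sampling on
the AC label: per stratum the train count is round(0.8·size), nudged by ±1 on
the stratum with the largest slack so the cluster totals round(0.8·n).
The configured cluster count (default 50) is capped at n/10 so clusters
average at least ~10 molecules; with singleton clusters the within-cluster
draw would be vacuous (round(0.8·1) = 1 sends everything to train). Splits
are a pure function of the seed; per-(target, type) seeds are derived from the
global seed so group iteration order is irrelevant.

## Network

All blocks share the hidden width d_h (default 300). Input featurization is
the chemprop convention: 133 atom features (atomic number one-hot over 1–100
plus unknown; total degree 0–5; formal charge −2…2; chiral tag; H count;
hybridization; aromaticity; 0.01·mass) and 14 bond features (null flag, bond
type, conjugation, ring membership, stereo code); a directed edge's input is
its source-atom features concatenated with its bond features (147).

**Ligand encoder (communicative message passing).** With H⁰(v), H⁰(e) the
ReLU-projected inputs, each layer computes the node message
M(v) = Σ_{u∈N(v)} H(e_{u,v}) ⊙ max_{u∈N(v)} H(e_{u,v}) — the element-wise
maximum over the incoming edge hiddens acts as a message booster (the printed
form of this max is self-referential after summation; the per-neighbor
element-wise max is the communicative-MPNN reading) — then
H(v) = ReLU(W·[H(v); M(v)]), the edge message
M(e_{u,v}) = H(v) − H(e_{v,u}) (reverse-edge subtraction), and
H(e) = ReLU(H⁰(e) + W·M(e)). After L layers (default 1) a final aggregation
repeats the sum⊙max step and the atom embedding is
H_atom(v) = ReLU(W·[M(v); H(v); E⁰(v)]) with E⁰(v) the sum of initial hidden
states of v's incoming edges (the natural shape-preserving aggregate for the
otherwise-undefined initial-edge term; empty neighborhoods contribute zero
vectors, so single-atom molecules are well defined).

**Readout.** The graph embedding is a sum over atoms of a shared GRU-cell
readout: the cell's hidden state (width 2·d_h, mirroring the doubled readout
width of bidirectional readouts in communicative MPNNs) is initialised from
[H_atom(v); M(v)], updated once with input H_atom(v), and the two d_h-wide
halves are summed back to d_h before the atom sum. A shared per-atom cell
plus a sum is used rather than a sequential (bidirectional) GRU over an atom
ordering: a sequence GRU is not permutation invariant, and permutation
invariance of H_lig is a contract this package tests.

**Protein encoder.** Residue graph adjacency is the union of seven contact
types computed from a structure (peptide bond; N/O donor–acceptor pairs within
3.5 Å; Cys SG–SG < 2.2 Å; oppositely charged side chains within 6 Å; aromatic
ring centroids 4.5–7 Å; sulfur within 5.3 Å of an aromatic ring; cations
within 6 Å of a ring centroid — standard residue-interaction-network
cutoffs), or the peptide-bond chain alone in sequence mode. With self-loops
added, one GCN layer computes H_res = ReLU(D̂^−1/2 Â D̂^−1/2 H⁰ W) from
1280-dimensional per-residue language-model embeddings (an L×21 one-hot
fallback exists for the no-embedding variant), and H_prot is the residue mean.

**Cross-attention pooling.** Five heads; per head, queries are atom
embeddings and keys/values are residue embeddings, affinely projected to
d_h/5 = 60; A = row-softmax(QKᵀ/√60), so each atom's attention over residues
is a probability vector. A head's output is the atom-average of AV, and
H_comp concatenates the five head outputs (dimension d_h). The per-head
attention matrices are returned for interpretability.

**Decoder.** y = ReLU([H_lig; H_comp; H_prot]·W⁰ + b⁰)·W¹ + b¹ — a 900→300→1
feed-forward map (the two bias terms are independent parameters).

**Parameter count.** At defaults the trainable scalars are: atom input
133→300 (40,200), edge input 147→300 (44,400), node update 600→300 (180,300),
edge update 300→300 (90,300), atom output 900→300 (270,300), readout GRU cell
in 300/hidden 600 (1,623,600), GCN 1280→300 (384,300), attention 5 heads × 3
projections 300→60 with biases (270,900), decoder (270,601) — total 3,174,901,
i.e. 3.2 M. The count is a pure function of the configuration and excludes
the frozen input embeddings.

**Ablation variants.** `no_mol_encoder` replaces the ligand branch by an
affine map of the 2048-bit ECFP (the molecule embedding doubles as the single
attention query); `no_prot_encoder` applies the residue projection without the
graph convolution; `no_esm` switches residue inputs to the 21-dim one-hot;
`no_cross_attention` drops H_comp and decodes [H_lig; H_prot] (600);
`kano_only` decodes H_lig alone and ignores the protein; `no_integration`
trains one model per assay type (a training-stage switch).

Dropout (default 0.1) follows each hidden ReLU and is disabled at inference.
Parameters are Xavier-uniform initialised from the config seed; everything is
float64 and bit-reproducible.

## Training

Mean-squared-error loss, Adam at learning rate 1e-4, batch size 256, 100
epochs (published defaults; small studies in the tests shrink epochs and
width, see below). Training pools all assay types, keeping the type tag as
metadata only — no type-specific heads. Cycle one runs 5-fold
cross-validation, selecting each member's best epoch by held-out MSE; cycle
two re-partitions with an independent seeded shuffle (the re-partitioning
scheme is unstated upstream; independence is the less leaky choice) and
selects against a Ki-matched subsample of the held-out fold: Ki records are
binned at 0.5 log units and draws are allocated equally across occupied bins
up to a budget (default: all available Ki records — no budget is stated
upstream, and subsampling below availability would only discard signal).
Folds without Ki records fall back to the full fold with a warning. The 10
members form the ensemble: prediction = member mean, uncertainty = member
standard deviation with the n−1 (sample) convention, std = 0 iff the members
agree. Fine-tuning re-trains every parameter; an overlap-removal helper drops
exact (molecule, target, value) matches between fine-tune and reference data
to prevent leakage.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
real assay distributions. Twelve ring-system templates (one ring system per
series, so Bemis–Murcko scaffolds — and hence scaffold similarity 1 — are
shared within a series and distinct across series) grow an alkyl chain to
produce congeneric members. The similarity contract (adjacent members > 0.9;
all cross-series pairs < 0.9) is *verified at generation time* with the
package's own similarity computation and violations raise — SMILES edit
distance does not always track chemical similarity, so the guarantee is
checked, not assumed. Bioactivities are a per-(series, protein) base level
in U(5, 9) plus U(−0.1, 0.1) member jitter; cliff members (probability
`cliff_rate`, default 0.15) receive an extra ±U(2.5, 3.5) log offset. With
these widths the worst-case planted-cliff gap is 2.3 (> 2) and the worst flat
gap 0.2 (< 2), so planted labels are recoverable as exact set equality — the
offset band is kept away from the 2-log threshold precisely so the jitter
cannot blur it. A `conflict_rate` fraction
of records (default 0.1) is duplicated with a ±U(1.2, 2.0) gap, planting
conflict groups that curation must drop whole. Proteins are random 50–200
residue sequences with a contiguous 8–15 residue synthetic "pocket" and
one-hot embeddings. Everything is a pure function of the spec, seed included.

What passing on this generator does *not* show: robustness to real assay
noise distributions, scaffold diversity beyond the template vocabulary,
structured measurement bias between sources, or chemistry where the three
similarity measures disagree with chemical intuition.

## Evaluation

RMSE, PCC and SRCC follow the textbook formulas (SRCC = Pearson on average
ranks; ties get average ranks). Correlations on degenerate inputs (n < 2 or
zero variance) are reported as explicitly undefined, never silent NaN. Cliff
metrics are the same statistics restricted to the AC mask. The enrichment
factor ranks by descending score, takes the top ⌈fraction·n⌉ (ceiling
guarantees a nonempty top set at small n; ties break by stable input order —
EF at 1% is tie-sensitive, so the rule is fixed and documented), and divides
the binder recall by the fraction; EF is invariant to strictly monotone score
transformations and bounded by 1/fraction. Scoring/ranking powers are
per-target PCC/SRCC with an unweighted mean (groups below 2 points or with
zero variance are excluded with a warning). The uncertainty sweep reports
subset MAE over samples with std ≤ t for ascending thresholds t. Pocket
enrichment averages attention over heads and query atoms to one coefficient
per residue, takes the top N (N = pocket size, stable tie-break), and reports
hits, EF = (hits/N)/(|pocket|/L), and an unequal-variance two-sample t-test
(the safe default when the variance structure is unknown) between pocket and
non-pocket coefficients.

## Numerical and testing choices

The compute layer is an in-package reverse-mode autodiff engine over NumPy
float64 tensors (dense affine maps, ReLU/sigmoid/tanh, row softmax,
concatenation, gather, segment sum/max) with a GRU cell and Adam built on
top; empty graph segments follow the zero convention, and segment-max routes
gradients to every row attaining the maximum. Gradient correctness is tested
by directional central finite differences (ε = 1e-6) against the analytic
directional derivative — more robust than coordinate-wise checks, whose
relative error is dominated by rounding noise on near-zero components.

Test problem sizes are deliberately small: the synthetic study defaults to 6
series × 6 members × 3 proteins (~130 records); optimisation tests use
narrow models (hidden width 10–60) and few epochs; the single-member overfit
demonstration runs a width-60 model at learning rate 3e-3 on 32 smooth
(cliff-free) pairs, reaching training RMSE < 0.1 within 300 epochs. The
published defaults (width 300, lr 1e-4, batch 256, 100 epochs) remain the
package defaults; the reduced sizes are the package's own choice of
demonstration scale, and determinism contracts (bit-identical reruns under a
seed) are tested at that scale too.

## Known limitations

* No censoring-aware modelling: "≤" relations are retained as tags but the
  values are treated as exact during training.
* The contact-graph builder uses simple distance rules on heavy atoms; it does
  not model hydrogen positions, ring planarity, or bond geometry, so hydrogen
  bonds and aromatic interactions are approximations.
* No pretrained weights ship with the package: the ligand encoder is the
  architecture with a weight-loading hook, randomly initialised; likewise
  residue embeddings are consumed as input (one-hot fallback), never computed
  by a language model in-package.
* Standardization exactness across RDKit versions is not promised (tautomer
  canonicalization in particular may differ between releases).
* The Levenshtein similarity is computed on canonical SMILES; results are
  sensitive to that choice because canonicalization can reorder atoms
  differently for close analogues.
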