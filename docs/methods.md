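# Methods

## Overview

`protofun` predicts Gene Ontology (GO) annotations from protein sequence
alone. The model assumes that (i) function leaves a signature in global
sequence statistics (composition, ordered physicochemical correlations),
(ii) the similarity structure *among descriptors* and *among proteins*
is itself informative and worth making explicit, and (iii) GO's
hierarchy carries exploitable label dependencies, in particular for the
long tail of small, deep families. Each stage below is an independent
module with its own tests.

## Sequence descriptors (1,484 dimensions)

Seven classes, in fixed order (the order defines the image channels):

| class | length | parameters (default) |
|---|---|---|
| amino-acid composition | 20 | — |
| pseudo-AAC (type I) | 50 | λ=30, w=0.05 |
| amphiphilic pseudo-AAC | 80 | λ=30, w=0.05 (2λ signed terms) |
| autocorrelation | 720 | Moreau-Broto, Moran, Geary × 8 scales × 30 lags |
| quasi-sequence-order | 124 | max lag 21, w=0.1, 2 distance matrices |
| CTD | 147 | 7 three-class property groupings × 21 |
| conjoint triad | 343 | 7-cluster alphabet, 7³ triads |

The per-class inventory is a documented design choice: the class names
and the 1,484 total are fixed constraints, the per-class split is chosen
from standard published definitions so the lengths sum exactly to 1,484
(20+50+80+720+124+147+343). Everything is configurable through
`DescriptorSpec`, and lengths are recomputed from parameters.

Property tables ship in-source (no network access): Kyte–Doolittle
hydropathy, Hopp–Woods hydrophilicity, residue mass, the three Grantham
side-chain properties, isoelectric point and Bhaskaran–Ponnuswamy
flexibility for autocorrelations; hydropathy/hydrophilicity/mass
(standardized) for the pseudo-AAC correlation factors. The two
quasi-sequence-order distance matrices are (a) the Grantham chemical
distance, recomputed from his composition/polarity/volume properties and
scaled to a mean off-diagonal distance of 100, and (b) this package's
physicochemical residue distance: the root-mean-square difference of
standardized hydropathy, hydrophilicity and residue mass, rescaled to a
maximum of 1. Amphiphilic pseudo-AAC correlation terms are products of
standardized (signed) scales and can be negative; the other composition
blocks are non-negative and AAC sums to 1.

Minimum sequence length under the default spec is 31 (λ=30 requires
length > λ); shorter sequences are rejected with the offending class
named. Non-canonical residues are mapped (B→D, Z→E, J→L, U→C, O→K,
X dropped) because the property tables cover only the 20 canonical
letters; a drop-all policy is available.

Every descriptor class is checked against a second, literal-from-formula
loop implementation (written independently in the test suite) to 1e-9.

## Template map and the two representations

Per-feature min–max normalization over the cohort maps the matrix to
[0, 1]; constant features go to 0 with a warning, and the stored min/max
are reused (with clipping) for queries. Cosine distance
`1 − a·b/(‖a‖‖b‖)` over columns gives the feature-distance matrix (FDM),
over rows the protein-distance matrix (PDM); zero-norm vectors receive
distance 1 by convention (no similarity signal). Both matrices are
symmetric, zero-diagonal and confined to [0, 2] (property-tested).

The FDM is reduced to 2-D by PCA (default; rows of the FDM as vectors)
or UMAP (`metric="precomputed"`, n_neighbors=15, min_dist=0.1, fixed
seed). The embedding is min–max rescaled to the unit square and features
are assigned to distinct cells of an S × S grid, S = ⌈√n_features⌉ (39
for 1,484, leaving 37 empty cells), by minimizing total squared
Euclidean distance to the cell centers with `scipy`'s Jonker–Volgenant
style `linear_sum_assignment`. Squared Euclidean cost is the standard
choice in grid-layout image embeddings; the solution is globally optimal
and is compared against exhaustive enumeration for up to 6 features in
the tests. PCA is the default reduction because it is deterministic,
fast at desk scale and parameter-free; UMAP is a config switch.

The **feature-map image** places each class's normalized intensities at
its cells in its own channel (7 × 39 × 39 under defaults). The
**similarity profile** of a reference protein is its PDM column; for a
new protein it is computed with the same cosine formula against the
frozen reference rows using the stored normalization — so training
proteins and queries are scored by one code path. Profiles are fed to
the network as distances in [0, 2], without further normalization.

## Ontology handling

OBO parsing (obonet) keeps non-obsolete terms and `is_a` edges only,
which yields one clean rooted DAG per namespace; `part_of`/`regulates`
are deliberately ignored. Levels: the namespace root is LEVEL 1 and a
term's level is 1 + the shortest `is_a` path to its root, so a
multi-parent term takes its minimum depth. Annotations are propagated
under the true-path rule (closed under ancestors, roots excluded;
idempotent). Label families are selected by protein count strictly
greater than the threshold (default 50); head/tail classification of a
level compares its average family size against the cutoff (default
2,000, boundary inclusive: head iff ANP ≥ cutoff).

## Networks

Implemented on an in-package numpy reverse-mode autodiff engine
(`protofun.autograd`) providing exactly the needed operations; all
gradients are verified against central finite differences.

Fixed defaults (stated values of the study design):

* CNN: two 3×3 stride-1 convolutions, each followed by max-pooling with
  pool size 2 and stride 1 (overlapping pooling, implemented exactly as
  specified), ReLU activations.
* Similarity path: 5 fully-connected ReLU layers, widths tapering
  geometrically from the input to the embedding width.
* Decoder: 3-layer LSTM, 256 units per layer, tanh activations,
  unrolled for 11 time steps.
* Training: batch 32, Adam with learning rate 2·10⁻⁴, focal loss
  (γ=2, α=0.25), early stopping on validation loss (patience 10);
  80/20 train/validation split.

Desk-scale defaults chosen by this package (configurable): conv filter
counts (8, 16) and per-path embedding width 128 (concatenated 256) —
sized so the full benchmark trains in minutes on one CPU; Adam as the
optimizer behind the stated learning rate; focal-loss parameters at
their canonical values.

Label-to-time-step mapping: one chunk per GO level, shallow to deep
(bucket t holds level t+1; deeper levels merge into the last bucket;
empty buckets keep the unrolled length fixed). The embedding enters at
step 1 and zeros afterwards (state-carried decoding; a
feed-every-step switch exists). The encoder's refinement head — a single
fully-connected layer onto the label space — is used for pre-training
only; the decoder consumes the concatenated pre-refinement embedding.

The k-NN similarity transfer scores
`score(q,t) = Σ_kNN sim·1[t annotated] / Σ sim` with
`sim = clip(1 − cosine distance, 0, 1)`, k=5 by default. The ensemble
weight α is selected on validation Fmax over the grid {0, 0.1, …, 1}.
Hierarchical consistency (ancestor score = max over descendants) is
applied at output time and is on by default; it never decreases Fmax on
propagated truth and makes outputs respect the true-path rule.

## Synthetic benchmark

The generator emulates the structural features the method targets: a
three-namespace DAG with diamonds (random parent attachment, acyclic by
construction), leaf families with power-law (exponent 1.5) prevalences
— so deeper levels have smaller families, the long tail — and sequences
whose labels are a deterministic function of planted signals: each
protein draws 1–3 leaves, embeds each leaf's 5-mer motif at
non-overlapping positions in a background where half the residues come
from the leaves' preferred 3-residue sets. Default scale: 500 proteins,
lengths 60–200, 12 leaf families, split 64/16/20 (an 80/20
train/validation split of the non-test portion), everything from one
seed.

What it does **not** emulate: real protein evolution (homology,
domains, indel structure), CAFA-scale cohorts and ontologies, realistic
annotation incompleteness, or inter-species composition. Passing tests
therefore demonstrate that the implementation is correct and that the
architecture can extract planted compositional/motif signals — not that
the model reaches any particular accuracy on real proteomes.

Measured on this benchmark (and recomputed by `scripts/acceptance.py`):
the deep path alone memorizes a 100-protein fixture (training Fmax
≥ 0.95 with early stopping disabled), and the full ensemble's held-out
Fmax exceeds both 0.5 and the label-frequency prior by a clear margin.

## Numerical choices and degenerate inputs

* Zero-variance autocorrelation tracks: Moran/Geary set to 0 (detected
  with a relative tolerance of 1e-12, since the realized mean of a
  constant float track is not exactly exact).
* Constant descriptor columns normalize to 0; zero-norm cosine vectors
  get distance 1.
* Focal loss clips log arguments at 1e-12 and logits at ±60.
* Fmax threshold grid: 0.01 steps (CAFA convention); AUPRC is
  micro-averaged over (protein, term) pairs with step-wise
  interpolation; per-level AUC macro-averages term-centric ROC AUCs and
  reports skipped single-class terms.
* All randomness (ontology, cohort, splits, parameter init, batch
  order) flows through seeded numpy generators; two runs with the same
  seed are bit-identical on the same machine.

## Known limitations

* Training is CPU-bound numpy; cohorts beyond a few thousand proteins
  or label spaces beyond a few hundred terms will be slow.
* The similarity profile's length is tied to the frozen training
  reference; enlarging the cohort requires re-training the encoder.
* Per-class descriptor parameters are standard-literature defaults, not
  fitted; the exact historical inventory behind the 1,484 split is not
  published, so other splits summing to the same total are equally
  admissible.
* The overlapping (stride-1) max-pooling enlarges feature maps compared
  to the common stride-2 choice and is the main cost of the CNN path.
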