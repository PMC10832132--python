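# protofun

Protein function annotation from sequence, for computational biologists
who need multi-label Gene Ontology (GO) predictions with honest,
CAFA-style evaluation — and a fully synthetic benchmark so every stage of
the method can be tested offline, at desk scale, on one CPU.

## The method

A protein `p` is first described by a 1,484-dimensional vector of seven
classic descriptor classes (amino-acid composition, pseudo-AAC,
amphiphilic pseudo-AAC, Moreau–Broto/Moran/Geary autocorrelations,
quasi-sequence-order, composition/transition/distribution, conjoint
triad). Over a training cohort this gives a protein-descriptor matrix
`PM`, min–max normalized per feature:

    x_ij_norm = (x_ij − min f_i) / (max f_i − min f_i)

Two cosine-distance matrices are derived from `PM`:

* feature–feature distances `d(f_a, f_b) = 1 − f_a·f_b / (‖f_a‖‖f_b‖)`
  drive the **template map**: features are reduced to 2-D (PCA or UMAP)
  and assigned to distinct cells of the smallest square grid
  (`⌈√1484⌉ = 39`, so 39 × 39) by an optimal linear-sum assignment.
  Rendering each protein's normalized intensities at its template cells,
  one channel per descriptor class, yields a 7 × 39 × 39 **feature-map
  image** — an "ordered" image whose spatial structure reflects feature
  similarity;
* protein–protein distances give each protein a **similarity profile** —
  its column of the protein distance matrix — a "globally relevant"
  vector of length `n_ref`.

A dual-path encoder (a 7-channel CNN: two 3×3 stride-1 convolutions with
2-wide stride-1 max-pooling; and a 5-layer fully-connected net over the
similarity profile) is pre-trained against the propagated GO labels with
focal loss (γ=2, α=0.25; Adam, batch 32, lr 2·10⁻⁴, early stopping).
The frozen concatenated embeddings are then decoded by a 3-layer,
256-unit LSTM unrolled over 11 time steps, one GO hierarchy level per
step (roots are LEVEL 1; the deepest bucket absorbs the rest), so
shallow-level decisions condition deeper, smaller — *tail* — families.
Final scores blend the decoder with a k-NN similarity transfer,
`α·deep + (1−α)·sim`, α picked on validation Fmax, followed by
true-path consistency (an ancestor scores at least its best descendant).

Evaluation is CAFA-style: protein-centric Fmax over a 0.01-step
threshold sweep, micro-averaged AUPRC, per-protein recall/precision, and
per-level term-centric AUC with head/tail classification of levels by
average family size (head: ≥ 2,000 proteins on real-scale data).

## Worked example

```python
import numpy as np
import protofun as pf
from protofun.network import ModelConfig, train_pipeline, predict, targets_from_annotations
from protofun.ontology import propagate_annotations, select_label_families
from protofun.evaluation import fmax_from_matrices

bench = pf.make_benchmark(n=500, seed=7)          # synthetic study
table = propagate_annotations(bench.truth, bench.ontology)
labels = select_label_families(table, bench.ontology, min_count=bench.family_min_count)
tr, va, te = (bench.indices(p) for p in ("train", "validation", "test"))

bundle = train_pipeline(bench.records, table, bench.ontology, labels,
                        tr, va, config=ModelConfig(seed=1))
pm = predict(bundle, [bench.records[i] for i in te])
truth = targets_from_annotations(table, pm.protein_ids, labels)
print("labels:", len(labels), " alpha:", bundle.alpha)
print("held-out Fmax:", round(fmax_from_matrices(pm.scores, truth)[0], 3))
```

On this benchmark the run prints:

    labels: 25  alpha: 0.8
    held-out Fmax: 0.894

25 GO families passed the toy selection threshold; the validation sweep
chose a blend weighting the deep model at 0.8; and the ensemble reaches
a held-out protein-centric Fmax of 0.894, versus 0.638 for a
label-frequency prior — the planted motifs and compositional biases are
recovered well beyond what class imbalance alone explains.

The same pipeline is scriptable from a shell:

```sh
protofun simulate --n 500 --seed 7 --out bench/
protofun features --fasta bench/cohort.fasta --out features.h5
protofun templatemap --features features.h5 --method pca --out map.h5
protofun train --fasta bench/cohort.fasta --annotations bench/annotations.tsv \
               --obo bench/ontology.obo --splits bench/splits.tsv \
               --min-count 5 --out model/
protofun predict --model model/ --fasta queries.fasta --out pred.tsv
protofun evaluate --pred pred.tsv --truth bench/annotations.tsv \
                  --obo bench/ontology.obo --min-count 5 --out report.json
```

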