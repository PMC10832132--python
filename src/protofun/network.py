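"""Dual-path encoder, level-wise LSTM decoder, and the prediction pipeline.

The encoder has two paths: a multi-channel CNN over the feature-map
images (two 3x3 stride-1 convolutions, each followed by overlapping
max-pooling with pool size 2 and stride 1, ReLU activations) and a
five-layer fully-connected network over the similarity profiles.  The two
path embeddings are concatenated and a final fully-connected refinement
layer scores the GO label space; the encoder is pre-trained against the
propagated annotations with focal loss (Adam, batch 32, learning rate
2e-4, early stopping on validation loss).

The decoder is a three-layer LSTM with 256 units per layer and tanh
activations, unrolled for 11 time steps by default.  Labels are chunked
by GO level (shallow to deep), and the hidden state at step ``t`` emits
sigmoid scores for the level-``t`` chunk, so the recurrence carries
shallow-level decisions into deeper ones — the mechanism that targets the
long-tail of small, deep families.

Final scores blend the decoder with a sequence-similarity k-NN transfer,
``alpha * deep + (1 - alpha) * similarity``, with alpha picked on
validation Fmax.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .descriptors import DescriptorSpec, descriptor_matrix
from .featmap import (
    DescriptorMatrix,
    TemplateMap,
    cohort_representations,
    make_feature_map,
    make_similarity_vector,
)
from .io_formats import AnnotationTable, ProteinRecord
from .ontology import GeneOntologyGraph, LabelSpace

logger = logging.getLogger("protofun")


@dataclass
class ModelConfig:
    """Hyperparameters; every study-stated value ships as the default."""

    conv_kernel: int = 3  # 3x3 kernels
    conv_stride: int = 1
    n_conv_layers: int = 2
    pool_size: int = 2
    pool_stride: int = 1  # overlapping pooling, exactly as stated
    conv_filters: tuple[int, int] = (8, 16)
    fc_layers: int = 5  # depth of the similarity-profile path
    embedding_width: int = 128  # per path; concatenated width is doubled
    lstm_layers: int = 3
    lstm_units: int = 256
    time_steps: int = 11  # one per GO level bucket
    batch_size: int = 32
    learning_rate: float = 2e-4
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    patience: int = 10
    max_epochs: int = 80
    seed: int = 0
    feed_embedding_every_step: bool = False
    hierarchical_consistency: bool = True
    knn_k: int = 5

    def __post_init__(self):
        if (self.conv_kernel, self.conv_stride) != (3, 1):
            raise ValueError("only 3x3 stride-1 convolutions are supported")
        if (self.pool_size, self.pool_stride) != (2, 1):
            raise ValueError("only pool size 2, stride 1 is supported")


@dataclass
class PredictionMatrix:
    """Per-protein scores over a label space, all finite in [0, 1]."""

    scores: np.ndarray  # n_proteins x n_labels
    protein_ids: list[str]
    label_space: LabelSpace

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            pid: {t: float(s) for t, s in zip(self.label_space.terms, row)}
            for pid, row in zip(self.protein_ids, self.scores)
        }


def _he(rng, shape, fan_in):
    return Tensor(
        rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32),
        requires_grad=True,
    )


def _taper(start: int, end: int, n_layers: int) -> list[int]:
    """Geometric width taper over n_layers hidden layers ending at *end*."""
    sizes = np.geomspace(max(start, 1), max(end, 1), n_layers + 1)[1:]
    sizes = np.maximum(np.round(sizes).astype(int), 4)
    sizes[-1] = end
    return sizes.tolist()


class DualPathEncoder:
    """7-channel CNN + 5FC-DNN encoder with a label-space refinement head."""

    def __init__(self, n_channels: int, grid_side: int, n_ref: int,
                 n_labels: int, config: ModelConfig):
        self.config = config
        self.n_channels, self.grid_side, self.n_ref = n_channels, grid_side, n_ref
        self.n_labels = n_labels
        rng = np.random.default_rng(config.seed)
        f1, f2 = config.conv_filters
        k = config.conv_kernel
        self.conv1_w = _he(rng, (f1, n_channels, k, k), n_channels * k * k)
        self.conv1_b = Tensor(np.zeros(f1, np.float32), requires_grad=True)
        self.conv2_w = _he(rng, (f2, f1, k, k), f1 * k * k)
        self.conv2_b = Tensor(np.zeros(f2, np.float32), requires_grad=True)
        side_out = grid_side - 2 * (k - 1) - 2 * (config.pool_size - 1)
        if side_out < 1:
            raise ValueError("grid too small for the conv/pool stack")
        flat = f2 * side_out * side_out
        emb = config.embedding_width
        self.cnn_dense_w = _he(rng, (flat, emb), flat)
        self.cnn_dense_b = Tensor(np.zeros(emb, np.float32), requires_grad=True)
        self.dnn_ws, self.dnn_bs = [], []
        prev = n_ref
        for width in _taper(n_ref, emb, config.fc_layers):
            self.dnn_ws.append(_he(rng, (prev, width), prev))
            self.dnn_bs.append(Tensor(np.zeros(width, np.float32), requires_grad=True))
            prev = width
        self.refine_w = _he(rng, (2 * emb, n_labels), 2 * emb)
        self.refine_b = Tensor(np.zeros(n_labels, np.float32), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [
            self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b,
            self.cnn_dense_w, self.cnn_dense_b,
            *self.dnn_ws, *self.dnn_bs, self.refine_w, self.refine_b,
        ]

    @property
    def embedding_dim(self) -> int:
        return 2 * self.config.embedding_width

    def forward(self, images: np.ndarray, profiles: np.ndarray):
        """Return (concatenated embedding, refinement logits) Tensors."""
        x = ag.maxpool2(ag.relu(ag.conv2d(Tensor(images), self.conv1_w, self.conv1_b)))
        x = ag.maxpool2(ag.relu(ag.conv2d(x, self.conv2_w, self.conv2_b)))
        x = ag.reshape(x, (images.shape[0], -1))
        cnn_emb = ag.relu(ag.add(ag.matmul(x, self.cnn_dense_w), self.cnn_dense_b))
        h = Tensor(profiles)
        for w, b in zip(self.dnn_ws, self.dnn_bs):
            h = ag.relu(ag.add(ag.matmul(h, w), b))
        emb = ag.concat([cnn_emb, h], axis=1)
        logits = ag.add(ag.matmul(emb, self.refine_w), self.refine_b)
        return emb, logits

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data = s.copy()


def build_encoder(n_channels: int, grid_side: int, n_ref: int,
                  label_space: LabelSpace, config: ModelConfig) -> DualPathEncoder:
    return DualPathEncoder(n_channels, grid_side, n_ref, len(label_space), config)


def _early_stopped_training(loss_of_batch, val_loss, params, config: ModelConfig,
                            n_train: int, rng) -> tuple[list[np.ndarray], list[float]]:
    """Shared mini-batch Adam loop with early stopping on validation loss."""
    opt = ag.Adam(params, lr=config.learning_rate)
    best_val, best_state, since_best = np.inf, [p.data.copy() for p in params], 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = loss_of_batch(idx)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            loss.backward()
            opt.step()
        vl = float(val_loss())
        history.append(vl)
        if vl < best_val - 1e-7:
            best_val, since_best = vl, 0
            best_state = [p.data.copy() for p in params]
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stop at epoch %d (best val %.5f)", epoch, best_val)
                break
    return best_state, history


def pretrain_encoder(encoder: DualPathEncoder, images: np.ndarray,
                     profiles: np.ndarray, targets: np.ndarray,
                     train_idx: np.ndarray, val_idx: np.ndarray,
                     config: ModelConfig) -> tuple[np.ndarray, list[float]]:
    """Pre-train the encoder against the propagated GO labels.

    Returns the frozen concatenated embeddings for every protein (computed
    with the best-validation parameters) and the validation-loss history.
    """
    images = images.astype(np.float32)
    profiles = profiles.astype(np.float32)
    rng = np.random.default_rng(config.seed + 1)

    def loss_of_batch(idx):
        _, logits = encoder.forward(images[idx], profiles[idx])
        return ag.focal_loss(logits, targets[idx],
                             config.focal_gamma, config.focal_alpha)

    def val_loss():
        return _eval_in_batches(
            lambda sl: ag.focal_loss(
                encoder.forward(images[val_idx][sl], profiles[val_idx][sl])[1],
                targets[val_idx][sl], config.focal_gamma, config.focal_alpha
            ).data,
            len(val_idx), config.batch_size,
        )

    best, history = _early_stopped_training(
        loss_of_batch, val_loss, encoder.params, config, len(train_idx), rng
    )
    encoder.set_state(best)
    embs = []
    for start in range(0, len(images), 256):
        emb, _ = encoder.forward(images[start:start + 256],
                                 profiles[start:start + 256])
        embs.append(emb.data)
    return np.concatenate(embs), history


def _eval_in_batches(fn, n, batch):
    vals, weights = [], []
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        vals.append(float(fn(sl)))
        weights.append(sl.stop - sl.start)
    return float(np.average(vals, weights=weights))


def chunk_labels_by_level(label_space: LabelSpace, time_steps: int) -> list[np.ndarray]:
    """Partition label indices into ordered level buckets, shallow to deep.

    Bucket ``t`` (1-based) holds the terms at level ``t + 1`` (roots are
    level 1 and never part of the label space); levels beyond the last
    bucket merge into it.  Empty buckets are kept so the unrolled step
    count always equals ``time_steps``.
    """
    if time_steps < 1:
        raise ValueError("time_steps must be >= 1")
    chunks = [[] for _ in range(time_steps)]
    for i, t in enumerate(label_space.terms):
        lvl = label_space.levels[t]
        chunks[min(max(lvl - 2, 0), time_steps - 1)].append(i)
    return [np.array(c, dtype=int) for c in chunks]


class LevelLSTMDecoder:
    """Three-layer LSTM emitting per-level label chunks step by step."""

    def __init__(self, input_dim: int, chunks: list[np.ndarray], config: ModelConfig):
        self.config = config
        self.chunks = chunks
        self.input_dim = input_dim
        h = config.lstm_units
        rng = np.random.default_rng(config.seed + 2)
        self.layers = []
        for li in range(config.lstm_layers):
            in_dim = input_dim if li == 0 else h
            wx = _he(rng, (in_dim, 4 * h), in_dim)
            wh = _he(rng, (h, 4 * h), h)
            b = Tensor(np.zeros(4 * h, np.float32), requires_grad=True)
            self.layers.append((wx, wh, b))
        self.heads = []
        for c in chunks:
            w = _he(rng, (h, max(len(c), 1)), h)
            b = Tensor(np.zeros(max(len(c), 1), np.float32), requires_grad=True)
            self.heads.append((w, b))

    @property
    def params(self) -> list[Tensor]:
        out = []
        for wx, wh, b in self.layers:
            out += [wx, wh, b]
        for w, b in self.heads:
            out += [w, b]
        return out

    def _cell(self, x, h_prev, c_prev, layer):
        wx, wh, b = layer
        units = self.config.lstm_units
        g = ag.add(ag.add(ag.matmul(x, wx), ag.matmul(h_prev, wh)), b)
        i = ag.sigmoid(ag.narrow(g, 0, units))
        f = ag.sigmoid(ag.narrow(g, units, units))
        o = ag.sigmoid(ag.narrow(g, 2 * units, units))
        c_tilde = ag.tanh(ag.narrow(g, 3 * units, units))
        c = ag.add(ag.mul(f, c_prev), ag.mul(i, c_tilde))
        h = ag.mul(o, ag.tanh(c))
        return h, c

    def forward(self, embeddings: np.ndarray) -> Tensor:
        """Unroll the LSTM; returns logits (n x n_labels) in label order."""
        n = embeddings.shape[0]
        h = self.config.lstm_units
        zeros_x = np.zeros((n, self.input_dim), np.float32)
        states = [
            (Tensor(np.zeros((n, h), np.float32)), Tensor(np.zeros((n, h), np.float32)))
            for _ in self.layers
        ]
        n_labels = sum(len(c) for c in self.chunks)
        step_logits: list[tuple[np.ndarray, Tensor]] = []
        for t, chunk in enumerate(self.chunks):
            x = Tensor(embeddings if (t == 0 or self.config.feed_embedding_every_step)
                       else zeros_x)
            for li, layer in enumerate(self.layers):
                h_state, c_state = states[li]
                h_new, c_new = self._cell(x, h_state, c_state, layer)
                states[li] = (h_new, c_new)
                x = h_new
            if len(chunk):
                w, b = self.heads[t]
                step_logits.append((chunk, ag.add(ag.matmul(x, w), b)))
        # stitch chunk columns back into label order with a constant 0/1
        # matrix; keeps the autograd graph to plain matmuls
        order = np.concatenate([c for c, _ in step_logits])
        cat = ag.concat([lg for _, lg in step_logits], axis=1)
        P = np.zeros((len(order), n_labels), np.float32)
        P[np.arange(len(order)), order] = 1.0
        return ag.matmul(cat, Tensor(P))

    def get_state(self):
        return [p.data.copy() for p in self.params]

    def set_state(self, state):
        for p, s in zip(self.params, state):
            p.data = s.copy()


def train_decoder(decoder: LevelLSTMDecoder, embeddings: np.ndarray,
                  targets: np.ndarray, train_idx: np.ndarray,
                  val_idx: np.ndarray, config: ModelConfig) -> list[float]:
    """Train the LSTM decoder on frozen embeddings with focal loss."""
    embeddings = embeddings.astype(np.float32)
    rng = np.random.default_rng(config.seed + 3)

    def loss_of_batch(idx):
        logits = decoder.forward(embeddings[idx])
        return ag.focal_loss(logits, targets[idx],
                             config.focal_gamma, config.focal_alpha)

    def val_loss():
        return _eval_in_batches(
            lambda sl: ag.focal_loss(
                decoder.forward(embeddings[val_idx][sl]), targets[val_idx][sl],
                config.focal_gamma, config.focal_alpha
            ).data,
            len(val_idx), config.batch_size,
        )

    best, history = _early_stopped_training(
        loss_of_batch, val_loss, decoder.params, config, len(train_idx), rng
    )
    decoder.set_state(best)
    return history


def decoder_scores(decoder: LevelLSTMDecoder, embeddings: np.ndarray) -> np.ndarray:
    out = []
    for start in range(0, len(embeddings), 256):
        logits = decoder.forward(embeddings[start:start + 256].astype(np.float32))
        out.append(1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60))))
    return np.concatenate(out)


def similarity_transfer(distances: np.ndarray, reference_targets: np.ndarray,
                        k: int = 5) -> np.ndarray:
    """k-NN label transfer from cosine-distance profiles.

    ``score(q, t) = sum_{r in kNN(q)} sim(q, r) * y[r, t] / sum sim`` with
    ``sim = clip(1 - distance, 0, 1)``.  Accepts a single profile or a
    stack of them.
    """
    single = distances.ndim == 1
    D = np.atleast_2d(distances)
    n_ref = reference_targets.shape[0]
    if D.shape[1] != n_ref:
        raise ValueError("profile length does not match reference cohort")
    if k > n_ref:
        raise ValueError(f"k={k} exceeds reference cohort size {n_ref}")
    sims = np.clip(1.0 - D, 0.0, 1.0)
    out = np.zeros((len(D), reference_targets.shape[1]))
    for qi, s in enumerate(sims):
        nn = np.argpartition(-s, k - 1)[:k]
        denom = s[nn].sum()
        if denom > 0:
            out[qi] = s[nn] @ reference_targets[nn] / denom
    return out[0] if single else out


def ensemble_combine(dl_scores: np.ndarray, sim_scores: np.ndarray,
                     alpha: float) -> np.ndarray:
    """alpha * deep-learning scores + (1 - alpha) * similarity scores."""
    if dl_scores.shape != sim_scores.shape:
        raise ValueError("score shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * dl_scores + (1.0 - alpha) * sim_scores


def select_alpha(dl_scores: np.ndarray, sim_scores: np.ndarray,
                 targets: np.ndarray, grid=None) -> float:
    """Pick the blend weight maximizing validation Fmax over a grid."""
    from .evaluation import fmax_from_matrices

    grid = np.round(np.arange(0.0, 1.01, 0.1), 2) if grid is None else grid
    best_alpha, best_f = 0.5, -1.0
    for a in grid:
        f, _ = fmax_from_matrices(ensemble_combine(dl_scores, sim_scores, a), targets)
        if f > best_f:
            best_f, best_alpha = f, float(a)
    return best_alpha


def ancestor_map(label_space: LabelSpace, ont: GeneOntologyGraph) -> dict[str, list[str]]:
    """Per term, its is_a ancestors restricted to the label space."""
    in_space = set(label_space.terms)
    return {t: sorted(ont.ancestors(t) & in_space) for t in label_space.terms}


def apply_hierarchical_consistency(scores: np.ndarray, label_space: LabelSpace,
                                   ancestors: dict[str, list[str]]) -> np.ndarray:
    """Enforce score(ancestor) >= score(descendant) by taking the max."""
    idx = label_space.index()
    out = scores.copy()
    # deepest first so maxima percolate upward in one pass
    for t in sorted(label_space.terms, key=lambda t: -label_space.levels[t]):
        ti = idx[t]
        for anc in ancestors.get(t, ()):
            ai = idx.get(anc)
            if ai is not None:
                np.maximum(out[:, ai], out[:, ti], out=out[:, ai])
    return out


def targets_from_annotations(table: AnnotationTable, protein_ids: list[str],
                             label_space: LabelSpace) -> np.ndarray:
    """0/1 target matrix (proteins x label-space terms)."""
    idx = label_space.index()
    y = np.zeros((len(protein_ids), len(label_space)), np.float32)
    rows = {p: i for i, p in enumerate(protein_ids)}
    for pid, term in table.pairs:
        r, c = rows.get(pid), idx.get(term)
        if r is not None and c is not None:
            y[r, c] = 1.0
    return y


@dataclass
class ModelBundle:
    """Everything needed to score new sequences end to end."""

    spec: DescriptorSpec
    reference: DescriptorMatrix
    template: TemplateMap
    encoder: DualPathEncoder
    decoder: LevelLSTMDecoder
    label_space: LabelSpace
    ancestors: dict[str, list[str]]
    reference_targets: np.ndarray
    alpha: float
    config: ModelConfig
    train_history: dict = field(default_factory=dict)


def train_pipeline(records: list[ProteinRecord], annotations: AnnotationTable,
                   ont: GeneOntologyGraph, label_space: LabelSpace,
                   train_idx: np.ndarray, val_idx: np.ndarray,
                   spec: DescriptorSpec | None = None,
                   config: ModelConfig | None = None,
                   method: str = "pca") -> ModelBundle:
    """Representation -> encoder pre-training -> decoder -> blend weight.

    The reference cohort for similarity profiles and the k-NN transfer is
    the training split only, so validation proteins are scored exactly the
    way unseen queries are.
    """
    spec = spec or DescriptorSpec()
    config = config or ModelConfig()
    ids = [r.id for r in records]
    train_records = [records[i] for i in train_idx]
    dm, tm, ref_images, pdm = cohort_representations(
        [r.sequence for r in train_records], [r.id for r in train_records],
        spec, method=method, seed=config.seed,
    )
    # representations for the full cohort against the frozen training reference
    raw_all = descriptor_matrix([r.sequence for r in records], spec)
    norm_all = dm.normalize_query(raw_all)
    images = np.stack([make_feature_map(v, tm, spec) for v in norm_all])
    profiles = np.stack([
        make_similarity_vector(norm_all[i], dm, pdm=pdm,
                               query_id=records[i].id)
        for i in range(len(records))
    ])
    targets = targets_from_annotations(annotations, ids, label_space)
    encoder = build_encoder(len(spec.classes), tm.grid_side, len(train_idx),
                            label_space, config)
    embeddings, enc_hist = pretrain_encoder(
        encoder, images, profiles, targets, train_idx, val_idx, config
    )
    chunks = chunk_labels_by_level(label_space, config.time_steps)
    decoder = LevelLSTMDecoder(encoder.embedding_dim, chunks, config)
    dec_hist = train_decoder(decoder, embeddings, targets, train_idx, val_idx, config)
    dl_val = decoder_scores(decoder, embeddings[val_idx])
    sim_val = similarity_transfer(profiles[val_idx], targets[train_idx],
                                  k=config.knn_k)
    alpha = select_alpha(dl_val, sim_val, targets[val_idx])
    logger.info("ensemble blend alpha=%.1f", alpha)
    return ModelBundle(
        spec=spec, reference=dm, template=tm, encoder=encoder, decoder=decoder,
        label_space=label_space, ancestors=ancestor_map(label_space, ont),
        reference_targets=targets[train_idx], alpha=alpha, config=config,
        train_history={"encoder_val_loss": enc_hist, "decoder_val_loss": dec_hist},
    )


def predict(bundle: ModelBundle, records: list[ProteinRecord]) -> PredictionMatrix:
    """Score query sequences over the bundle's label space."""
    if not records:
        import warnings

        warnings.warn("empty query cohort")
        return PredictionMatrix(
            np.zeros((0, len(bundle.label_space))), [], bundle.label_space
        )
    spec = bundle.spec
    raw = descriptor_matrix([r.sequence for r in records], spec)
    norm = bundle.reference.normalize_query(raw)
    images = np.stack([make_feature_map(v, bundle.template, spec) for v in norm])
    profiles = np.stack([
        make_similarity_vector(norm[i], bundle.reference, query_id=records[i].id)
        for i in range(len(records))
    ])
    emb, _ = bundle.encoder.forward(images.astype(np.float32),
                                    profiles.astype(np.float32))
    dl = decoder_scores(bundle.decoder, emb.data)
    sim = similarity_transfer(profiles, bundle.reference_targets,
                              k=bundle.config.knn_k)
    scores = ensemble_combine(dl, sim, bundle.alpha)
    if bundle.config.hierarchical_consistency:
        scores = apply_hierarchical_consistency(scores, bundle.label_space,
                                                bundle.ancestors)
    scores = np.clip(scores, 0.0, 1.0)
    return PredictionMatrix(scores, [r.id for r in records], bundle.label_space)


# ---------------------------------------------------------------------------
# Bundle persistence (npz arrays + json config)

def save_bundle(directory, bundle: ModelBundle) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    from .featmap import save_representation

    save_representation(d / "representation.h5", bundle.reference, bundle.template)
    np.savez(
        d / "weights.npz",
        *[p.data for p in bundle.encoder.params],
        *[p.data for p in bundle.decoder.params],
        reference_targets=bundle.reference_targets,
    )
    meta = {
        "config": asdict(bundle.config),
        "alpha": bundle.alpha,
        "label_terms": bundle.label_space.terms,
        "label_counts": bundle.label_space.counts,
        "label_levels": bundle.label_space.levels,
        "ancestors": bundle.ancestors,
        "n_encoder_params": len(bundle.encoder.params),
        "train_history": bundle.train_history,
    }
    (d / "bundle.json").write_text(json.dumps(meta))


def load_bundle(directory) -> ModelBundle:
    d = Path(directory)
    from .featmap import load_representation

    dm, tm = load_representation(d / "representation.h5")
    meta = json.loads((d / "bundle.json").read_text())
    cfg_d = dict(meta["config"])
    cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
    config = ModelConfig(**cfg_d)
    label_space = LabelSpace(
        terms=list(meta["label_terms"]),
        counts={t: int(c) for t, c in meta["label_counts"].items()},
        levels={t: int(v) for t, v in meta["label_levels"].items()},
    )
    with np.load(d / "weights.npz") as z:
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        reference_targets = z["reference_targets"]
    encoder = build_encoder(len(dm.spec.classes), tm.grid_side,
                            dm.values.shape[0], label_space, config)
    n_enc = meta["n_encoder_params"]
    encoder.set_state(arrays[:n_enc])
    chunks = chunk_labels_by_level(label_space, config.time_steps)
    decoder = LevelLSTMDecoder(encoder.embedding_dim, chunks, config)
    decoder.set_state(arrays[n_enc:])
    return ModelBundle(
        spec=dm.spec, reference=dm, template=tm, encoder=encoder,
        decoder=decoder, label_space=label_space,
        ancestors={t: list(a) for t, a in meta["ancestors"].items()},
        reference_targets=reference_targets, alpha=float(meta["alpha"]),
        config=config, train_history=meta.get("train_history", {}),
    )
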