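import numpy as np
import pytest

from protofun.network import (
    LevelLSTMDecoder,
    ModelConfig,
    build_encoder,
    chunk_labels_by_level,
    ensemble_combine,
    pretrain_encoder,
    similarity_transfer,
    targets_from_annotations,
)
from protofun.ontology import LabelSpace


def _label_space(levels):
    terms = [f"T:{i}" for i in range(len(levels))]
    return LabelSpace(terms=terms, counts={t: 10 for t in terms},
                      levels=dict(zip(terms, levels)))


class TestConfigDefaults:
    def test_stated_hyperparameters_are_defaults(self):
        c = ModelConfig()
        assert (c.conv_kernel, c.conv_stride) == (3, 1)
        assert c.n_conv_layers == 2
        assert (c.pool_size, c.pool_stride) == (2, 1)
        assert c.fc_layers == 5
        assert (c.lstm_layers, c.lstm_units) == (3, 256)
        assert c.time_steps == 11
        assert c.batch_size == 32
        assert c.learning_rate == 0.0002
        assert (c.focal_gamma, c.focal_alpha) == (2.0, 0.25)

    def test_unsupported_geometry_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(pool_stride=2)


class TestEncoder:
    CFG = ModelConfig(embedding_width=16, conv_filters=(2, 3), max_epochs=60,
                      patience=60, seed=0)

    def test_forward_shapes(self, rng):
        ls = _label_space([2, 2, 3])
        enc = build_encoder(7, 39, 20, ls, self.CFG)
        emb, logits = enc.forward(
            rng.normal(size=(2, 7, 39, 39)).astype(np.float32),
            rng.normal(size=(2, 20)).astype(np.float32),
        )
        assert emb.shape == (2, 32) and logits.shape == (2, 3)

    def test_similarity_path_depth_is_five(self):
        enc = build_encoder(1, 7, 10, _label_space([2]), self.CFG)
        assert len(enc.dnn_ws) == 5

    def test_same_seed_identical_parameters(self):
        ls = _label_space([2, 3])
        a = build_encoder(1, 7, 8, ls, self.CFG)
        b = build_encoder(1, 7, 8, ls, self.CFG)
        for pa, pb in zip(a.params, b.params):
            assert (pa.data == pb.data).all()

    def test_training_decreases_loss_and_is_seed_reproducible(self, rng):
        ls = _label_space([2, 2, 3, 3])
        n = 24
        images = rng.normal(size=(n, 1, 7, 7)).astype(np.float32)
        profiles = rng.normal(size=(n, 6)).astype(np.float32)
        targets = (rng.random((n, 4)) < 0.5).astype(np.float32)
        idx = np.arange(n)
        cfg = ModelConfig(embedding_width=8, conv_filters=(2, 2), max_epochs=5,
                          patience=10, seed=3)
        enc = build_encoder(1, 7, 6, ls, cfg)
        emb1, hist1 = pretrain_encoder(enc, images, profiles, targets, idx, idx, cfg)
        assert hist1[-1] < hist1[0]
        enc2 = build_encoder(1, 7, 6, ls, cfg)
        emb2, hist2 = pretrain_encoder(enc2, images, profiles, targets, idx, idx, cfg)
        assert hist1 == hist2 and (emb1 == emb2).all()
        cfg_b = ModelConfig(embedding_width=8, conv_filters=(2, 2), max_epochs=5,
                            patience=10, seed=4)
        enc3 = build_encoder(1, 7, 6, ls, cfg_b)
        emb3, _ = pretrain_encoder(enc3, images, profiles, targets, idx, idx, cfg_b)
        assert not (emb3 == emb1).all()


class TestLabelChunking:
    def test_levels_map_to_ordered_buckets(self):
        ls = _label_space([2, 3, 4, 4])
        chunks = chunk_labels_by_level(ls, 3)
        assert [c.tolist() for c in chunks] == [[0], [1], [2, 3]]

    def test_single_step_takes_everything(self):
        ls = _label_space([2, 5, 9])
        chunks = chunk_labels_by_level(ls, 1)
        assert chunks[0].tolist() == [0, 1, 2]

    def test_default_time_steps_is_eleven_and_padded_with_empty_chunks(self):
        ls = _label_space([2, 3])
        chunks = chunk_labels_by_level(ls, ModelConfig().time_steps)
        assert len(chunks) == 11
        assert sum(len(c) for c in chunks) == 2


class TestDecoder:
    def test_geometry_under_defaults(self):
        cfg = ModelConfig()
        dec = LevelLSTMDecoder(16, chunk_labels_by_level(_label_space([2, 3]), 11), cfg)
        assert len(dec.layers) == 3
        assert dec.layers[0][1].shape == (256, 4 * 256)  # recurrent weight
        assert len(dec.heads) == 11

    def test_forward_restores_label_order(self, rng):
        cfg = ModelConfig(lstm_units=8, seed=0)
        ls = _label_space([3, 2, 3])  # term order by construction, not level
        dec = LevelLSTMDecoder(4, chunk_labels_by_level(ls, 2), cfg)
        logits = dec.forward(rng.normal(size=(5, 4)).astype(np.float32))
        assert logits.shape == (5, 3)


class TestSimilarityTransfer:
    def test_identical_query_with_k1_copies_labels(self):
        ref_y = np.array([[1, 0, 1], [0, 1, 0]], dtype=float)
        d = np.array([0.0, 0.8])
        assert (similarity_transfer(d, ref_y, k=1) == ref_y[0]).all()

    def test_equal_similarities_give_frequencies(self):
        ref_y = np.array([[1, 0], [1, 1], [0, 1], [0, 1]], dtype=float)
        d = np.full(4, 0.5)
        out = similarity_transfer(d, ref_y, k=4)
        assert np.allclose(out, [0.5, 0.75])

    def test_hand_computed_weighted_scores(self):
        # 5 reference proteins, k=2: neighbors are r0 (sim .9) and r1 (sim .6)
        ref_y = np.array([[1, 0], [1, 1], [0, 1], [0, 0], [0, 0]], dtype=float)
        d = np.array([0.1, 0.4, 0.9, 1.2, 1.5])
        out = similarity_transfer(d, ref_y, k=2)
        assert np.allclose(out, [(0.9 + 0.6) / 1.5, 0.6 / 1.5])

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            similarity_transfer(np.zeros(3), np.zeros((3, 2)), k=4)


class TestEnsemble:
    def test_endpoints_and_midpoint(self, rng):
        a, b = rng.random((3, 4)), rng.random((3, 4))
        assert (ensemble_combine(a, b, 1.0) == a).all()
        assert (ensemble_combine(a, b, 0.0) == b).all()
        assert np.allclose(ensemble_combine(a, b, 0.5), (a + b) / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_combine(np.zeros((2, 2)), np.zeros((2, 3)), 0.5)


def test_targets_from_annotations(toy_ontology, toy_annotations):
    from protofun.ontology import propagate_annotations, select_label_families

    prop = propagate_annotations(toy_annotations, toy_ontology)
    ls = select_label_families(prop, toy_ontology, min_count=1)
    y = targets_from_annotations(prop, ["p1", "p2", "p3"], ls)
    idx = ls.index()
    assert y[0, idx["B:2"]] == 1.0 and y[2, idx["B:2"]] == 1.0
    assert y.shape == (3, len(ls))


def test_hierarchical_consistency_takes_descendant_max(toy_ontology):
    from protofun.network import ancestor_map, apply_hierarchical_consistency

    ls = LabelSpace(
        terms=["B:2", "B:4", "B:5"], counts={},
        levels={"B:2": 2, "B:4": 3, "B:5": 4},
    )
    anc = ancestor_map(ls, toy_ontology)
    scores = np.array([[0.1, 0.2, 0.9]])
    out = apply_hierarchical_consistency(scores, ls, anc)
    assert np.allclose(out, [[0.9, 0.9, 0.9]])
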