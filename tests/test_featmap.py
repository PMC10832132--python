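import itertools

import numpy as np
import pytest

from protofun.descriptors import DescriptorSpec
from protofun.featmap import (
    allocate_coordinates,
    build_template_map,
    default_grid_side,
    feature_distance_matrix,
    load_representation,
    make_feature_map,
    make_similarity_vector,
    normalize_matrix,
    protein_distance_matrix,
    reduce_to_2d,
    save_representation,
    _cell_centers,
    _rescale_unit,
)

AAC_SPEC = DescriptorSpec(classes=("aac",))


def _dm(rng, n=8, spec=AAC_SPEC):
    raw = rng.random((n, spec.total_length)) * 5
    return normalize_matrix(raw, [f"p{i}" for i in range(n)], spec)


class TestNormalization:
    def test_linear_map_endpoints(self):
        raw = np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]])
        with pytest.warns(UserWarning):
            dm = normalize_matrix(raw, ["a", "b", "c"], AAC_SPEC)
        assert np.allclose(dm.values[:, 0], [0.0, 0.5, 1.0])
        assert np.allclose(dm.values[:, 1], 0.0)  # constant column convention

    def test_range_zero_one_on_random_cohort(self, rng):
        dm = _dm(rng, 10)
        assert dm.values.min() == 0.0 and dm.values.max() == 1.0
        assert np.allclose(dm.values.min(axis=0), 0.0)
        assert np.allclose(dm.values.max(axis=0), 1.0)

    def test_query_normalization_reuses_stats_and_clips(self, rng):
        dm = _dm(rng, 6)
        raw_query = dm.feature_max * 2  # beyond the training range
        assert np.allclose(dm.normalize_query(raw_query), 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_matrix(np.array([[1.0, np.nan], [0.0, 1.0]]), ["a", "b"], AAC_SPEC)


class TestDistanceMatrices:
    def test_identical_orthogonal_antipodal(self):
        raw = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]).T  # features as cols
        dm = normalize_matrix(np.array([[1, 1, 0], [0, 0, 1], [0.5, 0.5, 0.5]]),
                              ["a", "b", "c"], AAC_SPEC)
        fdm = feature_distance_matrix(dm)
        assert fdm[0, 1] == pytest.approx(0.0, abs=1e-12)  # identical columns

    def test_cosine_extremes_directly(self):
        from protofun.featmap import _cosine_distance_matrix

        x = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [2.0, 0.0]])
        d = _cosine_distance_matrix(x)
        assert d[0, 1] == pytest.approx(1.0)  # orthogonal
        assert d[0, 2] == pytest.approx(2.0)  # antipodal
        assert d[0, 3] == pytest.approx(0.0)  # same direction

    def test_invariants_on_random_cohorts(self, rng):
        for n in (5, 9):
            dm = _dm(rng, n)
            for mat in (feature_distance_matrix(dm), protein_distance_matrix(dm)):
                assert np.abs(mat - mat.T).max() <= 1e-12
                assert np.allclose(np.diag(mat), 0.0)
                assert mat.min() >= 0.0 and mat.max() <= 2.0

    def test_protein_distances_match_loop_recomputation(self, rng):
        dm = _dm(rng, 6)
        pdm = protein_distance_matrix(dm)
        v = dm.values
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                expected = 1 - v[i] @ v[j] / (
                    np.linalg.norm(v[i]) * np.linalg.norm(v[j])
                )
                assert pdm[i, j] == pytest.approx(expected, abs=1e-12)


class TestReduction:
    def test_determinism(self, rng):
        dm = _dm(rng, 10)
        fdm = feature_distance_matrix(dm)
        a = reduce_to_2d(fdm, "pca", seed=3)
        b = reduce_to_2d(fdm, "pca", seed=3)
        assert (a == b).all()

    def test_collinear_inputs_stay_collinear_under_pca(self):
        # rank-1 row pattern: distance rows are scalar multiples + offset
        base = np.linspace(0, 1, 6)
        fdm = np.outer(np.array([0.0, 1.0, 2.0]), base)
        emb = reduce_to_2d(fdm, "pca", seed=0)
        # verify against a direct eigendecomposition: second component ~ 0
        centered = fdm - fdm.mean(axis=0)
        evals = np.linalg.eigvalsh(centered @ centered.T)
        assert evals[-2] == pytest.approx(0.0, abs=1e-18)
        assert np.abs(emb[:, 1]).max() == pytest.approx(0.0, abs=1e-9)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_to_2d(np.zeros((4, 4)), "tsne", 0)


class TestAllocation:
    def test_corner_points_identity_assignment(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        tm = allocate_coordinates(pts, 2)
        centers = _cell_centers(2)
        cost = sum(
            ((pts[i] - centers[r * 2 + c]) ** 2).sum()
            for i, (r, c) in enumerate(tm.assignment)
        )
        # each corner point lands in its own nearest cell
        for i, (r, c) in enumerate(tm.assignment):
            nearest = np.argmin(((pts[i] - centers) ** 2).sum(axis=1))
            assert nearest == r * 2 + c

    @pytest.mark.parametrize("n,side", [(4, 2), (5, 3), (6, 3)])
    def test_matches_exhaustive_enumeration(self, rng, n, side):
        pts = rng.random((n, 2))
        tm = allocate_coordinates(pts, side)
        centers = _cell_centers(side)
        scaled = _rescale_unit(pts)
        our_cost = sum(
            ((scaled[i] - centers[r * side + c]) ** 2).sum()
            for i, (r, c) in enumerate(tm.assignment)
        )
        best = min(
            sum(((scaled[i] - centers[cell]) ** 2).sum()
                for i, cell in enumerate(perm))
            for perm in itertools.permutations(range(side * side), n)
        )
        assert our_cost == pytest.approx(best, abs=1e-12)

    def test_never_worse_than_random_injections(self, rng):
        n, side = 50, 8
        pts = rng.random((n, 2))
        tm = allocate_coordinates(pts, side)
        centers = _cell_centers(side)
        scaled = _rescale_unit(pts)
        cells = tm.assignment[:, 0] * side + tm.assignment[:, 1]
        our_cost = ((scaled - centers[cells]) ** 2).sum()
        for _ in range(1000):
            perm = rng.permutation(side * side)[:n]
            assert our_cost <= ((scaled - centers[perm]) ** 2).sum() + 1e-12

    def test_infeasible_grid_suggests_side(self):
        with pytest.raises(ValueError, match="5"):
            allocate_coordinates(np.random.rand(20, 2), 4)

    def test_default_grid_side_for_published_feature_count(self):
        assert default_grid_side(1484) == 39
        assert default_grid_side(20) == 5


class TestTemplateAndRepresentations:
    def test_template_map_properties(self, rng):
        dm = _dm(rng, 12)
        tm = build_template_map(dm, seed=1)
        assert tm.grid_side == 5  # ceil(sqrt(20))
        assert len({tuple(rc) for rc in tm.assignment}) == 20

    def test_rerun_same_seed_identical(self, rng):
        raw = rng.random((12, 20))
        ids = [f"p{i}" for i in range(12)]
        a = build_template_map(normalize_matrix(raw, ids, AAC_SPEC), seed=5)
        b = build_template_map(normalize_matrix(raw, ids, AAC_SPEC), seed=5)
        assert (a.assignment == b.assignment).all()

    def test_feature_map_channels_and_partition(self, rng):
        dm = _dm(rng, 8)
        tm = build_template_map(dm, seed=0)
        img = make_feature_map(dm.values[0], tm, AAC_SPEC)
        assert img.shape == (1, 5, 5)
        assert (img > 0).sum() == (dm.values[0] > 0).sum()

    def test_all_zero_vector_gives_zero_image(self, rng):
        dm = _dm(rng, 8)
        tm = build_template_map(dm, seed=0)
        assert make_feature_map(np.zeros(20), tm, AAC_SPEC).sum() == 0.0

    def test_similarity_vector_of_reference_protein_is_pdm_column(self, rng):
        dm = _dm(rng, 7)
        pdm = protein_distance_matrix(dm)
        v = make_similarity_vector(dm.values[3], dm, pdm=pdm, query_id="p3")
        assert np.allclose(v, pdm[:, 3])
        assert v[3] == 0.0

    def test_query_similarity_matches_loop_oracle(self, rng):
        dm = _dm(rng, 10)
        q = rng.random(20)
        v = make_similarity_vector(q, dm)
        for j in range(10):
            ref = dm.values[j]
            expected = 1 - q @ ref / (np.linalg.norm(q) * np.linalg.norm(ref))
            assert v[j] == pytest.approx(expected, abs=1e-12)

    def test_serialization_roundtrip_exact(self, rng, tmp_path):
        dm = _dm(rng, 8)
        tm = build_template_map(dm, seed=2)
        path = tmp_path / "rep.h5"
        save_representation(path, dm, tm)
        dm2, tm2 = load_representation(path)
        assert (dm2.values == dm.values).all()
        assert (tm2.assignment == tm.assignment).all()
        assert dm2.spec == dm.spec
        img_a = make_feature_map(dm.values[1], tm, AAC_SPEC)
        img_b = make_feature_map(dm2.values[1], tm2, dm2.spec)
        assert (img_a == img_b).all()
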