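"""Multi-scale protein representation.

Turns a cohort descriptor matrix into

* a frozen **template map** — an injective assignment of every descriptor
  to a cell of a square grid, obtained by min-max normalization, cosine
  feature-distance computation, 2-D reduction (PCA or UMAP) and optimal
  linear-sum assignment of the embedded features to grid-cell centers; and
* per-protein representations: the **feature-map image** (one channel per
  descriptor class, normalized intensities placed at the template cells)
  and the **similarity profile** (cosine distances to a fixed reference
  cohort).

With the default 1,484-feature spec the grid side is
``ceil(sqrt(1484)) = 39``, i.e. a 39 x 39 template with 37 empty cells.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment

from .descriptors import DescriptorSpec, descriptor_matrix

logger = logging.getLogger("protofun")


@dataclass
class DescriptorMatrix:
    """Cohort x feature table with its normalization state."""

    values: np.ndarray  # n_proteins x n_features, normalized to [0, 1]
    protein_ids: list[str]
    spec: DescriptorSpec
    feature_min: np.ndarray
    feature_max: np.ndarray

    def normalize_query(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored min-max transform to raw query descriptors."""
        span = self.feature_max - self.feature_min
        safe = np.where(span == 0, 1.0, span)
        out = (raw - self.feature_min) / safe
        out[..., span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def normalize_matrix(
    raw: np.ndarray, protein_ids: list[str], spec: DescriptorSpec
) -> DescriptorMatrix:
    """Per-feature min-max normalization across the cohort.

    ``x_norm = (x - min_f) / (max_f - min_f)`` with the min/max taken per
    feature over proteins.  Constant features map to 0 (with a warning);
    the min/max are stored for reuse on query proteins.
    """
    if raw.ndim != 2 or raw.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 proteins")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite descriptor values")
    fmin, fmax = raw.min(axis=0), raw.max(axis=0)
    span = fmax - fmin
    n_const = int((span == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant feature(s) normalized to 0")
    safe = np.where(span == 0, 1.0, span)
    vals = (raw - fmin) / safe
    vals[:, span == 0] = 0.0
    return DescriptorMatrix(vals, list(protein_ids), spec, fmin, fmax)


def _cosine_distance_matrix(x: np.ndarray) -> np.ndarray:
    """1 - cosine similarity between rows; zero-norm rows get distance 1."""
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d zero-norm vector(s): distance 1 by convention", zero.sum())
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    d = 1.0 - unit @ unit.T
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


def feature_distance_matrix(dm: DescriptorMatrix) -> np.ndarray:
    """Pairwise cosine distances among features (columns of the matrix)."""
    return _cosine_distance_matrix(dm.values.T)


def protein_distance_matrix(dm: DescriptorMatrix) -> np.ndarray:
    """Pairwise cosine distances among proteins (rows of the matrix)."""
    return _cosine_distance_matrix(dm.values)


def reduce_to_2d(fdm: np.ndarray, method: str = "pca", seed: int = 0) -> np.ndarray:
    """Project the feature-distance matrix to 2-D coordinates per feature.

    PCA treats each feature's distance profile (its FDM row) as a vector;
    UMAP consumes the distance matrix directly (metric="precomputed").
    """
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed).fit_transform(fdm)
    if method == "umap":
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = umap.UMAP(
                n_components=2,
                n_neighbors=15,
                min_dist=0.1,
                metric="precomputed",
                random_state=seed,
            ).fit_transform(fdm)
        return np.asarray(emb, dtype=float)
    raise ValueError(f"unknown reduction method {method!r}")


@dataclass
class TemplateMap:
    """Frozen injective map from feature index to a grid cell."""

    grid_side: int
    assignment: np.ndarray  # n_features x 2 (row, col)
    embedding: np.ndarray  # n_features x 2
    method: str
    seed: int

    def __post_init__(self):
        n = len(self.assignment)
        if self.grid_side**2 < n:
            raise ValueError("grid too small for feature count")
        cells = {(int(r), int(c)) for r, c in self.assignment}
        if len(cells) != n:
            raise ValueError("assignment not injective")
        if self.assignment.min() < 0 or self.assignment.max() >= self.grid_side:
            raise ValueError("cell outside grid")


def default_grid_side(n_features: int) -> int:
    """Smallest square grid holding every feature: ceil(sqrt(n))."""
    return math.ceil(math.sqrt(n_features))


def _cell_centers(grid_side: int) -> np.ndarray:
    """Cell centers on the unit square, row-major order."""
    step = 1.0 / grid_side
    rc = np.indices((grid_side, grid_side)).reshape(2, -1).T
    return (rc + 0.5) * step


def _rescale_unit(points: np.ndarray) -> np.ndarray:
    lo, hi = points.min(axis=0), points.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    return (points - lo) / span


def allocate_coordinates(embedding: np.ndarray, grid_side: int) -> TemplateMap:
    """Optimally assign embedded features to distinct grid cells.

    Solves the rectangular linear-sum assignment problem minimizing total
    squared Euclidean distance between each min-max-rescaled embedding
    point and its cell center on the unit square (Jonker-Volgenant style
    solver from scipy).  The returned assignment attains the global
    optimum of that cost.
    """
    n = len(embedding)
    if grid_side**2 < n:
        raise ValueError(
            f"grid {grid_side}x{grid_side} < {n} features; "
            f"need side >= {default_grid_side(n)}"
        )
    pts = _rescale_unit(np.asarray(embedding, dtype=float))
    centers = _cell_centers(grid_side)
    cost = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows)
    cells = cols[order]
    assignment = np.stack([cells // grid_side, cells % grid_side], axis=1)
    return TemplateMap(
        grid_side=grid_side,
        assignment=assignment,
        embedding=np.asarray(embedding, dtype=float),
        method="unspecified",
        seed=-1,
    )


def build_template_map(
    dm: DescriptorMatrix,
    method: str = "pca",
    seed: int = 0,
    grid_side: int | None = None,
) -> TemplateMap:
    """Normalized cohort matrix -> frozen template map."""
    fdm = feature_distance_matrix(dm)
    emb = reduce_to_2d(fdm, method=method, seed=seed)
    side = grid_side or default_grid_side(emb.shape[0])
    tm = allocate_coordinates(emb, side)
    tm.method = method
    tm.seed = seed
    return tm


def make_feature_map(
    normalized_vector: np.ndarray, template: TemplateMap, spec: DescriptorSpec
) -> np.ndarray:
    """Render one protein's multi-channel feature-map image.

    Channel order follows the spec's class order; channel c holds the
    normalized intensities of class-c features at their template cells.
    """
    n_features = spec.total_length
    if len(template.assignment) != n_features:
        raise ValueError("template map does not match descriptor spec")
    if len(normalized_vector) != n_features:
        raise ValueError("vector length does not match spec")
    side = template.grid_side
    img = np.zeros((len(spec.classes), side, side))
    for ci, cname in enumerate(spec.classes):
        sl = spec.slices[cname]
        rows = template.assignment[sl, 0]
        cols = template.assignment[sl, 1]
        img[ci, rows, cols] = normalized_vector[sl]
    return img


def make_similarity_vector(
    query_normalized: np.ndarray,
    reference: DescriptorMatrix,
    pdm: np.ndarray | None = None,
    query_id: str | None = None,
) -> np.ndarray:
    """Cosine-distance profile of a protein against the reference cohort.

    A reference protein's profile is its column of the protein-distance
    matrix; a new protein's profile applies the same cosine-distance
    formula against every reference row.
    """
    if reference.values.shape[0] == 0:
        raise ValueError("empty reference cohort")
    if query_id is not None and query_id in reference.protein_ids:
        if pdm is None:
            pdm = protein_distance_matrix(reference)
        return pdm[:, reference.protein_ids.index(query_id)].copy()
    q = np.asarray(query_normalized, dtype=float)
    qn = np.linalg.norm(q)
    rn = np.linalg.norm(reference.values, axis=1)
    if qn == 0:
        return np.ones(len(rn))
    sims = np.where(
        rn == 0, 0.0, reference.values @ q / (np.where(rn == 0, 1.0, rn) * qn)
    )
    return np.clip(1.0 - sims, 0.0, 2.0)


def cohort_representations(
    sequences: list[str],
    protein_ids: list[str],
    spec: DescriptorSpec | None = None,
    method: str = "pca",
    seed: int = 0,
):
    """Full representation pipeline for a training cohort.

    Returns ``(descriptor_matrix, template_map, images, similarity_profiles)``
    where images is ``n x channels x side x side`` and the similarity
    profiles are the columns of the protein-distance matrix.
    """
    spec = spec or DescriptorSpec()
    raw = descriptor_matrix(sequences, spec)
    dm = normalize_matrix(raw, protein_ids, spec)
    tm = build_template_map(dm, method=method, seed=seed)
    images = np.stack([make_feature_map(row, tm, spec) for row in dm.values])
    pdm = protein_distance_matrix(dm)
    return dm, tm, images, pdm


# ---------------------------------------------------------------------------
# Persistence (HDF5)

def save_representation(path, dm: DescriptorMatrix, tm: TemplateMap) -> None:
    import dataclasses as _dc

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=dm.values)
        f.create_dataset("feature_min", data=dm.feature_min)
        f.create_dataset("feature_max", data=dm.feature_max)
        f.create_dataset(
            "protein_ids",
            data=np.array(dm.protein_ids, dtype=h5py.string_dtype()),
        )
        f.attrs["spec"] = json.dumps(_dc.asdict(dm.spec))
        g = f.create_group("template")
        g.create_dataset("assignment", data=tm.assignment)
        g.create_dataset("embedding", data=tm.embedding)
        g.attrs["grid_side"] = tm.grid_side
        g.attrs["method"] = tm.method
        g.attrs["seed"] = tm.seed


def load_representation(path) -> tuple[DescriptorMatrix, TemplateMap]:
    with h5py.File(path, "r") as f:
        spec_d = json.loads(f.attrs["spec"])
        for k in ("classes", "autocorr_scales"):
            spec_d[k] = tuple(spec_d[k])
        spec = DescriptorSpec(**spec_d)
        dm = DescriptorMatrix(
            values=f["values"][()],
            protein_ids=[s.decode() for s in f["protein_ids"][()]],
            spec=spec,
            feature_min=f["feature_min"][()],
            feature_max=f["feature_max"][()],
        )
        g = f["template"]
        tm = TemplateMap(
            grid_side=int(g.attrs["grid_side"]),
            assignment=g["assignment"][()],
            embedding=g["embedding"][()],
            method=str(g.attrs["method"]),
            seed=int(g.attrs["seed"]),
        )
    return dm, tm
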