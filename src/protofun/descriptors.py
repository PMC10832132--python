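"""Sequence descriptors: the seven-class, 1,484-dimensional feature vector.

Default class inventory (order fixed; it defines the image channel order
downstream):

====================  ======  =============================================
class                 length  definition
====================  ======  =============================================
aac                       20  amino-acid composition
paac                      50  type-I pseudo amino-acid composition, lam=30
apaac                     80  amphiphilic pseudo-AAC, lam=30 (2*lam terms)
autocorrelation          720  Moreau-Broto/Moran/Geary x 8 scales x 30 lags
qso                      124  quasi-sequence-order, max lag 21, 2 matrices
physicochemical_ctd      147  composition/transition/distribution, 7 groups
molecular_interaction    343  conjoint triad over the 7-cluster alphabet
====================  ======  =============================================

Lengths sum to 1,484.  The per-class parameters are configurable through
:class:`DescriptorSpec`; lengths are recomputed from the parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._aadata import (
    AA_INDEX,
    ALPHABET,
    AUTOCORRELATION_SCALES,
    CTD_GROUPS,
    PAAC_SCALES,
    TRIAD_CLUSTER_OF,
    grantham_distance_matrix,
    physicochemical_distance_matrix,
    standardize,
)

logger = logging.getLogger("protofun")

_CLASS_NAMES = (
    "aac",
    "paac",
    "apaac",
    "autocorrelation",
    "qso",
    "physicochemical_ctd",
    "molecular_interaction_triad",
)


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorSpec:
    """Ordered descriptor-class inventory with per-class parameters."""

    classes: tuple[str, ...] = _CLASS_NAMES
    paac_lambda: int = 30
    paac_weight: float = 0.05
    apaac_lambda: int = 30
    apaac_weight: float = 0.05
    autocorr_max_lag: int = 30
    autocorr_scales: tuple[str, ...] = tuple(AUTOCORRELATION_SCALES)
    qso_max_lag: int = 21
    qso_weight: float = 0.1

    def __post_init__(self):
        unknown = set(self.classes) - set(_CLASS_NAMES)
        if unknown:
            raise DescriptorError(f"unknown descriptor classes: {sorted(unknown)}")

    def class_length(self, name: str) -> int:
        if name == "aac":
            return 20
        if name == "paac":
            return 20 + self.paac_lambda
        if name == "apaac":
            return 20 + 2 * self.apaac_lambda
        if name == "autocorrelation":
            return 3 * len(self.autocorr_scales) * self.autocorr_max_lag
        if name == "qso":
            # coupling numbers + quasi-sequence-order terms, two matrices
            return 2 * self.qso_max_lag + 2 * (20 + self.qso_max_lag)
        if name == "physicochemical_ctd":
            return 21 * len(CTD_GROUPS)
        if name == "molecular_interaction_triad":
            return 343
        raise DescriptorError(f"unknown class {name!r}")

    @property
    def total_length(self) -> int:
        return sum(self.class_length(c) for c in self.classes)

    @property
    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for c in self.classes:
            n = self.class_length(c)
            out[c] = slice(start, start + n)
            start += n
        return out

    @property
    def min_sequence_length(self) -> int:
        """Shortest sequence every class in the spec accepts."""
        need = 1
        if "paac" in self.classes:
            need = max(need, self.paac_lambda + 1)
        if "apaac" in self.classes:
            need = max(need, self.apaac_lambda + 1)
        if "autocorrelation" in self.classes:
            need = max(need, self.autocorr_max_lag + 1)
        if "qso" in self.classes:
            need = max(need, self.qso_max_lag + 1)
        if "physicochemical_ctd" in self.classes:
            need = max(need, 2)
        if "molecular_interaction_triad" in self.classes:
            need = max(need, 3)
        return need


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray
    spec: DescriptorSpec

    def __post_init__(self):
        if len(self.values) != self.spec.total_length:
            raise DescriptorError(
                f"vector length {len(self.values)} != spec total "
                f"{self.spec.total_length}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DescriptorError("non-finite descriptor values")


def _indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in sequence], dtype=np.int64)
    except KeyError as e:
        raise DescriptorError(f"non-canonical residue {e.args[0]!r}") from None


def compute_aac(sequence: str) -> np.ndarray:
    """Frequencies of the 20 canonical residues (sums to 1)."""
    if not sequence:
        raise DescriptorError("empty sequence")
    idx = _indices(sequence)
    return np.bincount(idx, minlength=20) / len(sequence)


def _paac_theta(idx: np.ndarray, lam: int, props: list[np.ndarray]) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    Theta(i, j) is the mean squared difference of the standardized property
    values of residues i and j over the supplied property scales.
    """
    L = len(idx)
    tracks = np.stack([p[idx] for p in props])  # n_props x L
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diff = tracks[:, k:] - tracks[:, :-k]
        theta[k - 1] = np.mean(diff**2, axis=0).sum() / (L - k)
    return theta


def compute_paac(sequence: str, lam: int = 30, w: float = 0.05) -> np.ndarray:
    """Type-I pseudo amino-acid composition: 20 + lam values summing to 1."""
    if len(sequence) <= lam:
        raise DescriptorError(
            f"sequence length {len(sequence)} <= lambda {lam}; shorten lambda"
        )
    idx = _indices(sequence)
    freq = np.bincount(idx, minlength=20).astype(float)
    freq /= freq.sum()
    if lam == 0:
        return freq
    props = [standardize(p) for p in PAAC_SCALES]
    theta = _paac_theta(idx, lam, props)
    denom = 1.0 + w * theta.sum()
    return np.concatenate([freq, w * theta]) / denom


def compute_apaac(sequence: str, lam: int = 30, w: float = 0.05) -> np.ndarray:
    """Amphiphilic pseudo-AAC: 20 + 2*lam values.

    The 2*lam correlation factors alternate hydrophobicity and
    hydrophilicity products; these are signed, so unlike type-I PAAC the
    tail entries may be negative.
    """
    if len(sequence) <= lam:
        raise DescriptorError(
            f"sequence length {len(sequence)} <= lambda {lam}; shorten lambda"
        )
    idx = _indices(sequence)
    freq = np.bincount(idx, minlength=20).astype(float)
    freq /= freq.sum()
    if lam == 0:
        return freq
    h1 = standardize(PAAC_SCALES[0])[idx]
    h2 = standardize(PAAC_SCALES[1])[idx]
    L = len(idx)
    tau = np.empty(2 * lam)
    for k in range(1, lam + 1):
        tau[2 * k - 2] = (h1[:-k] * h1[k:]).sum() / (L - k)
        tau[2 * k - 1] = (h2[:-k] * h2[k:]).sum() / (L - k)
    denom = 1.0 + w * tau.sum()
    return np.concatenate([freq, w * tau]) / denom


def compute_autocorrelation(
    sequence: str,
    scales: dict[str, np.ndarray] | None = None,
    max_lag: int = 30,
) -> np.ndarray:
    """Moreau-Broto (normalized), Moran and Geary autocorrelations.

    Output order: type-major — all Moreau-Broto terms (scale-major, lags
    1..max_lag within a scale), then all Moran, then all Geary.  A realized
    property track with zero variance makes Moran/Geary undefined; those
    entries are set to 0 and a debug message logged.
    """
    scales = AUTOCORRELATION_SCALES if scales is None else scales
    L = len(sequence)
    if L <= max_lag:
        raise DescriptorError(f"sequence length {L} <= max lag {max_lag}")
    idx = _indices(sequence)
    mb, moran, geary = [], [], []
    for name, scale in scales.items():
        p = standardize(scale)[idx]
        pbar = p.mean()
        var = ((p - pbar) ** 2).sum()
        if var / L < 1e-12:  # constant track up to rounding
            var = 0.0
        if var == 0.0:
            logger.debug("zero-variance track for scale %s; Moran/Geary -> 0", name)
        for d in range(1, max_lag + 1):
            a, b = p[:-d], p[d:]
            mb.append((a * b).sum() / (L - d))
            if var == 0.0:
                moran.append(0.0)
                geary.append(0.0)
            else:
                moran.append(
                    (((a - pbar) * (b - pbar)).sum() / (L - d)) / (var / L)
                )
                geary.append(
                    (((a - b) ** 2).sum() / (2 * (L - d))) / (var / (L - 1))
                )
    return np.array(mb + moran + geary)


def compute_ctd(sequence: str, groups: dict | None = None) -> np.ndarray:
    """Composition / transition / distribution over 3-class groupings.

    Per property group: 3 composition + 3 transition + 15 distribution
    (for each class: relative positions of the first, 25%, 50%, 75% and
    last occurrence) = 21 values; 7 groups -> 147.
    """
    groups = CTD_GROUPS if groups is None else groups
    L = len(sequence)
    if L < 2:
        raise DescriptorError("sequence shorter than 2: transitions undefined")
    out = []
    for gname, classes in groups.items():
        cls_of = {aa: ci for ci, grp in enumerate(classes) for aa in grp}
        track = np.array([cls_of[a] for a in sequence])
        comp = np.bincount(track, minlength=3) / L
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        trans = np.zeros(3)
        for a, b in zip(track[:-1], track[1:]):
            if a != b:
                trans[pairs[(min(a, b), max(a, b))]] += 1
        trans /= L - 1
        dist = np.zeros((3, 5))
        for ci in range(3):
            pos = np.nonzero(track == ci)[0]
            if len(pos):
                qs = [0.0, 0.25, 0.50, 0.75, 1.0]
                picks = [pos[min(int(np.ceil(q * len(pos))) - 1, len(pos) - 1)]
                         if q > 0 else pos[0] for q in qs]
                dist[ci] = (np.array(picks) + 1) / L
        out.append(np.concatenate([comp, trans, dist.ravel()]))
    return np.concatenate(out)


def compute_conjoint_triad(sequence: str) -> np.ndarray:
    """Normalized frequencies of the 7^3 reduced-alphabet triads."""
    L = len(sequence)
    if L < 3:
        raise DescriptorError("sequence shorter than 3: no triads")
    track = np.array([TRIAD_CLUSTER_OF[a] for a in sequence])
    codes = track[:-2] * 49 + track[1:-1] * 7 + track[2:]
    return np.bincount(codes, minlength=343) / (L - 2)


def compute_qso(
    sequence: str, max_lag: int = 21, w: float = 0.1
) -> np.ndarray:
    """Quasi-sequence-order descriptors over two residue-distance matrices.

    For each matrix: max_lag sequence-order coupling numbers
    ``tau_d = sum_i d(R_i, R_{i+d})^2`` followed by 20 + max_lag
    quasi-sequence-order terms (composition then coupling, jointly
    normalized with weight w).  Matrices: Grantham chemical distance and a
    physicochemical distance over hydropathy/hydrophilicity/mass.
    Layout: couplings for both matrices first, then QSO terms for both.
    """
    L = len(sequence)
    if L <= max_lag:
        raise DescriptorError(f"sequence length {L} <= max lag {max_lag}")
    idx = _indices(sequence)
    freq = np.bincount(idx, minlength=20).astype(float)
    matrices = (grantham_distance_matrix(), physicochemical_distance_matrix())
    couplings, qso_terms = [], []
    for dm in matrices:
        tau = np.array(
            [np.sum(dm[idx[:-d], idx[d:]] ** 2) for d in range(1, max_lag + 1)]
        )
        couplings.append(tau)
        denom = freq.sum() + w * tau.sum()
        qso_terms.append(np.concatenate([freq, w * tau]) / denom)
    return np.concatenate(couplings + qso_terms)


def assemble_descriptor_vector(
    sequence: str, spec: DescriptorSpec | None = None
) -> DescriptorVector:
    """Concatenate every class in spec order into one feature vector."""
    spec = spec or DescriptorSpec()
    if len(sequence) < spec.min_sequence_length:
        raise DescriptorError(
            f"sequence length {len(sequence)} below spec minimum "
            f"{spec.min_sequence_length}"
        )
    parts = []
    for cname in spec.classes:
        try:
            if cname == "aac":
                v = compute_aac(sequence)
            elif cname == "paac":
                v = compute_paac(sequence, spec.paac_lambda, spec.paac_weight)
            elif cname == "apaac":
                v = compute_apaac(sequence, spec.apaac_lambda, spec.apaac_weight)
            elif cname == "autocorrelation":
                v = compute_autocorrelation(
                    sequence,
                    {k: AUTOCORRELATION_SCALES[k] for k in spec.autocorr_scales},
                    spec.autocorr_max_lag,
                )
            elif cname == "qso":
                v = compute_qso(sequence, spec.qso_max_lag, spec.qso_weight)
            elif cname == "physicochemical_ctd":
                v = compute_ctd(sequence)
            else:
                v = compute_conjoint_triad(sequence)
        except DescriptorError as e:
            raise DescriptorError(f"[{cname}] {e}") from e
        parts.append(v)
    return DescriptorVector(np.concatenate(parts), spec)


def descriptor_matrix(sequences: list[str], spec: DescriptorSpec | None = None) -> np.ndarray:
    """Stack :func:`assemble_descriptor_vector` over a cohort (rows=proteins)."""
    spec = spec or DescriptorSpec()
    return np.stack([assemble_descriptor_vector(s, spec).values for s in sequences])
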