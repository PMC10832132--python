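"""Amino-acid property tables used by the sequence descriptors.

All tables are keyed over the 20 canonical residues in the fixed order
``ACDEFGHIKLMNPQRSTVWY``.  Values are published physicochemical scales
(sources named per table); they ship in-source so the package works
without any network access.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Kyte & Doolittle hydropathy
HYDROPATHY_KD = np.array([
    1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
    1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3,
])

# Hopp & Woods hydrophilicity
HYDROPHILICITY_HW = np.array([
    -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
    -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3,
])

# Monoisotopic-free average residue mass (Da)
RESIDUE_MASS = np.array([
    71.0788, 103.1388, 115.0886, 129.1155, 147.1766, 57.0519, 137.1411,
    113.1594, 128.1741, 113.1594, 131.1926, 114.1038, 97.1167, 128.1307,
    156.1875, 87.0782, 101.1051, 99.1326, 186.2132, 163.1760,
])

# Grantham (1974) side-chain properties: composition, polarity, volume
GRANTHAM_COMPOSITION = np.array([
    0.0, 2.75, 1.38, 0.92, 0.0, 0.74, 0.58, 0.0, 0.33, 0.0,
    0.0, 1.33, 0.39, 0.89, 0.65, 1.42, 0.71, 0.0, 0.13, 0.20,
])
GRANTHAM_POLARITY = np.array([
    8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
    5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2,
])
GRANTHAM_VOLUME = np.array([
    31.0, 55.0, 54.0, 83.0, 132.0, 3.0, 96.0, 111.0, 119.0, 111.0,
    105.0, 56.0, 32.5, 85.0, 124.0, 32.0, 61.0, 84.0, 170.0, 136.0,
])

# Isoelectric point of the free amino acid
ISOELECTRIC_POINT = np.array([
    6.00, 5.07, 2.77, 3.22, 5.48, 5.97, 7.59, 6.02, 9.74, 5.98,
    5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.60, 5.96, 5.89, 5.66,
])

# Bhaskaran & Ponnuswamy average flexibility index
FLEXIBILITY_BP = np.array([
    0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462, 0.466, 0.365,
    0.295, 0.463, 0.509, 0.493, 0.529, 0.507, 0.444, 0.386, 0.305, 0.420,
])

#: Default 8 property scales for the autocorrelation descriptor class.
AUTOCORRELATION_SCALES: dict[str, np.ndarray] = {
    "hydropathy_kd": HYDROPATHY_KD,
    "hydrophilicity_hw": HYDROPHILICITY_HW,
    "residue_mass": RESIDUE_MASS,
    "polarity_grantham": GRANTHAM_POLARITY,
    "composition_grantham": GRANTHAM_COMPOSITION,
    "volume_grantham": GRANTHAM_VOLUME,
    "isoelectric_point": ISOELECTRIC_POINT,
    "flexibility_bp": FLEXIBILITY_BP,
}

#: Pseudo amino-acid composition property triple (Chou's convention:
#: hydrophobicity, hydrophilicity, side-chain mass).
PAAC_SCALES = (HYDROPATHY_KD, HYDROPHILICITY_HW, RESIDUE_MASS)


def standardize(scale: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd standardization over the 20-letter alphabet."""
    return (scale - scale.mean()) / scale.std()


def grantham_distance_matrix() -> np.ndarray:
    """Residue distance recomputed from Grantham's chemical-distance formula.

    ``D_ij = rho * sqrt(1.833 dc^2 + 0.1018 dp^2 + 0.000399 dv^2)`` with the
    scale ``rho`` fixed so the mean off-diagonal distance is 100, matching
    Grantham's published normalization.
    """
    c, p, v = GRANTHAM_COMPOSITION, GRANTHAM_POLARITY, GRANTHAM_VOLUME
    dc = c[:, None] - c[None, :]
    dp = p[:, None] - p[None, :]
    dv = v[:, None] - v[None, :]
    raw = np.sqrt(1.833 * dc**2 + 0.1018 * dp**2 + 0.000399 * dv**2)
    off = raw[~np.eye(20, dtype=bool)]
    return raw * (100.0 / off.mean())


def physicochemical_distance_matrix() -> np.ndarray:
    """Euclidean residue distance over standardized hydropathy,
    hydrophilicity and residue mass, rescaled to max 1.

    Serves as the second distance scale for the quasi-sequence-order
    descriptors alongside the Grantham matrix.
    """
    props = np.stack([standardize(s) for s in PAAC_SCALES])  # 3 x 20
    d = np.sqrt(((props[:, :, None] - props[:, None, :]) ** 2).mean(axis=0))
    return d / d.max()


# Composition/transition/distribution groupings: 7 properties, 3 classes
# each (Dubchak's convention).
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Conjoint-triad 7-cluster reduced alphabet (Shen's convention).
TRIAD_CLUSTERS = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

TRIAD_CLUSTER_OF = {aa: ci for ci, grp in enumerate(TRIAD_CLUSTERS) for aa in grp}

#: Default substitutions for ambiguous / non-canonical residues.
NONCANONICAL_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}
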