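"""Independent, literal-from-formula reference implementations.

Deliberately naive (explicit Python loops, no vectorization, no shared
code with the package) so they serve as oracles for the descriptor and
metric implementations.
"""

import math

from protofun._aadata import (
    ALPHABET,
    PAAC_SCALES,
    TRIAD_CLUSTERS,
    grantham_distance_matrix,
    physicochemical_distance_matrix,
)


def _std(scale):
    m = sum(scale) / 20.0
    sd = math.sqrt(sum((v - m) ** 2 for v in scale) / 20.0)
    return {aa: (v - m) / sd for aa, v in zip(ALPHABET, scale)}


def paac_reference(seq, lam, w):
    """Chou's type-I pseudo-AAC, straight from the defining equations."""
    props = [_std(list(s)) for s in PAAC_SCALES]
    L = len(seq)
    freq = [seq.count(aa) / L for aa in ALPHABET]

    def theta_pair(a, b):
        return sum((p[b] - p[a]) ** 2 for p in props) / len(props)

    thetas = []
    for k in range(1, lam + 1):
        thetas.append(
            sum(theta_pair(seq[i], seq[i + k]) for i in range(L - k)) / (L - k)
        )
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freq] + [w * t / denom for t in thetas]


def apaac_reference(seq, lam, w):
    h1 = _std(list(PAAC_SCALES[0]))
    h2 = _std(list(PAAC_SCALES[1]))
    L = len(seq)
    freq = [seq.count(aa) / L for aa in ALPHABET]
    taus = []
    for k in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + k]] for i in range(L - k)) / (L - k))
        taus.append(sum(h2[seq[i]] * h2[seq[i + k]] for i in range(L - k)) / (L - k))
    denom = 1.0 + w * sum(taus)
    return [f / denom for f in freq] + [w * t / denom for t in taus]


def autocorrelation_reference(seq, scale, max_lag):
    """Normalized Moreau-Broto, Moran and Geary for one property scale."""
    p = _std(list(scale))
    x = [p[a] for a in seq]
    L = len(x)
    xbar = sum(x) / L
    var_n = sum((v - xbar) ** 2 for v in x) / L
    var_n1 = sum((v - xbar) ** 2 for v in x) / (L - 1)
    mb, moran, geary = [], [], []
    for d in range(1, max_lag + 1):
        mb.append(sum(x[i] * x[i + d] for i in range(L - d)) / (L - d))
        if var_n == 0:
            moran.append(0.0)
            geary.append(0.0)
        else:
            moran.append(
                (sum((x[i] - xbar) * (x[i + d] - xbar) for i in range(L - d))
                 / (L - d)) / var_n
            )
            geary.append(
                (sum((x[i] - x[i + d]) ** 2 for i in range(L - d))
                 / (2 * (L - d))) / var_n1
            )
    return mb, moran, geary


def qso_reference(seq, max_lag, w):
    mats = (grantham_distance_matrix(), physicochemical_distance_matrix())
    idx = {aa: i for i, aa in enumerate(ALPHABET)}
    L = len(seq)
    freq = [seq.count(aa) for aa in ALPHABET]
    couplings, qsos = [], []
    for dm in mats:
        taus = []
        for d in range(1, max_lag + 1):
            taus.append(
                sum(dm[idx[seq[i]], idx[seq[i + d]]] ** 2 for i in range(L - d))
            )
        couplings.extend(taus)
        denom = sum(freq) + w * sum(taus)
        qsos.extend([f / denom for f in freq] + [w * t / denom for t in taus])
    return couplings + qsos


def conjoint_triad_reference(seq):
    cluster = {aa: ci for ci, grp in enumerate(TRIAD_CLUSTERS) for aa in grp}
    counts = [0] * 343
    for i in range(len(seq) - 2):
        a, b, c = cluster[seq[i]], cluster[seq[i + 1]], cluster[seq[i + 2]]
        counts[a * 49 + b * 7 + c] += 1
    total = len(seq) - 2
    return [c / total for c in counts]


# ---------------------------------------------------------------------------
# Metric oracles

def fmax_reference(scores, truth, thresholds):
    """Protein-centric Fmax by direct loops over the threshold grid."""
    best = (0.0, 0.0)
    proteins = [i for i in range(len(truth)) if any(truth[i])]
    for t in thresholds:
        prs, rcs = [], []
        for i in proteins:
            pred = [j for j, s in enumerate(scores[i]) if s >= t]
            inter = len([j for j in pred if truth[i][j]])
            if pred:
                prs.append(inter / len(pred))
            rcs.append(inter / sum(truth[i]))
        if not prs:
            continue
        pr, rc = sum(prs) / len(prs), sum(rcs) / len(rcs)
        if pr + rc > 0:
            f = 2 * pr * rc / (pr + rc)
            if f > best[0]:
                best = (f, t)
    return best


def auprc_reference(scores, truth):
    """Step-wise PR area with tied scores grouped, by direct enumeration."""
    pairs = sorted(zip(scores, truth), key=lambda x: -x[0])
    n_pos = sum(t for _, t in pairs)
    area, tp, fp, prev_rc = 0.0, 0, 0, 0.0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1]
            fp += 1 - pairs[j][1]
            j += 1
        rc = tp / n_pos
        pr = tp / (tp + fp)
        area += (rc - prev_rc) * pr
        prev_rc = rc
        i = j
    return area


def auc_mann_whitney(scores, labels):
    """ROC AUC via the rank-sum identity with midrank ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
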