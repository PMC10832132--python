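"""CAFA-style evaluation: protein-centric Fmax, micro-averaged AUPRC,
per-protein recall/precision, and level-stratified term-centric AUC.

Fmax sweeps a threshold grid (default 0.01..1.00 in steps of 0.01):
at each threshold t, precision is averaged over proteins with at least
one prediction at or above t, recall over all benchmark proteins, and
Fmax is the best harmonic mean across the grid.  Metrics are computed
per GO namespace when a graph is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


def fmax_from_matrices(
    scores: np.ndarray, truth: np.ndarray, thresholds: np.ndarray | None = None
) -> tuple[float, float]:
    """Protein-centric Fmax over a score matrix and 0/1 truth matrix.

    Proteins with an empty truth row are excluded (with a warning).
    Returns ``(fmax, argmax threshold)``; 0 at threshold 0 if precision
    and recall never both exist.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    truth = np.asarray(truth, dtype=bool)
    keep = truth.any(axis=1)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} protein(s) with empty truth")
    scores, truth = scores[keep], truth[keep]
    if len(scores) == 0:
        return 0.0, 0.0
    best_f, best_t = 0.0, 0.0
    n_true = truth.sum(axis=1)
    for t in thresholds:
        pred = scores >= t
        n_pred = pred.sum(axis=1)
        inter = (pred & truth).sum(axis=1)
        covered = n_pred > 0
        if not covered.any():
            continue
        pr = float((inter[covered] / n_pred[covered]).mean())
        rc = float((inter / n_true).mean())
        if pr + rc > 0:
            f = 2 * pr * rc / (pr + rc)
            if f > best_f:
                best_f, best_t = f, float(t)
    return best_f, best_t


def auprc_micro(scores: np.ndarray, truth: np.ndarray) -> float:
    """Micro-averaged area under the precision-recall curve.

    All (protein, term) pairs are pooled; the area uses step-wise
    (right-continuous) interpolation with tied scores grouped.
    """
    y = np.asarray(truth, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.sum() == 0:
        raise ValueError("AUPRC undefined: no positive (protein, term) pairs")
    return float(average_precision_score(y, s))


def protein_recall_precision(
    scores: np.ndarray, truth: np.ndarray, threshold: float
) -> list[tuple[float, float | None]]:
    """Per-protein (recall, precision) at a fixed threshold.

    Precision is ``None`` (not applicable) for proteins with no
    prediction at or above the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    truth = np.asarray(truth, dtype=bool)
    out = []
    for srow, trow in zip(scores, truth):
        pred = srow >= threshold
        inter = int((pred & trow).sum())
        rc = inter / int(trow.sum()) if trow.any() else 0.0
        pr = inter / int(pred.sum()) if pred.any() else None
        out.append((rc, pr))
    return out


def term_auc(scores_col: np.ndarray, truth_col: np.ndarray) -> float | None:
    """ROC AUC of one term over proteins; None without both classes."""
    y = np.asarray(truth_col, dtype=int)
    if y.min() == y.max():
        return None
    return float(roc_auc_score(y, scores_col))


def level_auc(
    scores: np.ndarray, truth: np.ndarray, term_levels: list[int]
) -> dict[int, dict]:
    """Macro-averaged term-centric AUC per hierarchy level.

    Terms lacking both a positive and a negative protein are skipped;
    each level reports its mean AUC, the number of scored terms and the
    number skipped.  Levels with no scorable term are omitted.
    """
    by_level: dict[int, list[float]] = {}
    skipped: dict[int, int] = {}
    for j, lvl in enumerate(term_levels):
        a = term_auc(scores[:, j], truth[:, j])
        if a is None:
            skipped[lvl] = skipped.get(lvl, 0) + 1
        else:
            by_level.setdefault(lvl, []).append(a)
    return {
        lvl: {
            "auc": float(np.mean(aucs)),
            "n_terms": len(aucs),
            "n_skipped": skipped.get(lvl, 0),
        }
        for lvl, aucs in sorted(by_level.items())
    }


@dataclass
class EvalReport:
    """Per-namespace metrics plus the level-stratified AUC table."""

    fmax: dict[str, float]
    fmax_threshold: dict[str, float]
    auprc: dict[str, float]
    per_level_auc: dict[int, dict]
    head_tail: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "auprc": self.auprc,
            "per_level_auc": {str(k): v for k, v in self.per_level_auc.items()},
            "head_tail": {str(k): v for k, v in self.head_tail.items()},
        }


def evaluate(prediction, truth_table, ont, thresholds=None) -> EvalReport:
    """Full report for a PredictionMatrix against a propagated truth table.

    Fmax and AUPRC are computed per namespace; the AUC table is stratified
    by GO level across all namespaces.
    """
    from .network import targets_from_annotations  # local to avoid a cycle

    ls = prediction.label_space
    truth = targets_from_annotations(truth_table, prediction.protein_ids, ls)
    namespaces = sorted({ont.namespace_of(t) for t in ls.terms})
    fmax_d, thr_d, auprc_d = {}, {}, {}
    for ns in namespaces:
        cols = [j for j, t in enumerate(ls.terms) if ont.namespace_of(t) == ns]
        sub_s, sub_t = prediction.scores[:, cols], truth[:, cols]
        f, t = fmax_from_matrices(sub_s, sub_t, thresholds)
        fmax_d[ns], thr_d[ns] = f, t
        auprc_d[ns] = auprc_micro(sub_s, sub_t) if sub_t.sum() else 0.0
    levels = [ls.levels[t] for t in ls.terms]
    return EvalReport(
        fmax=fmax_d,
        fmax_threshold=thr_d,
        auprc=auprc_d,
        per_level_auc=level_auc(prediction.scores, truth, levels),
    )
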