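"""External-cohort validation utilities: sensitivity/specificity and ROC/AUC.

AUC uses the rank (Mann-Whitney) formulation, which equals the trapezoidal
area under the ROC curve over all thresholds and handles ties by assigning
half credit to tied pairs.  Multi-gene discrimination combines dichotomized
genes through the linear predictor of an in-sample logistic fit (the
combination rule is deliberately simple and swappable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .screening import dichotomize_expression, logistic_univariate

logger = logging.getLogger(__name__)

__all__ = ["sensitivity_specificity", "roc_auc", "combine_genes", "validation_report"]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    return labels


def sensitivity_specificity(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) for binary predictions."""
    labels = _check_labels(labels)
    pred = np.asarray(pred)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)


def roc_auc(score: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over all positive/negative
    pairs; invariant under strictly monotone transforms of the score.
    """
    labels = _check_labels(labels)
    score = np.asarray(score, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(score)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def combine_genes(expression: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Combined risk score for k genes (rows = genes, columns = samples).

    Dichotomizes each gene at its median and returns the linear predictor of
    an in-sample logistic fit of the labels on the k indicators.
    Separation is flagged in the log, not raised.
    """
    labels = _check_labels(labels)
    import statsmodels.api as sm

    X = np.column_stack(
        [dichotomize_expression(expression.loc[g]).to_numpy()
         for g in expression.index]
    )
    Xd = np.column_stack([np.ones(len(labels)), X])
    try:
        res = sm.Logit(labels.astype(float), Xd).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 50):
            logger.warning("combine_genes: separation flagged in logistic fit")
        return np.asarray(Xd @ res.params)
    except Exception as exc:
        logger.warning("combine_genes logistic fit failed (%s); using row sum", exc)
        return X.sum(axis=1).astype(float)


def validation_report(
    expression: pd.DataFrame,
    labels: np.ndarray,
    genes: list[str],
    alias_map: dict[str, str] | None = None,
) -> dict:
    """Per-gene sensitivity/specificity plus combined ROC/AUC.

    ``alias_map`` substitutes a measured family member for an absent gene
    (e.g. a platform lacking one paralog).  The combined operating point is
    the Youden-optimal threshold of the combined score.
    """
    labels = _check_labels(labels)
    resolved = []
    for g in genes:
        if g not in expression.index and alias_map and g in alias_map:
            alt = alias_map[g]
            logger.info("gene %s not measured; substituting %s", g, alt)
            g = alt
        if g not in expression.index:
            logger.warning("gene %s not measured and no alias; skipped", g)
            continue
        resolved.append(g)
    if not resolved:
        raise ValueError("no validation genes measured")

    per_gene = {}
    for g in resolved:
        pred = dichotomize_expression(expression.loc[g]).to_numpy()
        sens, spec = sensitivity_specificity(pred, labels)
        per_gene[g] = {
            "sensitivity": sens,
            "specificity": spec,
            "auc": roc_auc(expression.loc[g].to_numpy(), labels),
        }

    combined = combine_genes(expression.loc[resolved], labels)
    auc = roc_auc(combined, labels)
    # Youden-optimal operating point on the combined score
    best, best_j = None, -np.inf
    for thr in np.unique(combined):
        pred = (combined >= thr).astype(int)
        if pred.min() == pred.max():
            continue
        sens, spec = sensitivity_specificity(pred, labels)
        if sens + spec - 1 > best_j:
            best_j, best = sens + spec - 1, (sens, spec)
    return {
        "genes": resolved,
        "per_gene": per_gene,
        "combined_auc": auc,
        "combined_sensitivity": best[0] if best else None,
        "combined_specificity": best[1] if best else None,
    }
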