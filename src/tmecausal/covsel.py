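"""Data-driven minimal confounder-set selection.

For a candidate exposure gene G_j with complete covariate pool C (the other
candidate genes plus clinical covariates), two nested reductions are made:

1. V ⊆ C, minimal such that Y ⊥ C\\V | V   (outcome-predictive set)
2. W ⊆ V, minimal such that G_j ⊥ V\\W | W  (exposure-linked subset)

W is the adjustment set passed to the causal estimator; V is reported for
diagnostics.  Both reductions use backward elimination: repeatedly test
each remaining covariate for conditional independence with the target given
the rest of the set, drop the covariate with the largest p-value above the
threshold, and stop when every remaining covariate tests below threshold.
Ties break by largest p-value then lexicographic name, making the procedure
deterministic.

The conditional-independence engine is pluggable; the default adapts to the
data: when the target, the candidate and every conditioning covariate are
discrete with a manageable stratum count, it is the exact stratified
G-squared (likelihood-ratio) contingency test — nonparametric in the
conditioning set; otherwise it is a likelihood-ratio test of nested
regressions (logistic for a binary target, Gaussian/OLS otherwise) with the
candidate column added to the conditioning design.  Constant columns are
dropped automatically with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderSets",
    "ci_test_lrt",
    "backward_eliminate",
    "select_outcome_set",
    "select_exposure_set",
    "select_confounders",
]


@dataclass
class ConfounderSets:
    gene: str
    V: list[str]
    W: list[str]
    steps: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"gene": self.gene, "V": self.V, "W": self.W, "steps": self.steps}


def _design(pool: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Dummy-code categoricals, pass numerics through; prepend an intercept."""
    parts = [np.ones((len(pool), 1))]
    for c in cols:
        col = pool[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_numpy(dtype=float)[:, None])
        else:
            parts.append(pd.get_dummies(col.astype(str), drop_first=True)
                         .to_numpy(dtype=float))
    return np.column_stack(parts)


def _loglik(target: np.ndarray, X: np.ndarray, binary: bool) -> tuple[float, int]:
    """(maximized log-likelihood, model df) guarding collinear designs."""
    rank = np.linalg.matrix_rank(X)
    if binary:
        res = sm.Logit(target, X).fit(disp=0, maxiter=200)
    else:
        res = sm.OLS(target, X).fit()
    return float(res.llf), int(rank)


_MAX_STRATA = 64
_MAX_LEVELS = 10


def _is_discrete(col: pd.Series) -> bool:
    return col.nunique(dropna=False) <= _MAX_LEVELS and (
        not pd.api.types.is_float_dtype(col)
        or np.allclose(col, np.round(col))
    )


def _g2_stratified(target: np.ndarray, cand: pd.Series,
                   strata: pd.Series | None) -> float:
    """Stratified G-squared test of target ⊥ cand within strata."""
    df_all = pd.DataFrame({
        "t": target,
        "c": cand.to_numpy(),
        "s": 0 if strata is None else strata.to_numpy(),
    })
    g2, dof = 0.0, 0
    for _, sub in df_all.groupby("s"):
        tab = pd.crosstab(sub["t"], sub["c"]).to_numpy(dtype=float)
        rows = tab.sum(1)
        cols = tab.sum(0)
        if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
            continue
        exp = np.outer(rows, cols) / tab.sum()
        nz = tab > 0
        g2 += 2.0 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz]))
        dof += int((rows > 0).sum() - 1) * int((cols > 0).sum() - 1)
    if dof == 0:
        return 1.0
    return float(stats.chi2.sf(g2, dof))


def ci_test_lrt(target: np.ndarray, candidate: str, conditioning: list[str],
                pool: pd.DataFrame) -> float:
    """p-value for target ⊥ pool[candidate] | pool[conditioning].

    All-discrete data (target, candidate and conditioning, with at most
    64 conditioning strata) is tested by the exact stratified G-squared
    statistic; anything else by a likelihood-ratio test of nested
    regressions with and without the candidate column (logistic when the
    target is binary, OLS otherwise).
    """
    binary = set(np.unique(target)) <= {0.0, 1.0}
    cols = [pool[c] for c in conditioning] + [pool[candidate]]
    if binary and all(_is_discrete(c) for c in cols):
        n_strata = int(np.prod([c.nunique(dropna=False)
                                for c in cols[:-1]]) or 1)
        if n_strata <= _MAX_STRATA:
            strata = None
            if conditioning:
                strata = pool[conditioning].astype(str).agg("|".join, axis=1)
            return _g2_stratified(target, pool[candidate].astype(str), strata)
    ll0, df0 = _loglik(target, _design(pool, conditioning), binary)
    ll1, df1 = _loglik(target, _design(pool, conditioning + [candidate]), binary)
    df = max(df1 - df0, 1)
    lr = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lr, df))


CITest = Callable[[np.ndarray, str, list[str], pd.DataFrame], float]


def backward_eliminate(
    target: np.ndarray,
    pool: pd.DataFrame,
    candidates: list[str],
    threshold: float = 0.10,
    test: CITest = ci_test_lrt,
) -> tuple[list[str], list[dict]]:
    """Backward elimination returning (retained set, per-step p-value log)."""
    current = []
    for c in sorted(candidates):
        col = pool[c]
        if col.nunique(dropna=False) < 2:
            logger.info("covsel: dropping constant column %s", c)
            continue
        current.append(c)
    steps: list[dict] = []
    while current:
        pvals = {}
        for c in current:
            rest = [o for o in current if o != c]
            try:
                pvals[c] = test(target, c, rest, pool)
            except Exception as exc:  # degenerate fit: treat as uninformative
                logger.info("covsel: test failed for %s (%s); dropping", c, exc)
                pvals[c] = 1.0
        # largest p first, lexicographic on ties
        worst = max(sorted(pvals), key=lambda c: pvals[c])
        steps.append({"tested": dict(pvals), "dropped": None})
        if pvals[worst] <= threshold:
            break
        steps[-1]["dropped"] = worst
        current.remove(worst)
    return current, steps


def select_outcome_set(pool: pd.DataFrame, y: np.ndarray,
                       threshold: float = 0.10,
                       test: CITest = ci_test_lrt) -> tuple[list[str], list[dict]]:
    """Minimal set V with Y ⊥ C\\V | V by backward elimination."""
    return backward_eliminate(np.asarray(y, dtype=float), pool,
                              list(pool.columns), threshold, test)


def select_exposure_set(V: list[str], G: np.ndarray, pool: pd.DataFrame,
                        threshold: float = 0.10,
                        test: CITest = ci_test_lrt) -> tuple[list[str], list[dict]]:
    """Minimal subset W of V with G ⊥ V\\W | W."""
    if not V:
        return [], []
    return backward_eliminate(np.asarray(G, dtype=float), pool, list(V),
                              threshold, test)


def select_confounders(gene: str, G: np.ndarray, y: np.ndarray,
                       pool: pd.DataFrame, threshold: float = 0.10,
                       test: CITest = ci_test_lrt) -> ConfounderSets:
    """Both reductions for one gene; the pool must exclude the gene itself."""
    if gene in pool.columns:
        raise ValueError(f"covariate pool must not contain the exposure gene {gene!r}")
    V, steps_v = select_outcome_set(pool, y, threshold, test)
    W, steps_w = select_exposure_set(V, G, pool, threshold, test)
    assert set(W) <= set(V)
    return ConfounderSets(gene=gene, V=V, W=W,
                          steps=[{"stage": "V", "steps": steps_v},
                                 {"stage": "W", "steps": steps_w}])
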