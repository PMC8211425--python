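"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities by enumeration or direct summation,
never by calling the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def bh_adjust_brute(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def ssgsea_brute(expression, in_set_mask, tau: float) -> float:
    """Step-by-step running-sum enrichment with |centered rank|^tau weights."""
    expression = np.asarray(expression, dtype=float)
    n = len(expression)
    ranks = stats.rankdata(expression)
    centered = np.abs(ranks - (n + 1) / 2.0)
    order = np.argsort(-ranks, kind="stable")
    k = int(np.sum(in_set_mask))
    w_total = sum(centered[i] ** tau for i in order if in_set_mask[i])
    score = 0.0
    cum_in = cum_out = 0.0
    for i in order:
        if in_set_mask[i]:
            cum_in += centered[i] ** tau / w_total
        else:
            cum_out += 1.0 / (n - k)
        score += cum_in - cum_out
    return score


def auc_pairwise(score, labels) -> float:
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    pos = score[labels == 1]
    neg = score[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def g2_ci_test(target: np.ndarray, x: np.ndarray, strata: np.ndarray | None) -> float:
    """Exact G-squared test of target ⊥ x within strata (all binary arrays)."""
    target = np.asarray(target, dtype=int)
    x = np.asarray(x, dtype=int)
    if strata is None or strata.size == 0:
        keys = np.zeros(len(target), dtype=int)
    else:
        strata = np.asarray(strata, dtype=int).reshape(len(target), -1)
        keys = np.zeros(len(target), dtype=int)
        for j in range(strata.shape[1]):
            keys = keys * 2 + strata[:, j]
    g2, df = 0.0, 0
    for s in np.unique(keys):
        m = keys == s
        tab = np.zeros((2, 2))
        for a in (0, 1):
            for b in (0, 1):
                tab[a, b] = np.sum((target[m] == a) & (x[m] == b))
        rows, cols = tab.sum(1), tab.sum(0)
        tot = tab.sum()
        if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
            continue
        exp = np.outer(rows, cols) / tot
        nz = tab > 0
        g2 += 2.0 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz]))
        df += int((rows > 0).sum() - 1) * int((cols > 0).sum() - 1)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(g2, df))


def minimal_set_exhaustive(target: np.ndarray, pool: dict[str, np.ndarray],
                           candidates: list[str], threshold: float = 0.10) -> list[str]:
    """Smallest S (lexicographically first on ties) with target ⊥ c | S for
    every candidate c outside S, using exact stratified G-squared tests."""
    names = sorted(candidates)
    for size in range(len(names) + 1):
        for S in itertools.combinations(names, size):
            strata = (np.column_stack([pool[c] for c in S]) if S else None)
            ok = all(
                g2_ci_test(target, pool[c], strata) > threshold
                for c in names
                if c not in S
            )
            if ok:
                return list(S)
    return names
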