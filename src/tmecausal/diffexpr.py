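"""Negative-binomial differential expression between score-defined groups.

Per gene the model is a two-group NB GLM (log link) with median-of-ratios
size factors as offsets; the group coefficient is the log fold change
(high vs low) and is tested with a Wald statistic, followed by
Benjamini-Hochberg adjustment across tested genes.

Dispersion is NB2 (variance = mu + alpha * mu^2), estimated per gene by
method of moments within groups and shrunk toward a fitted mean-dispersion
trend alpha(mu) = a0 + a1/mu.  This mirrors the qualitative behavior of the
empirical-Bayes shrinkage used by mainstream RNA-seq DE tools without
reproducing their machinery; no claim of numerical equality with them is
made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "filter_low_counts",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "select_degs",
    "shared_degs",
]

_MIN_ALPHA = 1e-8


@dataclass(frozen=True)
class DEResult:
    gene: str
    base_mean: float
    log2_fc: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fc >= 0 else "down"


def filter_low_counts(counts: pd.DataFrame, rule: str = "all_below_half_n") -> pd.DataFrame:
    """Drop genes with uniformly negligible counts.

    Default rule removes a gene iff every sample's count is below
    n_samples / 2.  Alternative readings of the same prefilter are exposed:
    ``total_below_half_n`` (summed count below n/2) and
    ``majority_below_half_n`` (more than half the samples below n/2).
    """
    n = counts.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    half = n / 2.0
    if rule == "all_below_half_n":
        keep = (counts >= half).any(axis=1)
    elif rule == "total_below_half_n":
        keep = counts.sum(axis=1) >= half
    elif rule == "majority_below_half_n":
        keep = (counts < half).sum(axis=1) <= n / 2.0
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per sample, the median over genes of the ratio of its count to the
    gene's geometric mean across samples; genes with any zero count are
    excluded from the reference.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna() & np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; cannot normalize")
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("degenerate size factor (all-zero sample?)")
    return sf.rename("size_factor")


def _trend_fit(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu with non-negative coefficients."""
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, *_ = np.linalg.lstsq(X, alpha, rcond=None)
    return float(max(coef[0], _MIN_ALPHA)), float(max(coef[1], 0.0))


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    sf: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB2 dispersions with trend shrinkage.

    Method-of-moments within groups on normalized counts, then a weighted
    average (on the log scale) with the fitted trend alpha(mu) = a0 + a1/mu;
    ``shrink_weight`` is the weight on the trend.
    """
    q = counts.divide(sf, axis=1)
    mu = q.mean(axis=1).to_numpy()
    resid_var = np.zeros(len(counts))
    shot = np.zeros(len(counts))
    n_tot = 0
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        sub = q[cols]
        resid_var += sub.var(axis=1, ddof=1).to_numpy() * (len(cols) - 1)
        shot += sub.mean(axis=1).to_numpy() * (1.0 / sf[cols]).mean() * (len(cols) - 1)
        n_tot += len(cols) - 1
    if n_tot == 0:
        # single-sample groups carry no replication: fall back to a flat prior
        logger.warning("no group has >= 2 samples; using default dispersion 0.1")
        return pd.Series(0.1, index=counts.index, name="dispersion")
    resid_var /= n_tot
    shot /= n_tot

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (resid_var - shot) / mu**2
    raw = np.where(np.isfinite(raw), raw, _MIN_ALPHA)
    raw = np.clip(raw, _MIN_ALPHA, None)

    ok = mu > 0
    a0, a1 = _trend_fit(mu[ok], raw[ok])
    trend = np.clip(a0 + a1 / np.clip(mu, 1e-8, None), _MIN_ALPHA, None)
    alpha = np.exp(
        (1.0 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _wald_one_gene(y: np.ndarray, design: np.ndarray, offset: np.ndarray,
                   alpha: float) -> tuple[float, float]:
    """(log2FC, p) from an NB GLM Wald test on the group column."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _MIN_ALPHA))
    model = sm.GLM(y, design, family=fam, offset=offset)
    res = model.fit(maxiter=100, tol=1e-10)
    beta, se = res.params[1], res.bse[1]
    if not np.isfinite(se) or se == 0:
        return beta / np.log(2.0), 1.0
    z = beta / se
    return float(beta / np.log(2.0)), float(2.0 * stats.norm.sf(abs(z)))


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series,
                 shrink_weight: float = 0.5) -> list[DEResult]:
    """Two-group NB Wald test for every gene (high vs low).

    ``groups`` maps sample id to 'high'/'low'.  Returns one DEResult per
    gene with BH-adjusted FDR across all tested genes.
    """
    groups = groups.loc[counts.columns]
    levels = set(groups)
    if levels != {"high", "low"}:
        raise ValueError(f"groups must be 'high'/'low', got {sorted(levels)}")
    sf = size_factors(counts)
    alphas = estimate_dispersions(counts, groups, sf, shrink_weight)
    design = np.column_stack(
        [np.ones(counts.shape[1]), (groups == "high").astype(float).to_numpy()]
    )
    offset = np.log(sf.to_numpy())
    base_mean = counts.divide(sf, axis=1).mean(axis=1)

    lfc = np.empty(len(counts))
    pval = np.ones(len(counts))
    for i, gene in enumerate(counts.index):
        y = counts.loc[gene].to_numpy(dtype=float)
        try:
            lfc[i], pval[i] = _wald_one_gene(y, design, offset, alphas.iloc[i])
        except Exception:  # non-convergence on degenerate genes
            m1 = y[design[:, 1] == 1].mean() + 0.5
            m0 = y[design[:, 1] == 0].mean() + 0.5
            lfc[i], pval[i] = np.log2(m1 / m0), 1.0
            logger.debug("GLM fallback for gene %s", gene)
    fdr = multipletests(pval, method="fdr_bh")[1]
    return [
        DEResult(g, float(base_mean.iloc[i]), float(lfc[i]), float(pval[i]),
                 float(fdr[i]))
        for i, g in enumerate(counts.index)
    ]


def select_degs(results: list[DEResult], lfc_cut: float = 1.5,
                fdr_cut: float = 0.05) -> list[DEResult]:
    """Keep genes with |log2FC| > lfc_cut and FDR < fdr_cut."""
    if not results:
        raise ValueError("no DE results to select from")
    return [r for r in results if abs(r.log2_fc) > lfc_cut and r.fdr < fdr_cut]


def shared_degs(immune_degs: list[DEResult],
                stromal_degs: list[DEResult]) -> list[DEResult]:
    """Direction-concordant intersection: (up ∩ up) ∪ (down ∩ down).

    Returns the immune-side records of the shared genes.
    """
    stromal_dir = {r.gene: r.direction for r in stromal_degs}
    return [r for r in immune_degs if stromal_dir.get(r.gene) == r.direction]


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "baseMean": r.base_mean,
                "log2FC": r.log2_fc,
                "pvalue": r.p_value,
                "padj": r.fdr,
                "direction": r.direction,
            }
            for r in results
        ]
    )
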