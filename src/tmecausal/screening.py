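"""Univariate logistic screening of dichotomized genes and clinical factors.

Each candidate gene is median-dichotomized (high = strictly above the
per-gene median expression) and regressed, one variable at a time, against
the binary 3-year-mortality outcome.  Categorical clinical factors are
reference-coded; a variable survives screening when any of its levels is
significant at ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import log_cpm

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateResult",
    "dichotomize_expression",
    "logistic_univariate",
    "screen",
]

_Z95 = stats.norm.ppf(0.975)
_SEP_SE = 50.0  # Wald SE beyond which we flag (quasi-)separation


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    level: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    separation: bool = False


def dichotomize_expression(expr: pd.Series) -> pd.Series:
    """1 = expression strictly above the median, else 0 (rank-invariant)."""
    if len(expr) < 2:
        raise ValueError("need at least 2 samples")
    if (expr == expr.iloc[0]).all():
        raise ValueError("constant expression cannot be dichotomized")
    return (expr > expr.median()).astype(int)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    try:
        return model.fit(disp=0, maxiter=200)
    except Exception:
        return model.fit(disp=0, method="bfgs", maxiter=500)


def logistic_univariate(
    x: pd.Series,
    y: pd.Series,
    variable: str | None = None,
    reference: str | None = None,
) -> list[UnivariateResult]:
    """Single-predictor logistic regression of a binary outcome.

    Numeric predictors yield one row; categorical predictors one row per
    non-reference level (reference = ``reference`` or the first level in
    order of appearance).  OR = exp(coef), 95% CI = exp(coef +- 1.96 SE).
    Separation is reported via a flag, never an exception.
    """
    variable = variable or str(x.name)
    x, y = x.align(y, join="inner")
    yv = y.to_numpy(dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome has a single class")

    if pd.api.types.is_numeric_dtype(x):
        levels = [("", x.to_numpy(dtype=float))]
    else:
        cats = list(pd.unique(x.astype(str)))
        ref = reference if reference is not None else cats[0]
        if ref not in cats:
            raise ValueError(f"reference level {ref!r} not observed")
        levels = [(c, (x.astype(str) == c).to_numpy(dtype=float))
                  for c in cats if c != ref]

    X = np.column_stack([np.ones(len(yv))] + [col for _, col in levels])
    res = _fit_logit(yv, X)
    out = []
    for j, (level, _) in enumerate(levels, start=1):
        beta, se = res.params[j], res.bse[j]
        sep = not np.isfinite(se) or se > _SEP_SE
        if sep:
            logger.warning("separation flagged for %s level %r", variable, level)
        z = beta / se if se > 0 else np.inf
        with np.errstate(over="ignore"):
            ci = (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))
        out.append(
            UnivariateResult(
                variable=variable,
                level=level or ("High expression level" if set(np.unique(X[:, j])) <= {0.0, 1.0} else "per unit"),
                odds_ratio=float(np.exp(beta)),
                ci95=ci,
                p_value=float(2.0 * stats.norm.sf(abs(z))),
                separation=bool(sep),
            )
        )
    return out


def screen(
    deg_genes: list[str],
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    y: pd.Series,
    alpha: float = 0.05,
    clinical_vars: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Univariate screen of genes and clinical factors against mortality.

    Genes are median-dichotomized on log2(CPM+1); a variable is retained if
    any level has p < alpha.  Returns (retained variable names, full result
    table mirroring an OR/CI/p layout).
    """
    expr = log_cpm(counts)
    rows: list[UnivariateResult] = []
    retained: list[str] = []

    for gene in deg_genes:
        if gene not in expr.index:
            logger.warning("screened gene %s absent from counts; skipped", gene)
            continue
        g = dichotomize_expression(expr.loc[gene])
        res = logistic_univariate(g, y, variable=gene)
        rows.extend(res)
        if any(r.p_value < alpha and not r.separation for r in res):
            retained.append(gene)

    for var in clinical_vars or []:
        x = clinical.set_index("sample_id")[var] if "sample_id" in clinical.columns else clinical[var]
        res = logistic_univariate(x, y, variable=var)
        rows.extend(res)
        if any(r.p_value < alpha and not r.separation for r in res):
            retained.append(var)

    table = pd.DataFrame(
        [
            {
                "variable": r.variable,
                "level": r.level,
                "OR": r.odds_ratio,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_value": r.p_value,
                "separation": r.separation,
            }
            for r in rows
        ]
    )
    return retained, table
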