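"""Targeted maximum likelihood estimation for a binary exposure and outcome.

Estimands (potential-outcome notation, Y(g) the outcome under exposure g):

    AE  = E[Y(1) - Y(0)]                                (average effect)
    IE_i = E[Y | G=1, W_i] - E[Y | G=0, W_i]            (individual effect)
    MOR = {E[Y(1)] (1-E[Y(0)])} / {(1-E[Y(1)]) E[Y(0)]} (marginal odds ratio)

Procedure: (1) initial estimates of the outcome regression Q(G, W) =
E[Y | G, W] and the propensity g(W) = P(G = 1 | W), each by a cross-validated
Super Learner (convex stacking of candidate learners minimizing CV
log-loss); (2) truncate g to the positivity bounds; (3) a single
two-parameter logistic fluctuation of Q with offset logit(Q) and clever
covariates H1 = G/g(W), H0 = -(1-G)/(1-g(W)), which solves both arms'
efficient-influence-curve score equations; (4) plug-in estimates from the
targeted Q*, with influence-curve standard errors, Wald confidence
intervals and two-sided p-values (MOR on the log scale by the delta
method).  The estimator is doubly robust: consistent when either Q or g is
estimated consistently.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from xgboost import XGBClassifier

from .scoring import log_cpm
from .screening import dichotomize_expression

logger = logging.getLogger(__name__)

__all__ = [
    "TMLEConfig",
    "CausalEstimates",
    "SuperLearner",
    "make_learner_library",
    "marginal_odds_ratio",
    "tmle_estimate",
    "run_per_gene",
]

_CLIP = 1e-6
_Z95 = stats.norm.ppf(0.975)


def marginal_odds_ratio(ey1: float, ey0: float) -> float:
    """Odds ratio of the two marginal counterfactual risks."""
    if not (0.0 < ey1 < 1.0 and 0.0 < ey0 < 1.0):
        raise ValueError("counterfactual means must lie strictly inside (0, 1)")
    return (ey1 * (1.0 - ey0)) / ((1.0 - ey1) * ey0)


# ---------------------------------------------------------------------------
# Super Learner
# ---------------------------------------------------------------------------

def make_learner_library(names: tuple[str, ...], seed: int) -> dict[str, object]:
    """Instantiate the candidate learners by name.

    The default library spans main-terms logistic regression, all-pairwise-
    interaction logistic regression, elastic-net logistic regression,
    gradient-boosted trees and a random forest.
    """
    lib: dict[str, object] = {}
    for name in names:
        if name == "glm":
            lib[name] = LogisticRegression(C=np.inf, max_iter=1000)
        elif name == "glm_interaction":
            lib[name] = make_pipeline(
                PolynomialFeatures(degree=2, interaction_only=True,
                                   include_bias=False),
                LogisticRegression(C=np.inf, max_iter=1000),
            )
        elif name == "glmnet":
            lib[name] = make_pipeline(
                StandardScaler(),
                LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0,
                                   max_iter=5000, random_state=seed),
            )
        elif name == "xgboost":
            lib[name] = XGBClassifier(
                n_estimators=100, max_depth=3, learning_rate=0.1,
                subsample=0.8, reg_lambda=1.0, n_jobs=1, verbosity=0,
                random_state=seed, eval_metric="logloss",
            )
        elif name == "random_forest":
            lib[name] = RandomForestClassifier(
                n_estimators=200, min_samples_leaf=5, n_jobs=1,
                random_state=seed,
            )
        else:
            raise ValueError(f"unknown learner {name!r}")
    return lib


class _ConstantClassifier:
    """Fallback predictor when there are no features: the outcome mean."""

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.p_)
        return np.column_stack([1 - p, p])


def _nll(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _CLIP, 1 - _CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class SuperLearner:
    """Convex cross-validated stacking of probability learners.

    V-fold CV predictions are computed for every learner; convex weights
    minimizing the CV negative log-likelihood are found on the simplex; the
    learners are refit on the full data and predictions are the weighted
    combination, clipped to (1e-6, 1 - 1e-6).  A learner that raises is
    excluded with weight 0 (logged), never a crash.
    """

    def __init__(self, learners: tuple[str, ...] = (
            "glm", "glm_interaction", "glmnet", "xgboost", "random_forest"),
            v_folds: int = 10, seed: int = 0):
        self.learner_names = tuple(learners)
        self.v_folds = v_folds
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuperLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] == 0 or len(np.unique(y)) < 2:
            self.models_ = {"constant": _ConstantClassifier().fit(X, y)}
            self.weights_ = {"constant": 1.0}
            self.cv_nll_ = {}
            return self
        lib = make_learner_library(self.learner_names, self.seed)

        if len(lib) == 1:
            name = next(iter(lib))
            self.models_ = {name: lib[name].fit(X, y)}
            self.weights_ = {name: 1.0}
            self.cv_nll_ = {}
            return self

        folds = min(self.v_folds, int(np.bincount(y.astype(int)).min()))
        folds = max(folds, 2)
        cv = StratifiedKFold(folds, shuffle=True, random_state=self.seed)
        preds: dict[str, np.ndarray] = {}
        for name, est in lib.items():
            try:
                z = np.empty(n)
                for tr, te in cv.split(X, y):
                    m = clone(est)
                    m.fit(X[tr], y[tr])
                    z[te] = m.predict_proba(X[te])[:, 1]
                preds[name] = np.clip(z, _CLIP, 1 - _CLIP)
            except Exception as exc:
                logger.warning("learner %s failed in CV (%s); excluded", name, exc)

        if not preds:
            self.models_ = {"constant": _ConstantClassifier().fit(X, y)}
            self.weights_ = {"constant": 1.0}
            self.cv_nll_ = {}
            return self

        names = list(preds)
        P = np.column_stack([preds[m] for m in names])
        self.cv_nll_ = {m: _nll(preds[m], y) for m in names}

        k = len(names)
        res = minimize(
            lambda w: _nll(P @ w, y),
            np.full(k, 1.0 / k),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        w = np.clip(res.x, 0.0, None)
        w /= w.sum()

        self.models_ = {}
        self.weights_ = {}
        for name, wi in zip(names, w):
            try:
                self.models_[name] = lib[name].fit(X, y)
                self.weights_[name] = float(wi)
            except Exception as exc:
                logger.warning("learner %s failed on refit (%s); excluded", name, exc)
        tot = sum(self.weights_.values())
        self.weights_ = {m: wi / tot for m, wi in self.weights_.items()}
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p = np.zeros(len(X))
        for name, m in self.models_.items():
            p += self.weights_[name] * m.predict_proba(X)[:, 1]
        return np.clip(p, _CLIP, 1 - _CLIP)


# ---------------------------------------------------------------------------
# TMLE
# ---------------------------------------------------------------------------

@dataclass
class TMLEConfig:
    learners: tuple[str, ...] = (
        "glm", "glm_interaction", "glmnet", "xgboost", "random_forest")
    v_folds: int = 10
    g_bounds: tuple[float, float] = (0.025, 0.975)
    positivity_warn_fraction: float = 0.10
    seed: int = 0


@dataclass
class CausalEstimates:
    ae: float
    ae_se: float
    ae_ci95: tuple[float, float]
    ae_p: float
    mor: float
    mor_ci95: tuple[float, float]
    mor_p: float
    ey1: float
    ey0: float
    ie: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict, repr=False)


def _fluctuate(y: np.ndarray, q_obs: np.ndarray, h0: np.ndarray,
               h1: np.ndarray) -> tuple[float, float]:
    """Two-parameter logistic fluctuation with offset logit(Q)."""
    X = np.column_stack([h0, h1])
    off = logit(np.clip(q_obs, _CLIP, 1 - _CLIP))
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial(), offset=off).fit(
            maxiter=500, tol=1e-12)
        return float(res.params[0]), float(res.params[1])
    except Exception as exc:
        logger.warning("fluctuation GLM failed (%s); epsilon set to 0", exc)
        return 0.0, 0.0


def tmle_estimate(
    y: np.ndarray,
    G: np.ndarray,
    W: pd.DataFrame | np.ndarray | None,
    config: TMLEConfig | None = None,
    q_init: tuple[np.ndarray, np.ndarray] | None = None,
    g_init: np.ndarray | None = None,
) -> CausalEstimates:
    """One TMLE fit of AE, IE and MOR.

    ``W`` may be None/empty (randomized-exposure analysis).  ``q_init``
    ((Q(0,W), Q(1,W)) arrays) and ``g_init`` override the Super Learner
    initial estimates — used for oracle checks and misspecification
    studies.
    """
    cfg = config or TMLEConfig()
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)
    if set(np.unique(G)) - {0.0, 1.0}:
        raise ValueError("exposure must be binary 0/1")
    if G.sum() == 0 or G.sum() == n:
        raise ValueError(
            "one exposure arm is empty; the positivity assumption is violated "
            "and the effects are not identifiable")

    if W is None:
        Wmat = np.empty((n, 0))
    else:
        Wmat = np.asarray(W, dtype=float)
        if Wmat.ndim == 1:
            Wmat = Wmat[:, None]

    # (a) initial Q and g
    sl_q_weights = sl_g_weights = {}
    if q_init is not None:
        q0, q1 = (np.clip(np.asarray(q, dtype=float), _CLIP, 1 - _CLIP)
                  for q in q_init)
    else:
        sl_q = SuperLearner(cfg.learners, cfg.v_folds, cfg.seed).fit(
            np.column_stack([G, Wmat]), y)
        q0 = sl_q.predict_proba(np.column_stack([np.zeros(n), Wmat]))
        q1 = sl_q.predict_proba(np.column_stack([np.ones(n), Wmat]))
        sl_q_weights = sl_q.weights_
    if g_init is not None:
        g = np.asarray(g_init, dtype=float)
    else:
        sl_g = SuperLearner(cfg.learners, cfg.v_folds, cfg.seed + 1).fit(Wmat, G)
        g = sl_g.predict_proba(Wmat)
        sl_g_weights = sl_g.weights_

    # (b) positivity truncation
    lo, hi = cfg.g_bounds
    truncated = float(np.mean((g < lo) | (g > hi)))
    if truncated > cfg.positivity_warn_fraction:
        logger.warning(
            "positivity: %.1f%% of propensities truncated to [%g, %g]",
            100 * truncated, lo, hi)
    g = np.clip(g, lo, hi)

    # (c) clever covariates, (d) fluctuation
    h1 = G / g
    h0 = -(1.0 - G) / (1.0 - g)
    q_obs = np.where(G == 1, q1, q0)
    eps0, eps1 = _fluctuate(y, q_obs, h0, h1)
    q1s = expit(logit(np.clip(q1, _CLIP, 1 - _CLIP)) + eps1 / g)
    q0s = expit(logit(np.clip(q0, _CLIP, 1 - _CLIP)) - eps0 / (1.0 - g))
    q_obs_s = np.where(G == 1, q1s, q0s)

    # (e) plug-in estimates from the targeted fit
    ey1, ey0 = float(q1s.mean()), float(q0s.mean())
    ie = q1s - q0s
    ae = float(ie.mean())
    mor = marginal_odds_ratio(ey1, ey0)

    # (f) influence-curve inference
    resid = y - q_obs_s
    ic1 = h1 * resid + q1s - ey1
    ic0 = -h0 * resid + q0s - ey0
    ic_ae = ic1 - ic0
    ae_se = float(ic_ae.std(ddof=1) / np.sqrt(n))
    z_ae = ae / ae_se if ae_se > 0 else np.inf
    ic_logmor = ic1 / (ey1 * (1 - ey1)) - ic0 / (ey0 * (1 - ey0))
    logmor_se = float(ic_logmor.std(ddof=1) / np.sqrt(n))
    z_mor = np.log(mor) / logmor_se if logmor_se > 0 else np.inf

    return CausalEstimates(
        ae=ae,
        ae_se=ae_se,
        ae_ci95=(ae - _Z95 * ae_se, ae + _Z95 * ae_se),
        ae_p=float(2 * stats.norm.sf(abs(z_ae))),
        mor=mor,
        mor_ci95=(float(mor * np.exp(-_Z95 * logmor_se)),
                  float(mor * np.exp(_Z95 * logmor_se))),
        mor_p=float(2 * stats.norm.sf(abs(z_mor))),
        ey1=ey1,
        ey0=ey0,
        ie=ie,
        diagnostics={
            "mean_ic": float(ic_ae.mean()),
            "epsilon": (eps0, eps1),
            "g_truncated_fraction": truncated,
            "sl_weights_Q": sl_q_weights,
            "sl_weights_g": sl_g_weights,
        },
    )


def _gene_seed(global_seed: int, gene: str) -> int:
    """Deterministic, order-independent per-gene substream (< 2^31)."""
    return (global_seed * 1_000_003 + zlib.crc32(gene.encode())) % (2**31 - 1)


def _covariate_design(pool: pd.DataFrame, cols: list[str]) -> np.ndarray:
    parts = []
    for c in cols:
        col = pool[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_numpy(dtype=float)[:, None])
        else:
            parts.append(pd.get_dummies(col.astype(str), drop_first=True)
                         .to_numpy(dtype=float))
    return np.column_stack(parts) if parts else np.empty((len(pool), 0))


def run_per_gene(
    candidates: list[str],
    counts: pd.DataFrame,
    covariate_pool: pd.DataFrame,
    y: pd.Series,
    confounder_sets: dict[str, list[str]],
    config: TMLEConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, CausalEstimates]]:
    """One TMLE fit per candidate gene.

    Exposure is the gene's median-dichotomized log2(CPM+1) expression; the
    adjustment set is the gene's selected confounders (columns of
    ``covariate_pool``).  Per-gene seeds are derived from the global seed
    and the gene id, so results are invariant to batch order.  A failing
    gene is recorded and skipped, never aborting the batch.
    """
    cfg = config or TMLEConfig()
    expr = log_cpm(counts)
    rows, fits = [], {}
    for gene in candidates:
        try:
            Gvec = dichotomize_expression(expr.loc[gene]).to_numpy()
            Wcols = confounder_sets.get(gene, [])
            Wmat = _covariate_design(covariate_pool, Wcols)
            gene_cfg = TMLEConfig(cfg.learners, cfg.v_folds, cfg.g_bounds,
                                  cfg.positivity_warn_fraction,
                                  _gene_seed(cfg.seed, gene))
            est = tmle_estimate(y.to_numpy(), Gvec, Wmat, gene_cfg)
        except Exception as exc:
            logger.warning("TMLE failed for gene %s: %s", gene, exc)
            continue
        fits[gene] = est
        rows.append({
            "gene": gene,
            "MOR": est.mor,
            "MOR_ci_low": est.mor_ci95[0],
            "MOR_ci_high": est.mor_ci95[1],
            "p_MOR": est.mor_p,
            "AE": est.ae,
            "AE_ci_low": est.ae_ci95[0],
            "AE_ci_high": est.ae_ci95[1],
            "p_AE": est.ae_p,
            "n_confounders": len(confounder_sets.get(gene, [])),
        })
    columns = ["gene", "MOR", "MOR_ci_low", "MOR_ci_high", "p_MOR",
               "AE", "AE_ci_low", "AE_ci_high", "p_AE", "n_confounders"]
    return pd.DataFrame(rows, columns=columns), fits
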