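"""Synthetic tumor cohorts with known causal ground truth.

Generates a gene-level read-count matrix with immune/stromal signature
structure, a clinical table with confounders, and a binary 3-year-mortality
outcome drawn from a known structural logistic model, so that the true
average effect (AE), per-sample individual effects (IE) and marginal odds
ratio (MOR) of the exposure are computable exactly.

Structural model
----------------
Confounders ``Z`` are drawn i.i.d. per sample from the distributions in
``SimulationConfig.confounders``.  The binary exposure (high expression of a
designated gene) follows

    logit P(G = 1 | Z) = a0 + sum_k a_k Z_k

and the outcome

    logit P(Y = 1 | G, Z) = b0 + beta * G + sum_k b_k Z_k

where ``beta`` is ``gene_effect_logit``.  Counterfactual risks
``p1(Z) = expit(b0 + beta + b'Z)`` and ``p0(Z) = expit(b0 + b'Z)`` give the
truth: ``IE_i = p1(Z_i) - p0(Z_i)``, ``AE = mean(IE)``, and MOR is formed from
the two counterfactual mean risks.  For purely discrete confounders the same
quantities are also available seed-free by exact enumeration of the
confounder support (:func:`enumerate_truth`).

Counts are negative binomial with variance ``mu + alpha * mu**2``.  Signature
genes have their mean multiplied by ``signature_fold_change`` in samples whose
latent immune (or stromal) state is high; the designated exposure gene has its
mean multiplied by ``exposure_fold_change`` when G = 1, so that a median split
of its expression recovers G.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ConfounderSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "enumerate_truth",
    "marginal_odds_ratio_from_means",
]


@dataclass(frozen=True)
class ConfounderSpec:
    """One confounder: its sampling distribution and structural coefficients.

    distribution is ("bernoulli", p) or ("normal", mean, sd); exposure_coef
    enters the exposure logit, outcome_coef the outcome logit.
    """

    name: str
    distribution: tuple
    exposure_coef: float
    outcome_coef: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind = self.distribution[0]
        if kind == "bernoulli":
            return rng.binomial(1, self.distribution[1], size=n).astype(float)
        if kind == "normal":
            return rng.normal(self.distribution[1], self.distribution[2], size=n)
        raise ValueError(f"unknown confounder distribution {kind!r}")


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_genes: int = 2000
    n_signature_genes: int = 100
    nb_dispersion: float = 0.2
    base_mean_log_range: tuple[float, float] = (3.0, 10.0)
    signature_fold_change: float = 8.0
    stromal_concordance_flip: float = 0.05
    confounders: tuple[ConfounderSpec, ...] = (
        ConfounderSpec("stage_adv", ("bernoulli", 0.4), 0.8, 1.0),
        ConfounderSpec("age", ("normal", 0.0, 1.0), 0.5, 0.6),
    )
    gene_effect_logit: float = -1.2
    exposure_intercept: float = 0.0
    outcome_intercept: float = -0.4
    exposure_fold_change: float = 20.0
    exposure_tme_fold: float = 6.0
    exposure_immune_coef: float = 0.0
    recurrent_fraction: float = 0.0
    early_censor_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if 2 * self.n_signature_genes + 1 > self.n_genes:
            raise ValueError("need n_genes > 2 * n_signature_genes for both signatures")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.signature_fold_change <= 0 or self.exposure_fold_change <= 0:
            raise ValueError("fold changes must be > 0")


@dataclass
class SyntheticTruth:
    """Ground-truth effects implied by the data-generating parameters."""

    true_AE: float
    true_MOR: float
    true_IE: np.ndarray
    true_EY1: float
    true_EY0: float
    true_confounders: frozenset[str]
    signature_membership: dict[str, str]
    exposure_gene: str
    G: np.ndarray = field(repr=False, default=None)
    latent_immune: np.ndarray = field(repr=False, default=None)
    latent_stromal: np.ndarray = field(repr=False, default=None)


def marginal_odds_ratio_from_means(ey1: float, ey0: float) -> float:
    """Odds ratio of the two marginal counterfactual risks."""
    if not (0.0 < ey1 < 1.0 and 0.0 < ey0 < 1.0):
        raise ValueError("counterfactual means must lie strictly inside (0, 1)")
    return (ey1 * (1.0 - ey0)) / ((1.0 - ey1) * ey0)


def _counterfactual_risks(
    config: SimulationConfig, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """p1(z), p0(z) for rows of the confounder matrix Z (n x k)."""
    b = np.array([c.outcome_coef for c in config.confounders])
    lin = config.outcome_intercept + (Z @ b if Z.size else np.zeros(len(Z)))
    return expit(lin + config.gene_effect_logit), expit(lin)


def enumerate_truth(config: SimulationConfig) -> tuple[float, float]:
    """Exact (AE, MOR) by enumerating the discrete confounder support.

    Independent of the seed: averages the counterfactual risks over the
    product of confounder supports, weighting each stratum by its
    probability.  Only defined when every confounder is discrete
    (bernoulli); a continuous confounder raises ValueError.
    """
    supports, weights = [], []
    for c in config.confounders:
        if c.distribution[0] != "bernoulli":
            raise ValueError(
                f"enumerate_truth requires discrete confounders; {c.name!r} is "
                f"{c.distribution[0]!r}"
            )
        p = c.distribution[1]
        supports.append((0.0, 1.0))
        weights.append((1.0 - p, p))
    ey1 = ey0 = 0.0
    combos = itertools.product(*supports) if supports else [()]
    wcombos = itertools.product(*weights) if weights else [()]
    for z, w in zip(combos, wcombos):
        pr = float(np.prod(w)) if w else 1.0
        p1, p0 = _counterfactual_risks(config, np.array([z], dtype=float))
        ey1 += pr * p1[0]
        ey0 += pr * p0[0]
    ae = ey1 - ey0
    return ae, marginal_odds_ratio_from_means(ey1, ey0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    # variance = mean + alpha * mean^2  <=>  size r = 1/alpha, p = r/(r+mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate (counts, clinical, truth) for one cohort.

    Returns a genes x samples integer count matrix, a per-sample clinical
    table (confounders plus standard clinic-pathologic columns), and the
    :class:`SyntheticTruth` implied by the structural model.  Reproducible:
    the single ``config.seed`` is split into fixed per-stage substreams
    (confounders/exposure, outcome, counts, clinical decoration).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_z, rng_y, rng_counts, rng_clin = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = cfg.n_samples

    # --- latent TME states ---------------------------------------------------
    # Immune and stromal infiltration co-vary in bulk tumors (both track
    # overall non-tumor content): the stromal state copies the immune state
    # except for a small flip fraction.
    lat_imm = rng_counts.binomial(1, 0.5, size=n)
    flips = rng_counts.binomial(1, cfg.stromal_concordance_flip, size=n)
    lat_str = lat_imm ^ flips

    # --- confounders and exposure -------------------------------------------
    # Optional centered coupling of the exposure to the latent immune state
    # (off by default; the latent state has no direct outcome effect, so
    # switching it on makes the latent an instrument, not a confounder).
    Z = (
        np.column_stack([c.sample(n, rng_z) for c in cfg.confounders])
        if cfg.confounders
        else np.empty((n, 0))
    )
    a = np.array([c.exposure_coef for c in cfg.confounders])
    g_lin = (
        cfg.exposure_intercept
        + (Z @ a if Z.size else np.zeros(n))
        + cfg.exposure_immune_coef * (lat_imm - 0.5)
    )
    G = rng_z.binomial(1, expit(g_lin))

    # --- outcome and truth ---------------------------------------------------
    p1, p0 = _counterfactual_risks(cfg, Z)
    p_obs = np.where(G == 1, p1, p0)
    Y = rng_y.binomial(1, p_obs)
    ey1, ey0 = float(p1.mean()), float(p0.mean())
    ie = p1 - p0

    # --- counts ---------------------------------------------------------------
    gene_ids = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    k = cfg.n_signature_genes
    membership = {g: "none" for g in gene_ids}
    for g in gene_ids[:k]:
        membership[g] = "immune"
    for g in gene_ids[k : 2 * k]:
        membership[g] = "stromal"
    exposure_gene = gene_ids[2 * k]

    lo, hi = cfg.base_mean_log_range
    base_mean = 2.0 ** rng_counts.uniform(lo, hi, size=cfg.n_genes)

    mu = np.tile(base_mean[:, None], (1, n)).astype(float)
    mu[:k, :] *= cfg.signature_fold_change ** lat_imm[None, :]
    mu[k : 2 * k, :] *= cfg.signature_fold_change ** lat_str[None, :]
    # The designated exposure gene is itself TME-responsive (so it reaches
    # the DE stage of the analysis) on top of its exposure elevation; with
    # exposure_fold_change >> exposure_tme_fold a median split of its
    # expression still recovers G.
    mu[2 * k, :] *= (
        cfg.exposure_fold_change ** G * cfg.exposure_tme_fold ** lat_imm
    )
    counts = _nb_draw(rng_counts, mu, cfg.nb_dispersion)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene_id"

    # --- clinical table -------------------------------------------------------
    clinical = pd.DataFrame({"sample_id": sample_ids})
    for j, c in enumerate(cfg.confounders):
        clinical[c.name] = Z[:, j]
    if "age" not in clinical.columns:
        clinical["age"] = rng_clin.normal(60.0, 10.0, size=n).round(1)
    clinical["figo_stage"] = rng_clin.choice(
        ["I", "II", "III", "IV"], size=n, p=[0.01, 0.05, 0.76, 0.18]
    )
    clinical["grade"] = rng_clin.choice(
        ["G2", "G3", "Unknown"], size=n, p=[0.12, 0.85, 0.03]
    )
    clinical["tumor_residual"] = rng_clin.choice(
        ["No macroscopic disease", "1-10 mm", "11-20 mm", ">20 mm", "Unknown"],
        size=n,
        p=[0.13, 0.47, 0.07, 0.21, 0.12],
    )
    clinical["sample_type"] = np.where(
        rng_clin.random(n) < cfg.recurrent_fraction, "recurrent", "primary"
    )

    # survival consistent with Y at the 3-year horizon (times in years)
    os_time = np.where(
        Y == 1, rng_clin.uniform(0.1, 2.99, size=n), rng_clin.uniform(3.0, 10.0, size=n)
    )
    vital = np.where(Y == 1, "dead", "alive")
    # survivors past the horizon may still die later; keep a dead/alive mix
    late_death = (Y == 0) & (rng_clin.random(n) < 0.3)
    vital = np.where(late_death, "dead", vital)
    # optional alive-with-short-follow-up samples (excluded by the outcome rule)
    censor = rng_clin.random(n) < cfg.early_censor_fraction
    os_time = np.where(censor, rng_clin.uniform(0.1, 2.9, size=n), os_time)
    vital = np.where(censor, "alive", vital)
    clinical["vital_status"] = vital
    clinical["os_time"] = np.round(os_time, 4)

    truth = SyntheticTruth(
        true_AE=float(ie.mean()),
        true_MOR=marginal_odds_ratio_from_means(ey1, ey0),
        true_IE=ie,
        true_EY1=ey1,
        true_EY0=ey0,
        true_confounders=frozenset(
            c.name
            for c in cfg.confounders
            if c.exposure_coef != 0 and c.outcome_coef != 0
        ),
        signature_membership=membership,
        exposure_gene=exposure_gene,
        G=G,
        latent_immune=lat_imm,
        latent_stromal=lat_str,
    )
    return counts_df, clinical, truth
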