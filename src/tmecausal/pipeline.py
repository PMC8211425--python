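"""End-to-end orchestration of the biomarker-discovery pipeline.

Stages: cohort construction -> immune/stromal scoring -> differential
expression (immune and stromal splits, direction-concordant intersection)
-> univariate logistic screening -> per-gene minimal confounder selection
-> per-gene TMLE -> optional ROC validation.  Every stage writes a plain
TSV/JSON artifact into the run directory and the run closes with a
machine-readable manifest (config, seed, per-stage record counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import covsel as covsel_mod
from . import diffexpr, io, scoring, screening, tmle, validation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "run"
    horizon_years: float = 3.0
    os_time_unit: str = "years"
    column_map: dict = field(default_factory=dict)
    lfc_cut: float = 1.5
    fdr_cut: float = 0.05
    low_count_rule: str = "all_below_half_n"
    screening_alpha: float = 0.05
    clinical_vars: list = field(default_factory=lambda: ["age", "tumor_residual"])
    covsel_threshold: float = 0.10
    sl_learners: list = field(default_factory=lambda: [
        "glm", "glm_interaction", "glmnet", "xgboost", "random_forest"])
    sl_folds: int = 10
    g_bounds: tuple = (0.025, 0.975)
    seed: int = 0
    ssgsea_weight_exponent: float = 0.25
    gene_alias_map: dict = field(default_factory=dict)
    validation_counts_path: str | None = None
    validation_clinical_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_config(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    gene_sets: dict[str, set[str]] | None = None,
) -> dict:
    """Execute the full flow; returns the manifest dict.

    Inputs may be passed in memory (as from the synthetic generator) or
    read from the configured paths.  Artifacts land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "stages": {},
    }
    t_start = time.time()

    def _stage(name):
        def deco(fn):
            def run(*a, **kw):
                t0 = time.time()
                try:
                    result = fn(*a, **kw)
                except PipelineError:
                    raise
                except Exception as exc:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                    raise PipelineError(name, str(exc)) from exc
                manifest["stages"][name].update(
                    {"status": "ok", "seconds": round(time.time() - t0, 3)})
                return result
            return run
        return deco

    # ---- load ---------------------------------------------------------------
    manifest["stages"]["load"] = {}

    @_stage("load")
    def _load():
        c = counts if counts is not None else io.read_counts(config.counts_path)
        cl = clinical if clinical is not None else io.read_clinical(
            config.clinical_path, config.column_map, config.os_time_unit)
        gs = gene_sets if gene_sets is not None else io.read_gmt(config.gmt_path)
        if "immune" not in gs or "stromal" not in gs:
            raise ValueError("gene sets must include 'immune' and 'stromal'")
        return c, cl, gs

    counts_df, clinical_df, gs = _load()
    manifest["stages"]["load"]["n_genes"] = int(counts_df.shape[0])
    manifest["stages"]["load"]["n_samples_input"] = int(counts_df.shape[1])

    # ---- cohort -------------------------------------------------------------
    manifest["stages"]["cohort"] = {}

    @_stage("cohort")
    def _cohort():
        return cohort_mod.filter_samples(clinical_df, counts_df, config.horizon_years)

    clin, cts, outcome = _cohort()
    manifest["stages"]["cohort"].update({
        "n_retained": int(len(outcome.y)),
        "n_excluded": len(outcome.excluded),
        "exclusions": outcome.excluded,
    })
    io.write_clinical(clin, out / "cohort_clinical.tsv")
    outcome.y.rename_axis("sample_id").to_csv(out / "outcome.tsv", sep="\t")

    # ---- scoring ------------------------------------------------------------
    manifest["stages"]["scoring"] = {}

    @_stage("scoring")
    def _score():
        immune = scoring.GeneSet("immune", frozenset(gs["immune"]))
        stromal = scoring.GeneSet("stromal", frozenset(gs["stromal"]))
        return scoring.estimate_scores(cts, immune, stromal,
                                       config.ssgsea_weight_exponent)

    scores = _score()
    scores.to_csv(out / "scores.tsv", sep="\t")
    manifest["stages"]["scoring"]["n_scored"] = int(len(scores))

    # ---- differential expression -------------------------------------------
    manifest["stages"]["diff_expr"] = {}

    @_stage("diff_expr")
    def _de():
        filtered = diffexpr.filter_low_counts(cts, config.low_count_rule)
        degs = {}
        for which in ("immune", "stromal"):
            groups = scoring.split_by_median(scores[f"{which}_score"])
            res = diffexpr.nb_wald_test(filtered, groups)
            diffexpr.results_frame(res).to_csv(out / f"de_{which}.tsv",
                                               sep="\t", index=False)
            degs[which] = diffexpr.select_degs(res, config.lfc_cut, config.fdr_cut)
        shared = diffexpr.shared_degs(degs["immune"], degs["stromal"])
        return filtered, degs, shared

    filtered, degs, shared = _de()
    diffexpr.results_frame(shared).to_csv(out / "de_shared.tsv", sep="\t", index=False)
    manifest["stages"]["diff_expr"].update({
        "n_filtered_genes": int(len(filtered)),
        "n_immune_degs": len(degs["immune"]),
        "n_stromal_degs": len(degs["stromal"]),
        "n_shared_degs": len(shared),
    })

    # ---- screening ----------------------------------------------------------
    manifest["stages"]["screening"] = {}

    @_stage("screening")
    def _screen():
        clin_vars = [v for v in config.clinical_vars if v in clin.columns]
        return screening.screen(
            [r.gene for r in shared], cts, clin, outcome.y,
            config.screening_alpha, clin_vars)

    candidates, screen_table = _screen()
    screen_table.to_csv(out / "screening.tsv", sep="\t", index=False)
    gene_candidates = [c for c in candidates if c in cts.index]
    manifest["stages"]["screening"].update({
        "n_candidates": len(candidates),
        "n_gene_candidates": len(gene_candidates),
        "candidates": candidates,
    })

    # ---- covariate pool: dichotomized candidate genes + clinical ------------
    expr = scoring.log_cpm(cts)
    pool = pd.DataFrame(index=clin.index)
    for g in gene_candidates:
        pool[g] = screening.dichotomize_expression(expr.loc[g]).to_numpy()
    for v in config.clinical_vars:
        if v in clin.columns:
            pool[v] = clin[v].to_numpy()

    # ---- covsel -------------------------------------------------------------
    manifest["stages"]["covsel"] = {}

    @_stage("covsel")
    def _covsel():
        sets = {}
        reports = []
        for g in gene_candidates:
            G = pool[g].to_numpy()
            sub = pool.drop(columns=[g])
            cs = covsel_mod.select_confounders(
                g, G, outcome.y.to_numpy(), sub, config.covsel_threshold)
            sets[g] = cs.W
            reports.append(cs.to_dict())
        (out / "confounder_sets.json").write_text(
            json.dumps(reports, indent=2, default=str))
        return sets

    conf_sets = _covsel()
    manifest["stages"]["covsel"]["set_sizes"] = {g: len(w) for g, w in conf_sets.items()}

    # ---- TMLE ---------------------------------------------------------------
    manifest["stages"]["tmle"] = {}

    @_stage("tmle")
    def _tmle():
        cfg = tmle.TMLEConfig(
            learners=tuple(config.sl_learners), v_folds=config.sl_folds,
            g_bounds=tuple(config.g_bounds), seed=config.seed)
        return tmle.run_per_gene(gene_candidates, cts, pool, outcome.y,
                                 conf_sets, cfg)

    tmle_table, fits = _tmle()
    tmle_table.to_csv(out / "tmle.tsv", sep="\t", index=False)
    (out / "tmle_ie.json").write_text(json.dumps(
        {g: fits[g].ie.tolist() for g in fits}, default=str))
    manifest["stages"]["tmle"]["n_fitted"] = len(fits)
    manifest["stages"]["tmle"]["significant"] = (
        tmle_table.loc[tmle_table["p_AE"] < 0.05, "gene"].tolist()
        if len(tmle_table) else [])

    # ---- validation (optional) ----------------------------------------------
    if config.validation_counts_path and config.validation_clinical_path:
        manifest["stages"]["validation"] = {}

        @_stage("validation")
        def _validate():
            vc = io.read_counts(config.validation_counts_path)
            vcl = io.read_clinical(config.validation_clinical_path,
                                   config.column_map, config.os_time_unit)
            vclin, vcts, voutcome = cohort_mod.filter_samples(
                vcl, vc, config.horizon_years)
            sig = manifest["stages"]["tmle"]["significant"]
            rep = validation.validation_report(
                scoring.log_cpm(vcts), voutcome.y.to_numpy(), sig,
                config.gene_alias_map)
            (out / "validation.json").write_text(json.dumps(rep, indent=2))
            return rep

        if manifest["stages"]["tmle"]["significant"]:
            _validate()
        else:
            manifest["stages"]["validation"] = {"status": "skipped",
                                                "reason": "no significant genes"}

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
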