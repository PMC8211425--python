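# tmecausal

Discovery of tumor-microenvironment (TME) related prognostic biomarkers
from bulk tumor RNA-seq with **targeted maximum likelihood estimation
(TMLE)** of their causal effect on binary 3-year mortality.

The package is aimed at biostatisticians and computational biologists who
want the full analysis chain as tested, reproducible code:

1. **Cohort** — outcome definition at a survival horizon (dead before 3
   years = case; survivor past 3 years = control; alive with shorter
   follow-up = excluded) and sample filtering.
2. **TME scoring** — per-sample immune and stromal scores by single-sample
   rank-based enrichment (weighted ECDF difference, |centered rank|^0.25
   weights), split at the median.
3. **Differential expression** — per-gene negative-binomial GLM Wald tests
   (median-of-ratios size factors, trend-shrunk NB2 dispersions) between
   high and low score groups; DEGs at |log2FC| > 1.5, FDR < 0.05;
   direction-concordant intersection of the immune and stromal splits.
4. **Screening** — median-dichotomized genes and clinical factors in
   univariate logistic regressions against mortality.
5. **Confounder selection** — per candidate gene, nested backward
   eliminations to the minimal sets V, W with Y ⊥ C\V | V and
   G ⊥ V\W | W (stratified G² / regression LRT engine, pluggable).
6. **TMLE** — Super Learner (glm, pairwise-interaction glm, elastic net,
   gradient boosting, random forest) initial estimates of E[Y|G,W] and
   P(G=1|W); one logistic fluctuation with clever covariates
   H₁ = G/g(W), H₀ = −(1−G)/(1−g(W)); influence-curve inference for

   - AE  = E[Y(1) − Y(0)]  (average effect),
   - IEᵢ = E[Y|G=1,Wᵢ] − E[Y|G=0,Wᵢ]  (individual effects),
   - MOR = {E[Y(1)](1−E[Y(0)])}/{(1−E[Y(1)])E[Y(0)]}  (marginal odds ratio).
7. **Validation** — per-gene sensitivity/specificity and multi-gene
   ROC/AUC (Mann–Whitney) utilities for external cohorts.

A synthetic-cohort generator with analytically known AE/IE/MOR ground truth
makes every stage testable without downloading anything; see
`docs/methods.md` for the models and defaults.

## Worked example

```python
import tmecausal as tc
from tmecausal.pipeline import PipelineConfig, run_pipeline

cfg = tc.SimulationConfig(n_samples=500, n_genes=800,
                          n_signature_genes=60, seed=11)
counts, clinical, truth = tc.generate_cohort(cfg)
gene_sets = {k: {g for g, m in truth.signature_membership.items() if m == k}
             for k in ("immune", "stromal")}

man = run_pipeline(
    PipelineConfig(out_dir="run", seed=11, sl_learners=["glm", "glmnet"],
                   clinical_vars=["stage_adv", "age"]),
    counts=counts, clinical=clinical, gene_sets=gene_sets)

print(man["stages"]["diff_expr"])   # stage counts
print(man["stages"]["tmle"]["significant"], truth.exposure_gene,
      round(truth.true_AE, 3))
```

prints (stage counts, then the TMLE-significant genes):

```
{'status': 'ok', 'seconds': 1.64, 'n_filtered_genes': 463,
 'n_immune_degs': 118, 'n_stromal_degs': 118, 'n_shared_degs': 118}
['GENE00120'] GENE00120 -0.244
```

Of the 118 shared DEGs, four survive univariate screening; after
confounder selection and TMLE only the truly causal gene `GENE00120`
remains significant, and `run/tmle.tsv` shows its estimates:

```
gene       MOR    MOR 95% CI      p_MOR   AE      AE 95% CI         p_AE
GENE00120  0.338  (0.239, 0.480)  <0.001  -0.248  (-0.325, -0.172)  <0.001
```

i.e. high expression lowers the 3-year mortality risk by an estimated 25
percentage points (truth: −0.244), while the three false-positive
candidates' confidence intervals cover zero.

The same flow is available from the shell:

```bash
tmecausal simulate --out sim --seed 11 --n-samples 500 --n-genes 800
tmecausal run --config pipeline.yaml --out run --seed 11
tmecausal score --counts sim/counts.tsv --gmt sim/signatures.gmt
```

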