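# glycoprog

Glycolysis-related prognostic (GRP) scoring for multi-cohort survival
transcriptomics, with an end-to-end synthetic study.

Pancreatic ductal adenocarcinoma (PDAC) tumours lean heavily on aerobic
glycolysis (the Warburg effect), and the expression of glycolytic genes
carries prognostic information. This package implements the full workflow
for building and validating a glycolysis-based risk score across several
expression cohorts with right-censored overall survival, for
bioinformaticians who work with multi-study compendia (TCGA / ICGC / GEO
style): per-gene survival screening, meta-analytic pooling, a weighted-sum
risk score, risk stratification, immune-infiltration scoring and
chemosensitivity prediction.

## The method

Within each cohort, every candidate gene *i* is dichotomized at its
within-cohort median (ties to the low group) and tested with a univariate
Cox proportional-hazards model (Efron tie correction) on the high-vs-low
indicator. Per-cohort estimates are pooled on the log scale by
inverse-variance fixed effects:

    b = Σ w_c b_c / Σ w_c,   w_c = 1 / SE(b_c)²,   SE(b) = (Σ w_c)^(-1/2)

with HRᵢ = exp(b) and SE(HRᵢ) = HRᵢ·SE(b) by the delta method. Genes with
meta-analysis P < 0.001 **and** BH FDR < 0.001 enter the signature, and the
GRP score of sample *s* is

    GRP(s) = Σᵢ (HRᵢ − 1) / SE(HRᵢ) · geneᵢ(s)

where geneᵢ(s) is the log2 expression. Dividing by SE(HRᵢ) damps the
influence of cohort size on each gene's weight. Scores are z-normalized
within cohort and split at the cohort median into high/low GRP strata.
Downstream, the package provides Kaplan-Meier / log-rank comparison of the
strata, uni/multivariate Cox, cumulative/dynamic time-dependent ROC with
inverse-probability-of-censoring weights, per-sample ssGSEA for 28 immune
cell-type marker sets, and ROC analysis of RECIST chemotherapy response
(CR/PR vs SD/PD and CR vs non-CR), including a ridge-logistic combination
of the GRP score with response-associated immune cell types.

Because the real consortium cohorts are controlled-access, the package
ships a synthetic multi-cohort generator with planted ground truth (known
prognostic genes, effect sizes, censoring rate, response link), so every
stage is tested against what was planted. See `docs/methods.md` for the
generative model and all modelling decisions.

## Worked example

The `analysis/` scripts run the whole study on synthetic data (seed 1;
6 training cohorts + 1 held-out validation cohort, 150 patients each):

```bash
python analysis/01_simulate_cohorts.py --seed 1   # writes results/data/
python analysis/02_screen_meta.py                 # screening + meta-analysis
python analysis/03_score_stratify.py              # frozen-weight GRP scores
python analysis/04_evaluate_survival.py           # KM, Cox, time ROC
python analysis/05_immune_enrichment.py           # ssGSEA by stratum
python analysis/06_chemo_response.py              # response AUCs
```

Selected output from that run:

```
selected 12 prognostic genes at P < 0.001 and FDR < 0.001 (10 poor, 2 good prognosis)
ground truth: 12/15 planted genes recovered, 0 false positives
  SIM-07: log-rank chi2 = 75.5, p = 3.63e-18
pooled time-dependent AUC: 1y = 0.903, 2y = 0.908, 3y = 0.905
SIM-01: 24/28 immune cell types significantly lower in the high-GRP stratum (q < 0.05)
CRPR_vs_SDPD: mean GRP AUC = 0.686
GRP + immune combined (responder scheme): mean AUC = 0.778
```

Reading this: the screen recovered 12 of the 15 genes planted by the
simulator with no false positives; scoring the held-out cohort SIM-07 with
the frozen training weights cleanly separates survival of the high and low
GRP strata; most immune cell types are depleted in high-GRP samples (as
planted); and a lower GRP score predicts chemotherapy response, improving
when combined with immune features.

The same workflow is available as a CLI (`glycoprog simulate`, `screen`,
`score`, `evaluate`, `enrich`, `chemo`, `run-all`) for TSV/GMT inputs of
your own: expression is genes × samples (first column gene id), the
clinical table needs `sample_id`, `os_time`, `os_event` (optional
`rfs_time`/`rfs_event`, `chemo_response`, covariates), gene sets are
standard GMT.

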