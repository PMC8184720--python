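# Methods

This note documents the statistical model, the synthetic data generator,
and every place where the design was genuinely open.

## Screening and meta-analysis

Each gene is dichotomized at its within-cohort median; values equal to the
median go to the low group, and a split is refused as degenerate when more
than half the samples tie at the median. The high-vs-low indicator enters a
univariate Cox proportional-hazards model. The Cox solver maximizes the
Efron-tie-corrected partial likelihood by Newton-Raphson with step-halving
(convergence when the scaled step falls below 1e-9, at most 100 iterations;
a coefficient passing |β| > 30 is reported as a monotone-likelihood /
separation failure). Efron's correction is used because day-resolution
survival data routinely carries tied event times, and it is the default of
the mainstream survival packages this implementation was cross-checked
against (agreement with lifelines to ~1e-5 on coefficients and standard
errors). Wald inference is reported — not likelihood-ratio — because the
meta-analysis consumes (log HR, SE) pairs and Wald is the matching
inference.

Per-cohort estimates are pooled with inverse-variance fixed effects **on
the log-HR scale**; SE on the HR scale, needed by the score weight, is
recovered by the delta method SE(HR) = HR·SE(log HR). Pooling on the log
scale is the standard construction (symmetric sampling distribution,
variance stabilisation); the delta step reconciles it with a weight defined
on the HR scale. Genes missing from a cohort are pooled over the cohorts
that measure them, with the cohort count recorded. Benjamini-Hochberg
correction is applied once across the whole screened universe, and
selection requires meta P < 0.001 and FDR < 0.001, both strict.

## The GRP score

Weights are wᵢ = (HRᵢ − 1)/SE(HRᵢ). The score is the weighted sum of log2
expression over the selected genes; "relative expression" is taken as the
expression matrix as loaded, **not** gene-wise standardized, and the single
z-normalization (sample SD, n−1 denominator) is applied to the final score
within each cohort. A `gene_standardize` switch enables per-gene z-scoring
first for sensitivity analysis, since heatmap-style displays of such
signatures usually scale per gene and the published description is
ambiguous on this point. Weights are frozen from the training meta-analysis
and applied unchanged to validation cohorts; only the z-scaling and the
median cut-off (score > cohort median = high stratum, same tie rule as the
gene screen) are cohort-specific. Stratification is invariant to any
strictly increasing transform of the score, so raw and z scores give
identical strata and log-rank results.

## Survival evaluation

Kaplan-Meier curves and the two-group log-rank test delegate to lifelines.
The time-dependent ROC is the cumulative/dynamic (Heagerty-type) AUC:
cases are subjects with an observed event by the horizon, controls are
subjects still at risk after it; cases are weighted by 1/G(T⁻), the
Kaplan-Meier estimate of the censoring survival evaluated at the left limit
of the event time, and tied scores get half credit. With no censoring
before the horizon this reduces exactly to the ordinary AUC of the
event-by-t indicator. Horizons default to 1, 2 and 3 years (365/730/1095
days) — conventional horizons for pancreatic cancer — and are configurable;
the estimator variant itself is a documented package choice, as "time ROC"
alone does not pin one down.

## Enrichment and association statistics

The ssGSEA score of a set in a sample integrates the difference between the
weighted in-set ECDF and the unweighted out-of-set ECDF over the sample's
expression ranking (descending, average ranks for ties; remaining ties are
ordered by gene identifier so results are permutation-stable). In-set genes
are weighted by rank^α with α = 0.25, the convention of the GSVA/ssGSEA
implementation family, and the matrix is normalized by its global range.
The statistic is rank-based and therefore exactly invariant to strictly
increasing transforms of expression. A set covering the whole universe is
an error (the out-of-set ECDF is undefined); sets with no gene in the
matrix are dropped with a warning.

Group comparisons use the Mann-Whitney rank-sum test (exact enumeration for
n₁+n₂ ≤ 10 without ties, otherwise the normal approximation with tie
correction and no continuity correction, so identical groups give p = 1
exactly), Spearman correlation with the t-approximation, and a chi-square
contingency test without continuity correction that falls back to the
two-sided Fisher exact test for 2×2 tables with any expected count below 5.
Comparisons across the 28 cell types are BH-corrected alongside raw p.

## Chemosensitivity

RECIST categories are encoded as responders {CR, PR} vs {SD, PD} or as CR
vs non-CR; both schemes are first-class because summary descriptions of
"response" often leave the grouping ambiguous. AUC uses the Mann-Whitney
rank identity with half credit for ties and no automatic orientation
flipping; since a *low* GRP score is the pro-response direction, reported
response AUCs use the negated score so that values above 0.5 mean the score
discriminates responders. The combined model is a ridge-regularized
logistic regression (standardized features, inverse penalty C = 100 —
small enough to keep separable data finite, large enough not to distort
in-sample ranking) on the GRP score plus the immune cell types whose
enrichment differs between response classes (rank-sum p < 0.05; the GRP
column is exempt from the filter). The reported AUC is in-sample, matching
how combined ROC curves are usually presented in signature papers; no
cross-validation is performed by default.

## Synthetic data generator

The generator emulates a multi-study PDAC compendium. Defaults (the study
conditions used throughout the tests): 6 cohorts (+1 validation where used)
of n = 150; a 106-gene screened universe with 15 planted prognostic genes,
|log HR| uniform on [0.5, 0.9] with ~21:8 poor:good direction mix (the
proportion reported for glycolytic prognostic genes in PDAC); 782 immune
marker genes in 28 cell-type sets; 1500 null background genes (a stand-in
for the rest of the transcriptome, needed so that rank-based enrichment has
a stable reference); gene means uniform on log2 4–12 with per-cohort,
per-gene shifts of SD 0.5 (platform/location effects) and unit residual SD.

Survival: effects are planted on standardized expression, so the latent
risk is η = Σ β_g z_g and |β| is comparable across genes. Event times are
exponential with rate h₀·exp(η), h₀ = log(2)/500 per day (median OS around
500 days at η = 0); censoring is an administrative Uniform(0, W) window
with W solved per cohort by bisection so the expected censoring proportion
hits the 40% target (typical of PDAC OS data); realized censoring stays
within ±5%.

Two consequences of this model matter for interpretation. First,
median-dichotomization plus the frailty contributed by the other planted
genes *attenuates* marginal effects: a Monte-Carlo evaluation of the model
at n = 10⁶ shows a planted β = 0.8 presenting as a dichotomized marginal
log HR of ≈ 0.44. Recovery of weakly planted genes at the strict double
threshold is therefore imperfect by construction: across repeated studies
the screen recovers ~80% of planted genes on average with essentially no
false positives, but individual studies range from ~60% to ~95%. Second,
per-sample enrichment is compositional — ranks are relative within a sample
— which is why the background gene pool exists and why immune depletion is
modelled with heterogeneous per-cell-type coupling (each set's genes are
shifted by −c_k·η̃ with c_k = 0.4×Uniform(0.2, 1.8)): most, but not all,
cell types then show significantly lower enrichment in the high-GRP
stratum, as observed in real PDAC data.

Response labels: P(responder) = logistic(a + b·η) with a = −0.5,
b = −0.3 (≈ 35–40% responders, oracle AUC of the latent risk ≈ 0.71,
matching the discrimination regime reported for glycolysis scores);
responders split CR:PR at 40:60 and non-responders SD:PD at 50:50 by a
secondary uniform draw, so both encoding schemes are exercised. The
numeric-integration oracle for the binormal-logistic AUC is implemented on
a dense grid (±8τ, 20k points).

What the generator does **not** emulate: RNA-seq count noise and
mean-variance coupling, co-expression structure (genes are independent by
default), probe-level artefacts, non-proportional hazards, informative
censoring, and cohort heterogeneity in true effects (the fixed-effects
assumption is true in the simulation). Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated model, not
robustness to those real-data features.

## Problem sizes and numerical choices in the test suite

Seeded property tests use 20–50 repeated studies at the default 6×150
design, small-n oracle comparisons (grid-search Cox at n ≤ 8, enumerated
IPCW pairs at n = 8, running-sum ssGSEA at ≤ 30 genes), and large-n checks
(n = 5000) where a law-of-large-numbers comparison against a frozen
Monte-Carlo or numeric-integration oracle is the point. Fixed seeds make
every stochastic test deterministic. Tolerances: 1e-4 against the Cox grid
oracle (grid refinement step 1e-5), 1e-10 for hand-computed risk-set and
enumeration oracles, exact equality where the identity is exact in floating
point (AUC complement, rank invariances).

## Known limitations

Gene identifiers are opaque strings (no symbol/alias mapping, no probe
collapsing); expression must arrive normalized and log2-transformed; no
random-effects meta-analysis or heterogeneity diagnostics; no optimal
cut-point search; in-sample evaluation for the combined chemosensitivity
model unless cross-validation is requested explicitly.
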