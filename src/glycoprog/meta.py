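"""Per-gene survival screening and fixed-effects meta-analysis.

Each candidate gene is dichotomized at its within-cohort median (values
equal to the median fall in the low group) and tested with a univariate Cox
model on the high-vs-low indicator.  Per-cohort log hazard ratios are pooled
with inverse-variance fixed-effects weights; SE on the hazard-ratio scale is
recovered by the delta method, because the downstream score weight
(HR - 1) / SE(HR) is defined on the HR scale while pooling is performed on
the log scale.  Benjamini-Hochberg correction is applied once across the
whole screened gene universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glycoprog.datamodel import Cohort
from glycoprog.survival import ConvergenceError, fit_cox

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSurvivalResult:
    """Univariate median-split Cox result for one gene in one cohort."""

    gene_id: str
    cohort_name: str
    log_hr: float
    se_log_hr: float
    wald_p: float
    n: int
    n_events: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))


@dataclass
class MetaResult:
    """Fixed-effects pooled hazard ratio for one gene across cohorts."""

    gene_id: str
    pooled_log_hr: float
    pooled_se_log_hr: float
    meta_p: float
    n_cohorts: int
    fdr_q: float = float("nan")

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def se_hr(self) -> float:
        """SE of the pooled HR via the delta method: HR * SE(log HR)."""
        return self.pooled_hr * self.pooled_se_log_hr

    @property
    def direction(self) -> str:
        return "poor" if self.pooled_hr > 1.0 else "good"


def median_dichotomize(values: np.ndarray) -> np.ndarray:
    """1 = above the median, 0 = at or below (ties go to the low group)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    indicator = (values > med).astype(float)
    n_tied = int(np.sum(values == med))
    if n_tied > len(values) / 2:
        raise ValueError(
            f"degenerate dichotomization: {n_tied}/{len(values)} samples tied at the median"
        )
    return indicator


def screen_gene_cohort(cohort: Cohort, gene_id: str) -> GeneSurvivalResult:
    """Median-split survival screen of one gene in one cohort."""
    if gene_id not in cohort.expression.index:
        raise KeyError(f"gene {gene_id!r} not present in cohort {cohort.name!r}")
    values = cohort.expression.loc[gene_id].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        raise ValueError(f"gene {gene_id!r} has no expression variation in cohort {cohort.name!r}")
    indicator = median_dichotomize(values)
    fit = fit_cox(
        indicator,
        cohort.clinical["os_time"].to_numpy(dtype=float),
        cohort.clinical["os_event"].to_numpy(dtype=float),
        names=(gene_id,),
    )
    return GeneSurvivalResult(
        gene_id=gene_id,
        cohort_name=cohort.name,
        log_hr=float(fit.log_hr[0]),
        se_log_hr=float(fit.se_log_hr[0]),
        wald_p=float(fit.wald_p[0]),
        n=fit.n_samples,
        n_events=fit.n_events,
    )


def fixed_effects_pool(results: Sequence[GeneSurvivalResult]) -> MetaResult:
    """Inverse-variance fixed-effects pooling on the log-HR scale.

    pooled b = sum(w_i b_i) / sum(w_i) with w_i = 1 / se_i^2;
    pooled SE = 1 / sqrt(sum w_i); two-sided normal p on b / SE.
    """
    if len(results) == 0:
        raise ValueError("fixed_effects_pool requires at least one cohort result")
    gene_ids = {r.gene_id for r in results}
    if len(gene_ids) != 1:
        raise ValueError(f"results mix genes: {sorted(gene_ids)}")
    b = np.array([r.log_hr for r in results], dtype=float)
    se = np.array([r.se_log_hr for r in results], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene_id=results[0].gene_id,
        pooled_log_hr=pooled,
        pooled_se_log_hr=pooled_se,
        meta_p=p,
        n_cohorts=len(results),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_screen(cohorts: Sequence[Cohort], gene_ids: Iterable[str]) -> list[MetaResult]:
    """Screen every gene in every cohort and pool; one BH pass over all genes.

    Genes absent from a cohort (or degenerate there) are pooled over the
    cohorts that measure them; genes testable in no cohort are dropped with
    a warning.
    """
    pooled: list[MetaResult] = []
    for gene in gene_ids:
        per_cohort: list[GeneSurvivalResult] = []
        for cohort in cohorts:
            if gene not in cohort.expression.index:
                continue
            try:
                per_cohort.append(screen_gene_cohort(cohort, gene))
            except (ValueError, ConvergenceError) as err:
                logger.warning("gene %s skipped in cohort %s: %s", gene, cohort.name, err)
        if not per_cohort:
            logger.warning("gene %s testable in no cohort, dropped from the meta-analysis", gene)
            continue
        pooled.append(fixed_effects_pool(per_cohort))
    if pooled:
        q = bh_adjust([m.meta_p for m in pooled])
        for m, qv in zip(pooled, q):
            m.fdr_q = float(qv)
    return pooled


def select_prognostic_genes(
    meta_results: Sequence[MetaResult],
    p_threshold: float = 0.001,
    fdr_threshold: float = 0.001,
) -> list[MetaResult]:
    """Keep genes with meta p and BH q both strictly below their thresholds."""
    for thr, label in ((p_threshold, "p_threshold"), (fdr_threshold, "fdr_threshold")):
        if not (0 < thr < 1):
            raise ValueError(f"{label} must lie in (0, 1), got {thr}")
    selected = [
        m for m in meta_results
        if m.meta_p < p_threshold and m.fdr_q < fdr_threshold
    ]
    if not selected:
        warnings.warn(
            f"no gene passed p < {p_threshold} and FDR < {fdr_threshold}; "
            "selection is empty",
            UserWarning,
            stacklevel=2,
        )
    return selected


def meta_results_table(meta_results: Sequence[MetaResult]) -> pd.DataFrame:
    """Tidy per-gene summary, the machine-readable twin of a forest plot."""
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in meta_results],
            "pooled_log_hr": [m.pooled_log_hr for m in meta_results],
            "pooled_se_log_hr": [m.pooled_se_log_hr for m in meta_results],
            "pooled_hr": [m.pooled_hr for m in meta_results],
            "se_hr": [m.se_hr for m in meta_results],
            "hr_ci_low": [np.exp(m.pooled_log_hr - 1.959963984540054 * m.pooled_se_log_hr) for m in meta_results],
            "hr_ci_high": [np.exp(m.pooled_log_hr + 1.959963984540054 * m.pooled_se_log_hr) for m in meta_results],
            "meta_p": [m.meta_p for m in meta_results],
            "fdr_q": [m.fdr_q for m in meta_results],
            "direction": [m.direction for m in meta_results],
            "n_cohorts": [m.n_cohorts for m in meta_results],
        }
    )
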