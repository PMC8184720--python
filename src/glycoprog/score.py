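"""GRP score construction: weights, per-sample scores, z-scores, strata.

The glycolysis-related prognostic (GRP) score of a sample is the weighted
sum over the selected prognostic genes

    GRP(s) = sum_i (HR_i - 1) / SE(HR_i) * gene_i(s)

where HR_i and SE(HR_i) are the pooled meta-analytic hazard ratio and its
standard error and gene_i(s) is the sample's log2 expression.  Dividing by
SE(HR) damps the influence of cohort sample size on each gene's weight.
Scores are z-normalized within each cohort (sample SD, n-1 denominator) and
dichotomized at the cohort median: score > median = "high" stratum.

Weights are frozen from the training meta-analysis; only the z-scaling and
the median cut-off are recomputed per cohort when scoring validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glycoprog.datamodel import Cohort
from glycoprog.meta import MetaResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GRPWeights:
    """Per-gene score weights with their meta-analytic provenance."""

    weights: dict[str, float]
    provenance: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValueError("GRPWeights requires at least one gene")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights)

    def to_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GRPWeights":
        prov = pd.read_csv(path, sep="\t")
        return cls(weights=dict(zip(prov["gene_id"].astype(str), prov["weight"])), provenance=prov)


def compute_weights(selected_meta_results) -> GRPWeights:
    """w_i = (HR_i - 1) / SE(HR_i) from pooled meta-analysis results."""
    if len(selected_meta_results) == 0:
        raise ValueError("cannot build weights from an empty gene selection")
    rows = []
    weights: dict[str, float] = {}
    for m in selected_meta_results:
        if m.se_hr <= 0:
            raise ValueError(f"gene {m.gene_id!r}: SE(HR) must be positive")
        w = (m.pooled_hr - 1.0) / m.se_hr
        weights[m.gene_id] = w
        rows.append(
            {
                "gene_id": m.gene_id,
                "weight": w,
                "pooled_hr": m.pooled_hr,
                "se_hr": m.se_hr,
                "direction": m.direction,
            }
        )
    return GRPWeights(weights=weights, provenance=pd.DataFrame(rows))


def compute_grp_scores(expression: pd.DataFrame, weights: GRPWeights) -> pd.Series:
    """Raw GRP score per sample: weighted sum over the genes present.

    The sum runs over the intersection of weight genes and matrix genes;
    missing genes are logged, zero overlap is an error.
    """
    present = [g for g in weights.gene_ids if g in expression.index]
    missing = [g for g in weights.gene_ids if g not in expression.index]
    if not present:
        raise ValueError(f"no weight gene present in the expression matrix; missing: {missing}")
    if missing:
        logger.warning("%d weight gene(s) absent from the matrix: %s", len(missing), missing)
    w = np.array([weights.weights[g] for g in present])
    raw = w @ expression.loc[present].to_numpy(dtype=float)
    return pd.Series(raw, index=expression.columns, name="raw_score")


def z_normalize(raw_scores: pd.Series) -> pd.Series:
    """(x - mean) / sample SD (n-1 denominator), within one cohort."""
    x = np.asarray(raw_scores, dtype=float)
    if len(x) < 2:
        raise ValueError("z-normalization requires at least 2 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("z-normalization undefined: zero variance")
    z = (x - x.mean()) / sd
    return pd.Series(z, index=raw_scores.index, name="z_score")


def stratify_by_median(scores: pd.Series) -> pd.Series:
    """'high' if score > cohort median else 'low' (ties to low)."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("stratification requires at least 2 samples")
    if np.ptp(x) == 0.0:
        raise ValueError("all scores identical: stratification undefined")
    med = np.median(x)
    return pd.Series(
        np.where(x > med, "high", "low"), index=scores.index, name="stratum"
    )


def score_cohort(
    cohort: Cohort, weights: GRPWeights, gene_standardize: bool = False
) -> pd.DataFrame:
    """Score one cohort with frozen weights: raw, z and stratum per sample.

    ``gene_standardize`` z-scores each gene across the cohort before
    weighting (sensitivity analysis); the default consumes expression as
    loaded, and the single z-normalization is applied to the final score.
    """
    expression = cohort.expression
    if gene_standardize:
        values = expression.to_numpy(dtype=float)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 0
        values = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep]
        expression = pd.DataFrame(values, index=expression.index[keep], columns=expression.columns)
    raw = compute_grp_scores(expression, weights)
    z = z_normalize(raw)
    stratum = stratify_by_median(raw)
    return pd.DataFrame(
        {
            "sample_id": raw.index,
            "raw_score": raw.to_numpy(),
            "z_score": z.to_numpy(),
            "stratum": stratum.to_numpy(),
            "cohort_name": cohort.name,
        }
    ).reset_index(drop=True)
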