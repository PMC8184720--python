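"""Chemotherapy response encoding and ROC-based discrimination.

RECIST categories are collapsed into a binary outcome under two schemes:
responders {CR, PR} versus non-responders {SD, PD}, or complete response
versus everything else.  AUC is computed through the Mann-Whitney identity
with half credit for tied scores and no automatic orientation flipping.
A ridge-regularized logistic regression combines the GRP score with immune
enrichment features (optionally pre-filtered by a rank-sum test between the
response classes); its in-sample linear predictor is the combined score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from glycoprog.datamodel import RESPONSE_LEVELS
from glycoprog.enrichment import rank_sum_test

logger = logging.getLogger(__name__)

SCHEMES = {
    "CRPR_vs_SDPD": {"CR": 1, "PR": 1, "SD": 0, "PD": 0},
    "CR_vs_nonCR": {"CR": 1, "PR": 0, "SD": 0, "PD": 0},
}


@dataclass(frozen=True)
class ResponseEncoding:
    """Binary response labels for samples with a non-missing RECIST category."""

    scheme: str
    labels: pd.Series  # sample_id -> 0/1
    n_pos: int
    n_neg: int


def encode_response(clinical: pd.DataFrame, scheme: str) -> ResponseEncoding:
    """Collapse RECIST categories to binary labels under the given scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    if "chemo_response" not in clinical.columns:
        raise ValueError("clinical table has no chemo_response column")
    resp = clinical.set_index("sample_id")["chemo_response"]
    non_missing = resp.dropna()
    non_missing = non_missing[non_missing.astype(str).str.len() > 0]
    n_dropped = len(resp) - len(non_missing)
    if n_dropped:
        logger.info("encode_response: dropped %d sample(s) with missing response", n_dropped)
    if len(non_missing) == 0:
        raise ValueError("no sample has a non-missing chemotherapy response")
    unknown = sorted(set(non_missing.astype(str)) - set(RESPONSE_LEVELS))
    if unknown:
        raise ValueError(f"unknown response label(s): {unknown}")
    mapping = SCHEMES[scheme]
    labels = non_missing.astype(str).map(mapping).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"scheme {scheme}: all labels fall in one class (pos={n_pos}, neg={n_neg})")
    return ResponseEncoding(scheme=scheme, labels=labels, n_pos=n_pos, n_neg=n_neg)


def roc_auc(scores, binary_labels) -> float:
    """AUC via the Mann-Whitney rank identity, half credit for tied scores.

    Orientation is taken as given (larger score = predicted positive); no
    automatic flipping, so values below 0.5 indicate inverse association.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def combine_predictors(
    feature_matrix: pd.DataFrame,
    binary_labels,
    prefilter_p: float | None = None,
    always_keep: tuple[str, ...] = ("grp_score",),
    C: float = 100.0,
    cv: int | None = None,
) -> tuple[pd.Series, np.ndarray, float]:
    """Ridge-logistic combination of predictors; combined-score AUC.

    Parameters
    ----------
    feature_matrix : DataFrame (samples x features)
    binary_labels : 0/1 outcome per sample
    prefilter_p : optional rank-sum p threshold; features whose two-class
        rank-sum p is not below it are dropped (columns named in
        ``always_keep`` are exempt)
    C : inverse ridge penalty (small fixed penalty keeps separable data
        finite)
    cv : if given, the combined scores are out-of-fold decision values from
        stratified k-fold cross-validation and the AUC is honest; by default
        the scores and AUC are in-sample

    Returns (coefficients incl. intercept, combined linear-predictor scores,
    AUC of the combined score).
    """
    y = np.asarray(binary_labels, dtype=int)
    if feature_matrix.ndim != 2 or feature_matrix.shape[1] < 1:
        raise ValueError("feature_matrix must have at least one feature column")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = feature_matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")

    keep_cols = list(feature_matrix.columns)
    if prefilter_p is not None:
        kept = []
        for col in feature_matrix.columns:
            if col in always_keep:
                kept.append(col)
                continue
            vals = feature_matrix[col].to_numpy(dtype=float)
            _, p = rank_sum_test(vals[y == 1], vals[y == 0])
            if p < prefilter_p:
                kept.append(col)
        if not kept:
            raise ValueError("feature pre-filter removed every column")
        keep_cols = kept
    Xk = feature_matrix[keep_cols].to_numpy(dtype=float)

    scaler = StandardScaler()
    Xs = scaler.fit_transform(Xk)
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    model.fit(Xs, y)
    if cv is not None:
        from sklearn.model_selection import StratifiedKFold, cross_val_predict

        combined = cross_val_predict(
            LogisticRegression(C=C, solver="lbfgs", max_iter=5000),
            Xs, y,
            cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=0),
            method="decision_function",
        )
    else:
        combined = Xs @ model.coef_[0] + model.intercept_[0]
    auc = roc_auc(combined, y)
    coef = pd.Series(
        np.concatenate([[model.intercept_[0]], model.coef_[0]]),
        index=["(intercept)", *keep_cols],
        name="coefficient",
    )
    return coef, combined, auc
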