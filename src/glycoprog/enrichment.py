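"""Per-sample gene-set enrichment (ssGSEA) and association statistics.

The ssGSEA score of a gene set in one sample integrates the difference
between the weighted in-set empirical CDF and the unweighted out-of-set
ECDF over the sample's expression ranking (descending, average ranks for
ties).  In-set genes are weighted by rank^alpha (alpha = 0.25 by default),
normalized within the set; final scores are normalized by the global range
of the raw enrichment matrix, so a gene set that behaves like a random draw
scores near 0.  Being rank-based, scores are invariant to strictly
increasing transforms of expression.

Association helpers wrap scipy: Mann-Whitney rank-sum (exact enumeration for
n1 + n2 <= 10 without ties, normal approximation with tie correction
otherwise), Spearman correlation, and a chi-square contingency test with an
automatic Fisher-exact fallback for sparse 2x2 tables.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycoprog.datamodel import GeneSet
from glycoprog.meta import bh_adjust

logger = logging.getLogger(__name__)


def _sample_enrichment(rank_values: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment for one sample.

    ``rank_values``: average ascending ranks (higher expression = larger);
    ``order``: gene indices sorted by decreasing rank (deterministic
    tie-break); ``in_set``: boolean membership mask over genes.
    """
    member = in_set[order]
    weights = rank_values[order] ** alpha
    w_in = np.where(member, weights, 0.0)
    total_in = w_in.sum()
    n_out = int((~member).sum())
    p_in = np.cumsum(w_in) / total_in
    p_out = np.cumsum(~member) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expression: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA enrichment matrix (sets x samples).

    Sets with no gene in the matrix are dropped with a warning; a set that
    covers the entire gene universe is an error (the out-of-set ECDF is
    undefined).  With ``normalize`` the matrix is divided by its global
    range (max - min across all sets and samples).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    genes = expression.index.to_numpy()
    universe = set(genes)
    masks: dict[str, np.ndarray] = {}
    for gs in gene_sets:
        overlap = gs.members & universe
        if not overlap:
            logger.warning("gene set %r has no gene in the matrix, dropped", gs.name)
            continue
        if len(overlap) == len(universe):
            raise ValueError(f"gene set {gs.name!r} covers the entire gene universe")
        masks[gs.name] = np.isin(genes, sorted(overlap))
    if not masks:
        raise ValueError("no gene set overlaps the expression matrix")

    values = expression.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    scores = np.empty((len(masks), n_samples))
    # precedence for ordering ties: gene identifier, so results are
    # deterministic under permutation of input rows
    id_order = np.argsort(genes.astype(str), kind="stable")
    for s in range(n_samples):
        col = values[:, s]
        ranks = stats.rankdata(col)  # ascending, average for ties
        # decreasing rank; among ties, increasing gene id
        order = id_order[np.argsort(-ranks[id_order], kind="stable")]
        for k, mask in enumerate(masks.values()):
            scores[k, s] = _sample_enrichment(ranks, order, mask, alpha)
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return pd.DataFrame(scores, index=list(masks), columns=expression.columns)


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, p).

    Exact enumeration when n1 + n2 <= 10 and no cross-group ties, otherwise
    the normal approximation with tie correction (no continuity correction,
    so identical groups give p = 1 exactly).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman_corr requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def contingency_test(table) -> tuple[float, float, str]:
    """Chi-square independence test on a 2 x k count table.

    No continuity correction.  For 2x2 tables with any expected count < 5
    the Fisher exact test (two-sided) is used instead; the statistic is then
    the odds ratio.  Returns (statistic, p, method_used).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    return float(chi2), float(p), "chi_square"


def compare_enrichment_by_group(
    enrichment: pd.DataFrame, group_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Rank-sum comparison of every gene set between two sample groups.

    Returns a tidy table with per-set group medians, U, raw p and BH q
    (one correction across all sets).
    """
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    mask = labels == levels[0]
    rows = []
    for set_name, row in enrichment.iterrows():
        vals = row.to_numpy(dtype=float)
        u, p = rank_sum_test(vals[mask], vals[~mask])
        rows.append(
            {
                "set_name": set_name,
                f"median_{levels[0]}": float(np.median(vals[mask])),
                f"median_{levels[1]}": float(np.median(vals[~mask])),
                "U": u,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].clip(lower=np.nextafter(0, 1)))
    return out
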