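import numpy as np
import pandas as pd
import pytest

from glycoprog.meta import (
    MetaResult,
    meta_screen,
    select_prognostic_genes,
)
from glycoprog.score import (
    compute_grp_scores,
    compute_weights,
    score_cohort,
    stratify_by_median,
    z_normalize,
)
from glycoprog.simulate import SimConfig, simulate_multi_cohort
from glycoprog.survival import fit_cox, logrank_test


def _meta(gene, hr, se_hr):
    # back out the log-scale fields so pooled_hr/se_hr land where we want
    log_hr = np.log(hr)
    return MetaResult(
        gene_id=gene,
        pooled_log_hr=log_hr,
        pooled_se_log_hr=se_hr / hr,
        meta_p=1e-5,
        n_cohorts=6,
        fdr_q=1e-4,
    )


class TestWeights:
    @pytest.mark.parametrize(
        "hr, se_hr, expected",
        [(1.0, 0.3, 0.0), (2.0, 0.5, 2.0), (0.5, 0.25, -2.0)],
    )
    def test_weight_formula(self, hr, se_hr, expected):
        w = compute_weights([_meta("g", hr, se_hr)])
        assert w.weights["g"] == pytest.approx(expected, rel=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_weights([])

    def test_tsv_round_trip(self, tmp_path):
        from glycoprog.score import GRPWeights

        w = compute_weights([_meta("g1", 2.0, 0.5), _meta("g2", 0.5, 0.25)])
        w.to_tsv(tmp_path / "w.tsv")
        w2 = GRPWeights.from_tsv(tmp_path / "w.tsv")
        assert w2.weights == pytest.approx(w.weights)


class TestRawScores:
    def _expr(self, data, samples=("s1", "s2", "s3")):
        return pd.DataFrame(data, columns=list(samples))

    def test_zero_weights_give_zero_scores(self):
        expr = self._expr({"s1": [1.0, 2.0], "s2": [3.0, 4.0], "s3": [5.0, 6.0]})
        expr.index = ["g1", "g2"]
        w = compute_weights([_meta("g1", 1.0, 0.3), _meta("g2", 1.0, 0.4)])
        assert (compute_grp_scores(expr, w) == 0).all()

    def test_single_gene_scalar_product(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=["a", "b", "c"])
        expr.loc["pad"] = 0.0
        w = compute_weights([_meta("g1", 2.0, 0.5)])  # weight 2
        np.testing.assert_allclose(compute_grp_scores(expr, w), [2.0, 4.0, 6.0])

    def test_two_term_sum(self):
        expr = pd.DataFrame(
            {"s": [1.5, 2.0]}, index=["g1", "g2"]
        ).assign(pad=[0.0, 0.0])
        w = compute_weights([_meta("g1", 2.0, 0.5), _meta("g2", 0.5, 0.5)])  # +2, -1
        assert compute_grp_scores(expr[["s", "pad"]], w)["s"] == pytest.approx(1.0)

    def test_zero_overlap_rejected_listing_missing(self):
        expr = pd.DataFrame(np.ones((2, 2)), index=["x", "y"], columns=["a", "b"])
        w = compute_weights([_meta("g1", 2.0, 0.5)])
        with pytest.raises(ValueError, match="g1"):
            compute_grp_scores(expr, w)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(4, 5)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{i}" for i in range(5)],
        )
        w1 = compute_weights([_meta("g1", 2.0, 0.5), _meta("g3", 0.5, 0.2)])
        w2 = compute_weights([_meta("g2", 1.5, 0.4), _meta("g3", 3.0, 0.7)])
        from glycoprog.score import GRPWeights

        merged = {
            g: w1.weights.get(g, 0.0) + w2.weights.get(g, 0.0)
            for g in set(w1.weights) | set(w2.weights)
        }
        w_sum = GRPWeights(weights=merged, provenance=pd.DataFrame({"gene_id": list(merged)}))
        np.testing.assert_allclose(
            compute_grp_scores(expr, w_sum),
            compute_grp_scores(expr, w1) + compute_grp_scores(expr, w2),
            atol=1e-12,
        )


class TestNormalizeAndStratify:
    def test_z_normalize_small_example(self):
        z = z_normalize(pd.Series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_z_moments(self):
        rng = np.random.default_rng(1)
        z = z_normalize(pd.Series(rng.normal(5, 3, 50)))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            z_normalize(pd.Series([2.0, 2.0, 2.0]))

    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([-1.0, 0.0, 1.0, 2.0], ["low", "low", "high", "high"]),
            ([1.0, 2.0, 3.0], ["low", "low", "high"]),  # tie at the median -> low
        ],
    )
    def test_median_split(self, scores, expected):
        assert list(stratify_by_median(pd.Series(scores))) == expected

    def test_strata_invariant_to_increasing_transform(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.normal(size=21))
        a = stratify_by_median(s)
        b = stratify_by_median(np.exp(2 * s) + 3)
        assert (a == b).all()

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_median(pd.Series([1.0, 1.0]))


class TestScoreCohort:
    def test_raw_and_z_scores_give_same_strata_and_logrank(self, sim_study):
        _, cohorts, truth = sim_study
        cohort = cohorts[0]
        meta = meta_screen(cohorts[:3], [f"GLY_{i + 1:03d}" for i in range(106)])
        weights = compute_weights(select_prognostic_genes(meta))
        raw = compute_grp_scores(cohort.expression, weights)
        z = z_normalize(raw)
        strata_raw = stratify_by_median(raw)
        strata_z = stratify_by_median(z)
        assert (strata_raw == strata_z).all()
        t = cohort.clinical["os_time"].to_numpy()
        e = cohort.clinical["os_event"].to_numpy()
        assert logrank_test(t, e, strata_raw.to_numpy()) == pytest.approx(
            logrank_test(t, e, strata_z.to_numpy())
        )

    def test_gene_standardize_switch_changes_scores_not_interface(self, sim_study):
        _, cohorts, truth = sim_study
        meta = meta_screen(cohorts[:3], [f"GLY_{i + 1:03d}" for i in range(106)])
        weights = compute_weights(select_prognostic_genes(meta))
        plain = score_cohort(cohorts[0], weights)
        standardized = score_cohort(cohorts[0], weights, gene_standardize=True)
        assert set(plain.columns) == set(standardized.columns)
        assert not np.allclose(plain["raw_score"], standardized["raw_score"])

    def test_high_stratum_has_worse_survival_under_planted_effects(self):
        """Across 50 seeded studies the high stratum carries HR > 1, p < 0.05."""
        universe = [f"GLY_{i + 1:03d}" for i in range(106)]
        successes = 0
        for seed in range(50):
            config = SimConfig(seed=seed)
            cohorts, _ = simulate_multi_cohort(config)
            meta = meta_screen(cohorts, universe)
            selected = select_prognostic_genes(meta)
            if not selected:
                continue
            weights = compute_weights(selected)
            frames, times, events = [], [], []
            for cohort in cohorts:
                raw = compute_grp_scores(cohort.expression, weights)
                frames.append((stratify_by_median(raw) == "high").astype(float))
                times.append(cohort.clinical["os_time"].to_numpy())
                events.append(cohort.clinical["os_event"].to_numpy())
            high = pd.concat(frames).to_numpy()
            fit = fit_cox(high, np.concatenate(times), np.concatenate(events))
            if fit.hr[0] > 1 and fit.wald_p[0] < 0.05:
                successes += 1
        assert successes >= 45
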