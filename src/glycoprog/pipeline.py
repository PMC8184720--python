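"""End-to-end orchestration: screen -> pool -> select -> weight -> score ->
stratify -> evaluate -> enrich -> chemo.

Weights are derived exclusively from the training cohorts; validation
cohorts are scored with the frozen weights, and only the score's
z-normalization and median cut-off are recomputed per cohort.  Scoring of
every cohort happens before any evaluation stage reads survival outcomes,
so validation outcomes cannot leak into score construction.

Recurrence-free survival, when present, re-runs the evaluation stages with
the rfs columns; there is no separate code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycoprog.chemo import SCHEMES, combine_predictors, encode_response, roc_auc
from glycoprog.datamodel import Cohort, GeneSet, load_cohort, read_gmt
from glycoprog.enrichment import compare_enrichment_by_group, ssgsea_scores
from glycoprog.meta import meta_results_table, meta_screen, select_prognostic_genes
from glycoprog.score import GRPWeights, compute_weights, score_cohort
from glycoprog.survival import fit_cox, km_estimate, logrank_test, time_dependent_auc

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (365.0, 730.0, 1095.0)  # 1, 2, 3 years in days


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    training: list[Cohort]
    validation: list[Cohort] = field(default_factory=list)
    gene_universe: tuple[str, ...] = ()
    immune_sets: list[GeneSet] = field(default_factory=list)
    p_threshold: float = 0.001
    fdr_threshold: float = 0.001
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    response_scheme: str = "CRPR_vs_SDPD"
    gene_standardize: bool = False
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if len(self.training) < 1:
            raise ValueError("at least one training cohort is required")
        for thr in (self.p_threshold, self.fdr_threshold):
            if not (0 < thr < 1):
                raise ValueError("thresholds must lie in (0, 1)")
        if self.response_scheme not in SCHEMES:
            raise ValueError(f"unknown response scheme {self.response_scheme!r}")
        if not self.gene_universe:
            # default universe: genes shared by every training cohort
            shared = set(self.training[0].gene_ids)
            for c in self.training[1:]:
                shared &= set(c.gene_ids)
            self.gene_universe = tuple(sorted(shared))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        spec = yaml.safe_load(Path(path).read_text())
        training = [
            load_cohort(c["expression"], c["clinical"], c["name"])
            for c in spec.get("training", [])
        ]
        validation = [
            load_cohort(c["expression"], c["clinical"], c["name"])
            for c in spec.get("validation", [])
        ]
        universe: tuple[str, ...] = ()
        if spec.get("glycolysis_gmt"):
            sets = read_gmt(spec["glycolysis_gmt"])
            universe = tuple(sorted(set().union(*(s.members for s in sets))))
        immune = read_gmt(spec["immune_gmt"]) if spec.get("immune_gmt") else []
        return cls(
            training=training,
            validation=validation,
            gene_universe=universe,
            immune_sets=immune,
            p_threshold=float(spec.get("p_threshold", 0.001)),
            fdr_threshold=float(spec.get("fdr_threshold", 0.001)),
            horizons=tuple(spec.get("horizons", DEFAULT_HORIZONS)),
            response_scheme=spec.get("response_scheme", "CRPR_vs_SDPD"),
            gene_standardize=bool(spec.get("gene_standardize", False)),
            seed=int(spec.get("seed", 0)),
            output_dir=spec.get("output_dir"),
        )


@dataclass
class RunReport:
    """Per-stage tables plus a scalar summary and a config echo."""

    tables: dict[str, pd.DataFrame]
    summary: dict
    config_echo: dict
    version: str

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        payload = {"version": self.version, "config": self.config_echo, "summary": self.summary}
        (out / "report.json").write_text(json.dumps(payload, indent=1, default=str))


def _evaluate_survival(
    scores: pd.DataFrame,
    cohorts: list[Cohort],
    horizons: tuple[float, ...],
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """KM/log-rank, Cox and time-AUC tables over all scored cohorts."""
    km_rows, cox_rows, auc_rows = [], [], []
    pooled_frames = []
    for cohort in cohorts:
        if time_col not in cohort.clinical.columns or event_col not in cohort.clinical.columns:
            logger.info("cohort %s: no %s/%s columns, evaluation skipped", cohort.name, time_col, event_col)
            continue
        sub = scores[scores["cohort_name"] == cohort.name].set_index("sample_id")
        clin = cohort.clinical.set_index("sample_id").loc[sub.index]
        mask = clin[time_col].notna() & clin[event_col].notna()
        t = clin.loc[mask, time_col].to_numpy(dtype=float)
        e = clin.loc[mask, event_col].to_numpy(dtype=float)
        z = sub.loc[mask, "z_score"].to_numpy(dtype=float)
        stratum = sub.loc[mask, "stratum"].to_numpy()

        chi2, p = logrank_test(t, e, stratum)
        high = stratum == "high"
        km_rows.append(
            {
                "cohort_name": cohort.name,
                "endpoint": time_col,
                "n": int(mask.sum()),
                "n_events": int(e.sum()),
                "n_high": int(high.sum()),
                "n_low": int((~high).sum()),
                "median_surv_high": _median_survival(t[high], e[high]),
                "median_surv_low": _median_survival(t[~high], e[~high]),
                "logrank_chi2": chi2,
                "logrank_p": p,
            }
        )
        fit_uni = fit_cox(z, t, e, names=("grp_z",))
        cox_rows.append(
            {
                "cohort_name": cohort.name,
                "endpoint": time_col,
                "model": "univariate",
                "covariate": "grp_z",
                "hr": float(fit_uni.hr[0]),
                "log_hr": float(fit_uni.log_hr[0]),
                "se_log_hr": float(fit_uni.se_log_hr[0]),
                "wald_p": float(fit_uni.wald_p[0]),
            }
        )
        covars = [c for c in ("age",) if c in clin.columns]
        if covars:
            X = pd.DataFrame({"grp_z": z})
            for c in covars:
                X[c] = clin.loc[mask, c].to_numpy(dtype=float)
            try:
                fit_multi = fit_cox(X, t, e)
                for j, name in enumerate(fit_multi.names):
                    cox_rows.append(
                        {
                            "cohort_name": cohort.name,
                            "endpoint": time_col,
                            "model": "multivariate",
                            "covariate": name,
                            "hr": float(fit_multi.hr[j]),
                            "log_hr": float(fit_multi.log_hr[j]),
                            "se_log_hr": float(fit_multi.se_log_hr[j]),
                            "wald_p": float(fit_multi.wald_p[j]),
                        }
                    )
            except Exception as err:  # degenerate covariates in tiny cohorts
                logger.warning("cohort %s: multivariate Cox skipped: %s", cohort.name, err)

        for horizon in horizons:
            try:
                auc = time_dependent_auc(z, t, e, horizon)
            except ValueError as err:
                logger.info("cohort %s horizon %g: time AUC skipped (%s)", cohort.name, horizon, err)
                continue
            auc_rows.append(
                {"cohort_name": cohort.name, "endpoint": time_col, "horizon": horizon, "auc": auc}
            )
        pooled_frames.append(pd.DataFrame({"t": t, "e": e, "z": z}))

    if len(pooled_frames) > 1:
        pooled = pd.concat(pooled_frames, ignore_index=True)
        for horizon in horizons:
            try:
                auc = time_dependent_auc(pooled["z"], pooled["t"], pooled["e"], horizon)
            except ValueError:
                continue
            auc_rows.append(
                {"cohort_name": "POOLED", "endpoint": time_col, "horizon": horizon, "auc": auc}
            )
    return pd.DataFrame(km_rows), pd.DataFrame(cox_rows), pd.DataFrame(auc_rows)


def _median_survival(t: np.ndarray, e: np.ndarray) -> float:
    curve = km_estimate(t, e)
    below = curve.survival_prob <= 0.5
    return float(curve.event_times[below.argmax()]) if below.any() else float("nan")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; see module docstring for the stage order."""
    from glycoprog import __version__

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    # 1. screening + meta-analysis on training cohorts only
    universe = [
        g for g in config.gene_universe
        if any(g in c.expression.index for c in config.training)
    ]
    meta = meta_screen(config.training, universe)
    tables["meta_analysis"] = meta_results_table(meta)

    # 2. selection at the configured thresholds
    selected = select_prognostic_genes(meta, config.p_threshold, config.fdr_threshold)
    if not selected:
        raise RuntimeError(
            f"empty gene selection at p < {config.p_threshold} and "
            f"FDR < {config.fdr_threshold}; aborting"
        )
    tables["selected_genes"] = meta_results_table(selected)
    summary["n_genes_screened"] = len(meta)
    summary["n_genes_selected"] = len(selected)
    summary["n_poor"] = sum(m.direction == "poor" for m in selected)
    summary["n_good"] = sum(m.direction == "good" for m in selected)

    # 3. frozen weights from the training meta-analysis
    weights = compute_weights(selected)
    tables["weights"] = weights.provenance

    # 4. score and stratify every cohort (training first, then validation)
    all_cohorts = list(config.training) + list(config.validation)
    score_frames = [score_cohort(c, weights, config.gene_standardize) for c in all_cohorts]
    scores = pd.concat(score_frames, ignore_index=True)
    scores["role"] = np.where(
        scores["cohort_name"].isin([c.name for c in config.training]), "training", "validation"
    )
    tables["scores"] = scores

    # 5. survival evaluation (OS always; RFS when the columns exist)
    km, cox, auc = _evaluate_survival(scores, all_cohorts, config.horizons)
    tables["km_logrank"] = km
    tables["cox"] = cox
    tables["time_auc"] = auc
    rfs_cohorts = [c for c in all_cohorts if "rfs_time" in c.clinical.columns]
    if rfs_cohorts:
        km_r, cox_r, auc_r = _evaluate_survival(
            scores, rfs_cohorts, config.horizons, time_col="rfs_time", event_col="rfs_event"
        )
        tables["km_logrank"] = pd.concat([km, km_r], ignore_index=True)
        tables["cox"] = pd.concat([cox, cox_r], ignore_index=True)
        tables["time_auc"] = pd.concat([auc, auc_r], ignore_index=True)

    # 6. enrichment: glycolysis + immune ssGSEA per cohort, compared by stratum
    enrich_rows = []
    immune_by_cohort: dict[str, pd.DataFrame] = {}
    if config.immune_sets:
        for cohort in all_cohorts:
            try:
                es = ssgsea_scores(cohort.expression, config.immune_sets)
            except ValueError as err:
                logger.warning("cohort %s: enrichment skipped (%s)", cohort.name, err)
                continue
            immune_by_cohort[cohort.name] = es
            sub = scores[scores["cohort_name"] == cohort.name].set_index("sample_id")
            comp = compare_enrichment_by_group(es, sub.loc[es.columns, "stratum"])
            comp.insert(0, "cohort_name", cohort.name)
            enrich_rows.append(comp)
    if enrich_rows:
        tables["immune_enrichment"] = pd.concat(enrich_rows, ignore_index=True)
    else:
        logger.info("enrichment stage skipped: no immune gene sets configured")

    # 7. chemosensitivity: GRP AUC under both schemes + combined model
    chemo_rows = []
    for cohort in all_cohorts:
        if "chemo_response" not in cohort.clinical.columns:
            continue
        sub = scores[scores["cohort_name"] == cohort.name].set_index("sample_id")
        for scheme in SCHEMES:
            try:
                enc = encode_response(cohort.clinical, scheme)
            except ValueError as err:
                logger.info("cohort %s scheme %s: %s", cohort.name, scheme, err)
                continue
            z = sub.loc[enc.labels.index, "z_score"]
            # low GRP is the pro-response direction; orient so AUC > 0.5
            # means the score discriminates responders
            auc_grp = roc_auc(-z, enc.labels)
            row = {
                "cohort_name": cohort.name,
                "scheme": scheme,
                "n_pos": enc.n_pos,
                "n_neg": enc.n_neg,
                "auc_grp": auc_grp,
            }
            if scheme == config.response_scheme and cohort.name in immune_by_cohort:
                feats = immune_by_cohort[cohort.name].T.loc[enc.labels.index]
                feats.insert(0, "grp_score", -z)
                try:
                    coef, _, auc_comb = combine_predictors(
                        feats, enc.labels, prefilter_p=0.05, always_keep=("grp_score",)
                    )
                    row["auc_combined"] = auc_comb
                    row["n_features"] = len(coef) - 1
                except ValueError as err:
                    logger.info("cohort %s: combined model skipped (%s)", cohort.name, err)
            chemo_rows.append(row)
    if chemo_rows:
        tables["chemo_response"] = pd.DataFrame(chemo_rows)
    else:
        logger.info("chemo stage skipped: no cohort carries chemo_response")

    config_echo = {
        "training": [c.name for c in config.training],
        "validation": [c.name for c in config.validation],
        "n_gene_universe": len(config.gene_universe),
        "p_threshold": config.p_threshold,
        "fdr_threshold": config.fdr_threshold,
        "horizons": list(config.horizons),
        "response_scheme": config.response_scheme,
        "gene_standardize": config.gene_standardize,
        "seed": config.seed,
    }
    report = RunReport(tables=tables, summary=summary, config_echo=config_echo, version=__version__)
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
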