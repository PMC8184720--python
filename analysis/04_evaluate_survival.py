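"""Evaluate the GRP strata: Kaplan-Meier / log-rank, Cox and time-dependent ROC.

Per cohort: log-rank test of high vs low GRP, univariate Cox on the z-score
(and age-adjusted multivariate), and cumulative/dynamic AUC at 1/2/3 years.
Writes km_logrank.tsv, cox.tsv, time_auc.tsv and a KM figure per cohort.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from glycoprog.datamodel import load_cohort
from glycoprog.pipeline import DEFAULT_HORIZONS, _evaluate_survival
from glycoprog.survival import km_estimate

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--tables", type=Path, default=Path("results/tables"))
parser.add_argument("--figures", type=Path, default=Path("results/figures"))
args = parser.parse_args()
args.figures.mkdir(parents=True, exist_ok=True)

config = yaml.safe_load((args.data / "config.yaml").read_text())
cohorts = [
    load_cohort(e["expression"], e["clinical"], e["name"])
    for role in ("training", "validation")
    for e in config[role]
]
scores = pd.read_csv(args.tables / "grp_scores.tsv", sep="\t")

km, cox, auc = _evaluate_survival(scores, cohorts, DEFAULT_HORIZONS)
km.to_csv(args.tables / "km_logrank.tsv", sep="\t", index=False)
cox.to_csv(args.tables / "cox.tsv", sep="\t", index=False)
auc.to_csv(args.tables / "time_auc.tsv", sep="\t", index=False)

print("high vs low GRP, overall survival:")
for _, row in km.iterrows():
    print(f"  {row['cohort_name']}: log-rank chi2 = {row['logrank_chi2']:.1f}, "
          f"p = {row['logrank_p']:.2e}")
pooled = auc[auc["cohort_name"] == "POOLED"]
if not pooled.empty:
    spans = ", ".join(f"{int(r.horizon / 365)}y = {r.auc:.3f}" for r in pooled.itertuples())
    print(f"pooled time-dependent AUC: {spans}")

# KM figures: one panel per cohort, stepped survival by stratum
for cohort in cohorts:
    sub = scores[scores["cohort_name"] == cohort.name].set_index("sample_id")
    clin = cohort.clinical.set_index("sample_id").loc[sub.index]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for stratum, color in (("low", "tab:blue"), ("high", "tab:red")):
        mask = (sub["stratum"] == stratum).to_numpy()
        curve = km_estimate(clin["os_time"][mask], clin["os_event"][mask])
        ax.step(
            [0, *curve.event_times], [1, *curve.survival_prob],
            where="post", color=color, label=f"{stratum} GRP (n={mask.sum()})",
        )
    p = km.loc[km["cohort_name"] == cohort.name, "logrank_p"].iloc[0]
    ax.set(xlabel="days", ylabel="overall survival", ylim=(0, 1.02),
           title=f"{cohort.name}  (log-rank p = {p:.1e})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(args.figures / f"km_{cohort.name}.png", dpi=120)
    plt.close(fig)
print(f"KM figures written to {args.figures}")
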