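"""Chemosensitivity prediction: GRP score alone and combined with immune cells.

Encodes RECIST response two ways (CR/PR vs SD/PD responders, and CR vs
non-CR), measures the ROC AUC of the (low-oriented) GRP score, and fits a
ridge-logistic combination of the GRP score with the immune cell types that
differ between response classes (rank-sum p < 0.05).  Writes
chemo_response.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from glycoprog.chemo import combine_predictors, encode_response, roc_auc
from glycoprog.datamodel import load_cohort, read_gmt
from glycoprog.enrichment import ssgsea_scores

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--tables", type=Path, default=Path("results/tables"))
args = parser.parse_args()

config = yaml.safe_load((args.data / "config.yaml").read_text())
immune_sets = read_gmt(config["immune_gmt"])
scores = pd.read_csv(args.tables / "grp_scores.tsv", sep="\t")

rows = []
for role in ("training", "validation"):
    for entry in config[role]:
        cohort = load_cohort(entry["expression"], entry["clinical"], entry["name"])
        sub = scores[scores["cohort_name"] == cohort.name].set_index("sample_id")
        for scheme in ("CRPR_vs_SDPD", "CR_vs_nonCR"):
            enc = encode_response(cohort.clinical, scheme)
            z = sub.loc[enc.labels.index, "z_score"]
            row = {
                "cohort_name": cohort.name,
                "scheme": scheme,
                "n_pos": enc.n_pos,
                "n_neg": enc.n_neg,
                "auc_grp": roc_auc(-z, enc.labels),
            }
            if scheme == "CRPR_vs_SDPD":
                es = ssgsea_scores(cohort.expression, immune_sets)
                feats = es.T.loc[enc.labels.index]
                feats.insert(0, "grp_score", -z)
                coef, _, auc_comb = combine_predictors(
                    feats, enc.labels, prefilter_p=0.05, always_keep=("grp_score",)
                )
                row["auc_combined"] = auc_comb
                row["n_immune_features"] = len(coef) - 2  # minus intercept and GRP
            rows.append(row)

table = pd.DataFrame(rows)
table.to_csv(args.tables / "chemo_response.tsv", sep="\t", index=False)
for scheme, group in table.groupby("scheme"):
    print(f"{scheme}: mean GRP AUC = {group['auc_grp'].mean():.3f}")
comb = table["auc_combined"].dropna()
print(f"GRP + immune combined (responder scheme): mean AUC = {comb.mean():.3f}")
print("low GRP is oriented as the pro-response direction (AUC > 0.5 = "
      "lower score predicts response)")
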