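"""Generate the synthetic multi-cohort PDAC-like study used by the analysis.

Writes, under results/data/: one expression + clinical TSV pair per cohort
(6 training + 1 validation, 150 patients each), the glycolysis gene-set GMT,
the 28-set immune marker GMT, the ground-truth JSON and a ready-to-run
pipeline config.
"""

import argparse
from pathlib import Path

from glycoprog.datamodel import write_cohort, write_gmt
from glycoprog.simulate import (
    SimConfig,
    attach_response,
    glycolysis_gene_set,
    immune_gene_sets,
    simulate_multi_cohort,
)
import yaml

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
config = SimConfig(n_cohorts=7, seed=args.seed)
cohorts, truth = simulate_multi_cohort(config)
cohorts = [attach_response(c, truth) for c in cohorts]

entries = []
for cohort in cohorts:
    expr = args.out / f"{cohort.name}_expression.tsv"
    clin = args.out / f"{cohort.name}_clinical.tsv"
    write_cohort(cohort, expr, clin)
    entries.append({"name": cohort.name, "expression": str(expr), "clinical": str(clin)})
    events = int(cohort.clinical["os_event"].sum())
    print(f"{cohort.name}: {cohort.n_samples} patients, {events} deaths "
          f"({100 * (1 - events / cohort.n_samples):.0f}% censored)")

write_gmt([glycolysis_gene_set(config)], args.out / "glycolysis.gmt")
write_gmt(immune_gene_sets(truth), args.out / "immune.gmt")
truth.to_json(args.out / "truth.json")
(args.out / "config.yaml").write_text(
    yaml.safe_dump(
        {
            "training": entries[:6],
            "validation": entries[6:],
            "glycolysis_gmt": str(args.out / "glycolysis.gmt"),
            "immune_gmt": str(args.out / "immune.gmt"),
            "seed": args.seed,
        },
        sort_keys=False,
    )
)
print(f"\nplanted {len(truth.planted_gene_ids)} prognostic genes "
      f"({sum(1 for b in truth.planted_log_hr.values() if b > 0)} poor / "
      f"{sum(1 for b in truth.planted_log_hr.values() if b < 0)} good direction)")
print(f"wrote cohorts, gene sets, truth and config to {args.out}")
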