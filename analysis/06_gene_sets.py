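#!/usr/bin/env python
"""Cross-cohort gene sets at noise fold-change thresholds.

Five cohorts are simulated independently (distinct affected-gene subsets, as
different cancer types would have) and their tumor-vs-normal noise tables
intersected: genes with increased noise in all five, at ratio thresholds 1,
1.5 and 2, and genes with noise decreased (by any amount, and by >10%)
everywhere.  Gene lists are exported one symbol per line for enrichment tools.
"""

from pathlib import Path

from popnoise.experiments import paired_groups
from popnoise.gene_sets import decreased_set, increased_set, write_gene_list
from popnoise.io import write_json
from popnoise.noise import noise_table
from popnoise.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "gene_sets"
OUT.mkdir(parents=True, exist_ok=True)

tables = {}
for i in range(5):
    config = SimulationConfig(n_genes=800, n_patients=50, seed=3000 + i)
    cohort, _ = simulate_cohort(config)
    normals, tumors = paired_groups(cohort)
    tables[f"cohort{i + 1}"] = noise_table(
        cohort, normals, tumors, label_a="normal", label_b="tumor"
    )

counts = {}
for threshold in (1.0, 1.5, 2.0):
    res = increased_set(tables, threshold)
    counts[f"increased_gt_{threshold:g}"] = len(res.intersection)
    write_gene_list(sorted(res.intersection), OUT / f"increased_gt_{threshold:g}.txt")
for threshold in (1.0, 0.9):
    res = decreased_set(tables, threshold)
    counts[f"decreased_lt_{threshold:g}"] = len(res.intersection)
    write_gene_list(sorted(res.intersection), OUT / f"decreased_lt_{threshold:g}.txt")

write_json(counts, OUT / "counts.json")
print(
    "shared across 5 cohorts of 800 genes: "
    f"{counts['increased_gt_1']} increased, "
    f"{counts['increased_gt_1.5']} at >1.5-fold, "
    f"{counts['increased_gt_2']} at >2-fold; "
    f"{counts['decreased_lt_1']} decreased, "
    f"{counts['decreased_lt_0.9']} decreased >10% "
    "(increased noise dominates, decreases are rare)"
)
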