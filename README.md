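# popnoise

Population-level gene expression noise analysis for paired tumor–normal
RNA-seq cohorts.

Bulk transcriptomes of a patient cohort carry a second signal besides mean
expression: how *variable* each gene is across patients. `popnoise` measures
that variability per gene as the coefficient of variation,

    Noise(g) = SD(x_g) / mean(x_g),

and compares it between patient groups — tumor vs paired normal tissue,
high- vs low-purity tumors, top vs bottom quartiles of p53 pathway activity
(geometric mean of CDKN1A and MDM2) or cytolytic immune activity (geometric
mean of GZMA and PRF1), and early (stage I) vs late (stage III/IV) disease.
Each comparison reports, over all analyzable genes, the fraction with noise
ratio Noise_B/Noise_A > 1, the median log10 noise ratio, and a two-sided
Wilcoxon signed-rank test of that median against zero (exact for small n,
tie-corrected normal approximation otherwise), with an optional
patient-label permutation null for the log-ratio histogram. Gene sets with
noise increased (or decreased) beyond a fold-change threshold in every cohort
of a panel can be extracted and exported for enrichment tools.

It is written for computational biologists analyzing TCGA-style cohorts
(gene × sample TSV of normalized abundances plus a sample sheet with patient,
tissue, optional purity and stage) and ships a synthetic cohort generator
with known ground truth — per-gene lognormal expression, controllable tumor
noise inflation, latent marker-driven activity scores, Beta-distributed
purity with contaminant mixing — so every stage of the pipeline is testable
without external downloads.

## Worked example

Simulate a 2000-gene, 50-patient paired cohort with purity mixing, then
compare tumor against normal:

```sh
popnoise simulate --config sim.yaml \
    --out-matrix matrix.tsv --out-sheet sheet.tsv --out-truth truth.tsv
popnoise noise-compare --matrix matrix.tsv --sheet sheet.tsv \
    --group-a tissue=normal --group-b tissue=tumor \
    --out-table noise_table.tsv --out-summary summary.json
```

with `sim.yaml`:

```yaml
n_genes: 2000
n_patients: 50
purity_model: beta
purity_alpha: 16.0
purity_beta: 4.0
seed: 2026
```

This prints:

```
simulated 2000 genes x 100 samples (50 patients), 1800 affected genes
2000 genes (0 excluded): fraction_increased=0.9515, median_log_ratio=0.1890, wilcoxon_p=0
```

Read: of 2000 analyzable genes, 95.2% are noisier across tumor samples than
across the paired normals (the generator inflated the tumor lognormal shape
1.5× for 90% of genes, and purity mixing adds more), the median log10 noise
ratio is 0.19, and the signed-rank p-value underflows — the median log-ratio
is overwhelmingly above zero. On a null cohort (`inflation_factor: 1.0`,
`fraction_affected: 0.0`, `purity_model: none`) the same command reports a
fraction near 0.50.

The numbered drivers under `analysis/` run the full study on synthetic data —
`01_simulate_cohorts.py` through `06_gene_sets.py` (tumor vs normal, purity
subgroups and purity sweep, activity quartiles with and without coupling,
stage groups as a negative control, cross-cohort gene sets) — writing tables
under `results/`. `popnoise run-all` produces the same bundle from any
matrix + sheet pair, with a manifest recording config, seed, version and
input checksums.

The model, parameter meanings, and every numerical convention are documented
in [docs/methods.md](docs/methods.md).

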