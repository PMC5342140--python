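# Methods

## The statistic

Population-level expression noise of a gene is its coefficient of variation
across a patient group:

    noise(g) = SD(x_g) / mean(x_g)

computed on normalized, non-negative abundances (RSEM-like), with the sample
standard deviation (n−1 denominator — the spreadsheet STDEV convention,
which is what "STDEV/AVERAGE" style analyses use). Two groups A and B are
compared per gene through

    ratio(g)     = noise_B(g) / noise_A(g)
    log_ratio(g) = log10 ratio(g)

and summarized by (a) the fraction of genes with ratio strictly > 1, ties
reported separately, (b) the median log-ratio, and (c) a two-sided Wilcoxon
signed-rank test of the log-ratios against zero. Log base 10 is a display
choice only: sign-, fraction- and median-based conclusions are base-invariant.

**Computability filter.** A gene enters a comparison iff its mean is strictly
positive in both groups *and* its sample SD is non-zero in both; otherwise the
ratio or its logarithm is undefined. Excluded genes are always counted and
reported (`n_excluded`). There is no fixed gene universe: the filter is the
operative definition of "analyzable gene" for whatever matrix is supplied.
No multiple-testing correction is applied across genes: the reported p-value
belongs to the single cohort-level median test, not to per-gene inference.

## Signed-rank test

Exact zeros are dropped; tied absolute values receive average ranks; the
statistic is the sum of ranks of positive values. For n ≤ 25 the two-sided
p-value is exact: average ranks are multiples of ½, so doubled ranks are
integers and the full 2^n sign-pattern null distribution is obtained by
dynamic programming (convolution of {0, d_i} increments) — identical to
literal enumeration, in polynomial time. Two-sided extremity is distance from
the null mean n(n+1)/4; the distribution is symmetric about it even under
ties because flipping every sign maps W to T − W. Above n = 25 a normal
approximation with tie correction (−Σ(t³−t)/48 on the variance) and a 0.5
continuity correction is used; the boundary is configurable
(`exact_threshold`). Exhaustive comparison at n = 15 shows a worst-case
|exact − approx| of 0.0111, reached near p ≈ 0.5; the approximation is
reserved for sample sizes (hundreds to thousands of genes) where the residual
error is far smaller.

## Permutation null

The reference ("random") distribution a log-ratio histogram is contrasted
with is a group-label permutation: when the two groups pair one-to-one within
patients (tumor/normal), each patient's two labels are swapped independently
with probability ½, preserving the paired design; otherwise pooled labels are
shuffled preserving group sizes. The noise table is recomputed per
permutation. Outputs are explicitly labelled as permutation nulls
(`null_histogram_permutation.tsv`) because this is the package's construction,
not an analytically prescribed one.

## Stratification

* **Activity scores.** Per sample, the geometric mean of a marker pair:
  CDKN1A (p21) and MDM2 for p53 pathway output; GZMA and PRF1 for local
  cytolytic immune activity. Marker identifiers are configurable because ID
  namespaces vary across matrices.
* **Quartiles.** Samples are sorted ascending by (score, sample_id) — the
  secondary key makes ties deterministic and auditable — and the bottom and
  top k = floor(n/4) samples are contrasted (minimum n = 8 so each group can
  support a noise estimate). Which tissue's samples feed the score and which
  feed the noise comparison are explicit parameters (tumor/tumor for the
  cancer analyses; normal/normal for the normal-tissue analysis).
* **Purity.** Patients qualify when their tumor sample's recorded purity is
  strictly greater than the threshold ("larger than" is read as strict);
  patients without a recorded purity are excluded, not imputed.
* **Stage.** Early = stage I, late = stage III or IV; stage II and unstaged
  patients are in neither group. Stage is a patient-level label; conflicting
  per-sample stage tokens are an error.

## Gene sets

Per cohort, the increased set at threshold t is {g : ratio > t} and the
decreased set is {g : ratio < t} (strict, matching ">" / "decreased above
10%" ⇒ t = 0.9 wording). Cross-cohort sets are plain intersections applied
*after* per-cohort thresholding; a gene filtered out of any cohort's table
cannot qualify (it is treated as not satisfying the criterion, not as missing
data). Intersections are order-invariant and nest monotonically in the
threshold.

## Synthetic cohort generator

The generator emulates a paired TCGA-like cohort with known truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_patients` | 2000, 50 | matrix size; one tumor + one normal sample per patient |
| `base_log_mean_range` | (0, 6) natural-log | per-gene log-mean, uniform — spans ~1–400 abundance units |
| `sigma_normal` | 0.5 | lognormal shape per gene in normal tissue |
| `inflation_factor` | 1.5 | multiplier on sigma in tumor for affected genes |
| `fraction_affected` | 0.9 | fraction of genes inflated (uniform random subset, recorded in the truth) |
| `marker_effects` | loading 1.0 each | per-patient multiplicative effect exp(loading·a) on the four marker genes; a ~ N(0,1) latent p53/immune activity |
| `couple_inflation_to` | None | restrict inflation to patients with below-median latent p53/immune activity |
| `purity_model` | none | "beta": purity ~ Beta(α, β); observed tumor = purity·tumor + (1−purity)·contaminant |
| `sigma_contaminant` | 2.5 × sigma_normal | contaminant lognormal shape |
| `contaminant_logfc_sd` | 1.0 | per-gene log-fold offset of the contaminant profile |
| `stage_probs` | (.30,.35,.25,.10) | multinomial stage I–IV mix, skewed toward early diagnosis |

Expression is lognormal rather than count-based because the statistic is a CV
on normalized abundances and the lognormal has a closed-form CV,
sqrt(exp(σ²)−1), which the tests use as an independent oracle (σ = 0.5 gives
CV ≈ 0.5329; inflation 1.5 gives 0.878 — a clearly separable truth at n = 50).

**Why the contaminant is more heterogeneous than the tumor.** Mixing a tumor
draw with an independent contaminant of the *same* dispersion provably lowers
the across-patient CV (the variance of a convex combination of i.i.d.
variables is smaller), which would invert the expected purity effect. Lower
purity increases bulk noise only when the admixed compartment varies more
across patients than the tumor compartment does — which is what infiltrate
composition does in real tumors. The generator therefore gives the
contaminant per-gene log-fold offsets (sd 1.0) and a larger shape
(2.5 × sigma_normal); under this model the median tumor-group noise rises
monotonically as mean purity falls through 0.95 → 0.80 → 0.60 (Beta
concentration fixed at 20), matching the direction expected of bulk cohorts.

Randomness: one `numpy` Generator seeded once per call; draws are consumed in
a fixed documented order (gene log-means, affected subset, p53 activities,
immune activities, purity uniforms, stages, contaminant offsets, normal /
tumor / contaminant deviates). Purity is drawn by inverse-CDF on a fixed
block of uniforms so cohorts at different purity settings share all other
draws. Equal configs give bit-identical cohorts.

**What the generator does not emulate:** library-size and GC artifacts, batch
effects, count noise at low abundance, gene–gene correlation, and any real
coupling between stage and noise (stages are independent labels, so the stage
comparison on default synthetic cohorts is a negative control). Passing tests
therefore demonstrate correctness and calibration of the *pipeline*, not
biological claims about real cohorts.

## Study conditions used by the tests and the acceptance script

Simulation sizes were chosen once as desk-scale analogues of the cohorts the
method targets: null calibration at 200 replicates of 500 genes × 30
patients; inflation recovery at 1000 genes × 50 patients; quartile recovery
at 500 genes × 200 patients (quartile k = 50); purity sweep at 500 genes × 50
patients; cross-cohort gene sets over five independent 800-gene cohorts. The
affected-fraction estimator rescales the observed increased fraction by
P(ratio > 1 | inflated) obtained from a direct 20 000-gene lognormal
simulation that bypasses the cohort machinery.

## Numerical and edge-case choices

* Ratio ties (exactly 1) count as *not increased*; the tie fraction is
  reported separately.
* `gene_noise` requires ≥ 2 observations and a positive mean; all-zero genes
  are excluded upstream and counted.
* Table output renders floats at 8 significant digits (round-trips within
  1e-6 relative); summaries are JSON with sorted keys, so reruns are
  byte-identical.
* Histogram bins are half-open [k·w, (k+1)·w), anchored at zero, covering the
  data range; frequencies sum to 1.
* Pipeline stage seeds derive from the config seed as
  `seed + 7919 · stage_index (mod 2^31)`, so toggling analyses never changes
  another stage's permutations.
* On any stage failure the stage's partial output directory is removed and
  the error is re-raised with the stage name.

## Known limitations

* The CV is estimated without small-sample bias correction; with groups of
  equal size the tumor-vs-normal comparison is symmetric and calibrated (the
  null fraction averages 0.50), but comparisons between groups of very
  different sizes inherit the estimator's size-dependent skew.
* The permutation null is one defensible choice of reference distribution;
  analyses that used a different "random" reference are not reproduced
  exactly.
* Quartile stratification operates on exactly the sample set supplied;
  whether exclusions happen before or after quartiling is the caller's
  decision.
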