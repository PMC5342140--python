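"""Reusable simulation experiments over the full pipeline.

These are the study designs the analysis drivers, the test suite and the
acceptance script all execute: null calibration of the tumor-vs-normal
comparison, recovery of a known noise inflation, estimation of the affected
gene fraction, quartile-stratification recovery, and the purity-noise
direction.  Every function takes an explicit seed and is deterministic.
"""

from __future__ import annotations

import numpy as np

from .noise import noise_table, summarize_comparison
from .simulate import SimulationConfig, simulate_cohort, with_mean_purity
from .stratify import activity_score, quartile_split

__all__ = [
    "paired_groups",
    "tumor_vs_normal_summary",
    "null_calibration",
    "inflation_recovery",
    "oracle_prob_increased",
    "estimate_affected_fraction",
    "quartile_recovery",
    "median_tumor_noise",
]


def paired_groups(cohort):
    """(normal samples, tumor samples) for the paired patients of a cohort."""
    pairs = cohort.sheet.paired_patients()
    return [n for _, _, n in pairs], [t for _, t, _ in pairs]


def tumor_vs_normal_summary(config: SimulationConfig):
    """Simulate one cohort and summarize its paired tumor-vs-normal comparison."""
    cohort, truth = simulate_cohort(config)
    normals, tumors = paired_groups(cohort)
    nt = noise_table(cohort, normals, tumors, label_a="normal", label_b="tumor")
    return summarize_comparison(nt), truth


def null_calibration(
    n_reps: int = 200, n_genes: int = 500, n_patients: int = 30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated null cohorts (no inflation): per-replicate fraction of genes
    with increased tumor noise and the signed-rank p-value.

    Under the null the tumor-vs-normal noise comparison of each gene is a fair
    coin, so the fractions average 0.5 and the p-values are uniform.
    """
    fractions = np.empty(n_reps)
    pvalues = np.empty(n_reps)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    for i in range(n_reps):
        config = SimulationConfig(
            n_genes=n_genes,
            n_patients=n_patients,
            inflation_factor=1.0,
            fraction_affected=0.0,
            seed=int(seeds[i]),
        )
        summary, _ = tumor_vs_normal_summary(config)
        fractions[i] = summary.fraction_increased
        pvalues[i] = summary.p_value
    return fractions, pvalues


def inflation_recovery(
    inflation_factor: float = 1.5,
    fraction_affected: float = 1.0,
    n_genes: int = 1000,
    n_patients: int = 50,
    seed: int = 0,
):
    """One inflated cohort's tumor-vs-normal ComparisonSummary."""
    config = SimulationConfig(
        n_genes=n_genes,
        n_patients=n_patients,
        inflation_factor=inflation_factor,
        fraction_affected=fraction_affected,
        seed=seed,
    )
    summary, _ = tumor_vs_normal_summary(config)
    return summary


def oracle_prob_increased(
    inflation_factor: float,
    sigma_normal: float = 0.5,
    n_per_group: int = 50,
    n_genes: int = 20000,
    seed: int = 0,
) -> float:
    """Brute-force P(noise ratio > 1 | inflated gene): direct lognormal
    simulation of independent genes, bypassing the cohort machinery."""
    rng = np.random.default_rng(seed)
    a = rng.lognormal(0.0, sigma_normal, size=(n_genes, n_per_group))
    b = rng.lognormal(0.0, sigma_normal * inflation_factor, size=(n_genes, n_per_group))
    cv_a = a.std(axis=1, ddof=1) / a.mean(axis=1)
    cv_b = b.std(axis=1, ddof=1) / b.mean(axis=1)
    return float((cv_b > cv_a).mean())


def estimate_affected_fraction(
    fraction_affected: float = 0.75,
    inflation_factor: float = 1.5,
    n_genes: int = 1000,
    n_patients: int = 50,
    seed: int = 0,
    prob_increased_if_affected: float | None = None,
) -> float:
    """Estimate the affected-gene fraction from the observed fraction of
    increased-noise genes.

    The observed fraction mixes affected genes (increased with probability p1)
    and unaffected genes (fair coin), so fraction_affected is recovered as
    (observed - 0.5) / (p1 - 0.5) with p1 from the brute-force oracle.
    """
    summary = inflation_recovery(
        inflation_factor, fraction_affected, n_genes, n_patients, seed
    )
    p1 = (
        prob_increased_if_affected
        if prob_increased_if_affected is not None
        else oracle_prob_increased(inflation_factor, n_per_group=n_patients, seed=seed + 1)
    )
    return (summary.fraction_increased - 0.5) / (p1 - 0.5)


def quartile_recovery(
    couple_to: str = "p53",
    n_genes: int = 500,
    n_patients: int = 200,
    inflation_factor: float = 1.5,
    seed: int = 0,
):
    """Low-vs-high activity quartile ComparisonSummary on a cohort where tumor
    noise inflation is coupled to low latent activity.

    Group A is the top (high-activity) quartile and group B the bottom, so a
    fraction_increased above 0.5 reproduces the reported direction: more noise
    in low-activity patients.
    """
    markers = ("CDKN1A", "MDM2") if couple_to == "p53" else ("GZMA", "PRF1")
    config = SimulationConfig(
        n_genes=n_genes,
        n_patients=n_patients,
        inflation_factor=inflation_factor,
        couple_inflation_to=couple_to,
        seed=seed,
    )
    cohort, _ = simulate_cohort(config)
    tumors = cohort.sheet.samples_with_tissue("tumor")
    split = quartile_split(activity_score(cohort.matrix, markers, tumors))
    nt = noise_table(
        cohort,
        list(split.top_ids),
        list(split.bottom_ids),
        label_a=f"{couple_to}_high",
        label_b=f"{couple_to}_low",
    )
    return summarize_comparison(nt)


def median_tumor_noise(mean_purity: float, seed: int = 0, **config_kwargs) -> float:
    """Median per-gene tumor-group noise at a given mean simulated purity."""
    base = SimulationConfig(
        n_genes=config_kwargs.pop("n_genes", 500),
        n_patients=config_kwargs.pop("n_patients", 50),
        inflation_factor=config_kwargs.pop("inflation_factor", 1.0),
        fraction_affected=config_kwargs.pop("fraction_affected", 0.0),
        seed=seed,
        **config_kwargs,
    )
    cohort, _ = simulate_cohort(with_mean_purity(base, mean_purity))
    tumors = cohort.sheet.samples_with_tissue("tumor")
    vals = cohort.matrix.values_for(tumors)
    return float(np.median(vals.std(axis=1, ddof=1) / vals.mean(axis=1)))
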