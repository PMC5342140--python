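"""Synthetic paired tumor-normal cohort generator with known noise structure.

Each gene's expression is lognormal: a gene-specific log-mean drawn uniformly
from ``base_log_mean_range`` and a lognormal shape ``sigma_normal`` shared by
all genes in normal tissue.  In tumor samples, a chosen fraction of genes has
its shape multiplied by ``inflation_factor`` — the ground-truth "noisier in
tumor" signal.  A lognormal with shape sigma has a closed-form coefficient of
variation sqrt(exp(sigma^2) - 1), which the test suite uses as an oracle.

Four marker genes (CDKN1A and MDM2 for p53 pathway output, GZMA and PRF1 for
cytolytic immune activity) are additionally scaled per patient by
exp(loading * latent_activity) with standard-normal latent activities, so
marker-based activity scores recover the latent patient ordering.  Setting
``couple_inflation_to`` to "p53" or "immune" restricts tumor noise inflation
to patients whose latent activity is below the cohort median, creating the
ground truth for quartile-stratification recovery.

Tumor purity: with ``purity_model="beta"``, each patient's purity is a
Beta(alpha, beta) draw and the observed tumor value is a purity-weighted
mixture of the tumor draw and a contaminant draw.  The contaminant compartment
(stromal/immune infiltrate of varying composition) is modelled as more
heterogeneous across patients than the tumor compartment: per-gene log-fold
offsets (sd ``contaminant_logfc_sd``) and a larger shape
``sigma_contaminant`` (default 2.5 x sigma_normal).  Under this model lower
purity increases across-patient noise, the direction bulk-cohort studies
report; a same-dispersion independent contaminant would instead *reduce*
noise by averaging.

All randomness comes from one generator seeded once per call; sub-draws are
consumed in a fixed documented order (gene log-means, affected subset, p53
activities, immune activities, purities, stages, contaminant offsets, normal
deviates, tumor deviates, contaminant deviates), so equal configs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .io import Cohort, ExpressionMatrix, SampleSheet, ValidationError, VALID_STAGES

__all__ = [
    "P53_MARKERS",
    "IMMUNE_MARKERS",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "mix_purity",
    "assign_stages",
]

P53_MARKERS = ("CDKN1A", "MDM2")
IMMUNE_MARKERS = ("GZMA", "PRF1")
_MARKERS = P53_MARKERS + IMMUNE_MARKERS


def _default_marker_effects() -> dict[str, float]:
    return {m: 1.0 for m in _MARKERS}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults describe a desk-scale paired cohort: 2000 genes, 50 patients,
    lognormal shape 0.5 in normal tissue, tumor shape inflated 1.5-fold for
    90% of genes, no purity mixing, unit marker loadings, and a stage mix
    skewed toward early diagnosis.
    """

    n_genes: int = 2000
    n_patients: int = 50
    base_log_mean_range: tuple[float, float] = (0.0, 6.0)
    sigma_normal: float = 0.5
    inflation_factor: float = 1.5
    fraction_affected: float = 0.9
    purity_model: str = "none"  # "none" | "beta"
    purity_alpha: float = 16.0
    purity_beta: float = 4.0
    sigma_contaminant: float | None = None  # default: 2.5 * sigma_normal
    contaminant_logfc_sd: float = 1.0
    marker_effects: Mapping[str, float] = field(default_factory=_default_marker_effects)
    couple_inflation_to: str | None = None  # None | "p53" | "immune"
    stage_probs: tuple[float, float, float, float] = (0.30, 0.35, 0.25, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be a positive integer")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be a positive integer")
        lo, hi = self.base_log_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValidationError("base_log_mean_range must be a finite interval (lo, hi)")
        if not self.sigma_normal > 0:
            raise ValidationError("sigma_normal must be > 0")
        if not self.inflation_factor >= 1:
            raise ValidationError("inflation_factor must be >= 1")
        if not 0 <= self.fraction_affected <= 1:
            raise ValidationError("fraction_affected must be in [0, 1]")
        if self.purity_model not in ("none", "beta"):
            raise ValidationError("purity_model must be 'none' or 'beta'")
        if self.purity_model == "beta" and (self.purity_alpha <= 0 or self.purity_beta <= 0):
            raise ValidationError("purity_alpha and purity_beta must be > 0")
        if self.sigma_contaminant is not None and not self.sigma_contaminant > 0:
            raise ValidationError("sigma_contaminant must be > 0")
        if not self.contaminant_logfc_sd >= 0:
            raise ValidationError("contaminant_logfc_sd must be >= 0")
        unknown = sorted(set(self.marker_effects) - set(_MARKERS))
        if unknown:
            raise ValidationError(f"marker_effects has unknown marker(s): {unknown}")
        if self.marker_effects and self.n_genes < len(_MARKERS):
            raise ValidationError("n_genes must be >= 4 when marker effects are requested")
        if self.couple_inflation_to not in (None, "p53", "immune"):
            raise ValidationError("couple_inflation_to must be None, 'p53' or 'immune'")
        probs = np.asarray(self.stage_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("stage_probs must be 4 non-negative values summing to 1")

    @property
    def effective_sigma_contaminant(self) -> float:
        return (
            self.sigma_contaminant
            if self.sigma_contaminant is not None
            else 2.5 * self.sigma_normal
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: the recovery target for tests."""

    affected_genes: frozenset[str]
    patient_activity_p53: pd.Series  # indexed by patient_id
    patient_activity_immune: pd.Series
    patient_purity: pd.Series


def mix_purity(tumor_value, contaminant_value, purity):
    """Purity-weighted bulk mixture: purity * tumor + (1 - purity) * contaminant.

    Accepts scalars or broadcastable arrays; purity must lie in [0, 1].
    """
    p = np.asarray(purity, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("purity must be in [0, 1]")
    t = np.asarray(tumor_value, dtype=float)
    c = np.asarray(contaminant_value, dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValidationError("expression values must be >= 0")
    out = p * t + (1.0 - p) * c
    return float(out) if out.ndim == 0 else out


def assign_stages(
    n_patients: int, stage_probs: Sequence[float], seed: int
) -> list[str]:
    """Multinomial stage draw over I-IV; deterministic given seed."""
    probs = np.asarray(stage_probs, dtype=float)
    if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("stage_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    return list(rng.choice(VALID_STAGES, size=n_patients, p=probs))


def _gene_ids(n_genes: int, with_markers: bool) -> list[str]:
    width = max(4, len(str(n_genes)))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    if with_markers:
        ids[: len(_MARKERS)] = _MARKERS
    return ids


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one paired tumor-normal cohort plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, P = config.n_genes, config.n_patients

    # fixed draw order — see module docstring
    log_means = rng.uniform(*config.base_log_mean_range, size=G)
    n_affected = int(round(config.fraction_affected * G))
    affected_idx = rng.choice(G, size=n_affected, replace=False)
    act_p53 = rng.standard_normal(P)
    act_imm = rng.standard_normal(P)
    # purity via inverse-CDF of a fixed block of uniforms, so the stream stays
    # aligned across purity settings and the remaining draws are shared
    purity_u = rng.random(P)
    if config.purity_model == "beta":
        purity = beta_dist.ppf(purity_u, config.purity_alpha, config.purity_beta)
    else:
        purity = np.ones(P)
    stage_idx = rng.choice(4, size=P, p=np.asarray(config.stage_probs, dtype=float))
    delta = rng.normal(0.0, config.contaminant_logfc_sd, size=G)
    z_normal = rng.standard_normal((G, P))
    z_tumor = rng.standard_normal((G, P))
    z_contam = rng.standard_normal((G, P))

    # tumor shape: sigma_normal everywhere, inflated on affected genes —
    # for every patient, or only for below-median-activity patients if coupled
    sigma_t = np.full((G, P), config.sigma_normal)
    affected_mask = np.zeros(G, dtype=bool)
    affected_mask[affected_idx] = True
    if config.couple_inflation_to is None:
        patient_inflated = np.ones(P, dtype=bool)
    else:
        activity = act_p53 if config.couple_inflation_to == "p53" else act_imm
        patient_inflated = activity < np.median(activity)
    sigma_t[np.ix_(affected_mask, patient_inflated)] *= config.inflation_factor

    normal = np.exp(log_means[:, None] + config.sigma_normal * z_normal)
    tumor = np.exp(log_means[:, None] + sigma_t * z_tumor)
    contaminant = np.exp(
        (log_means + delta)[:, None] + config.effective_sigma_contaminant * z_contam
    )

    gene_ids = _gene_ids(G, with_markers=bool(config.marker_effects))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for marker, loading in config.marker_effects.items():
        act = act_p53 if marker in P53_MARKERS else act_imm
        factor = np.exp(loading * act)
        row = gene_pos[marker]
        normal[row] *= factor
        tumor[row] *= factor
        contaminant[row] *= factor

    if config.purity_model == "beta":
        tumor = mix_purity(tumor, contaminant, purity[None, :])

    patients = [f"P{i + 1:04d}" for i in range(P)]
    tumor_ids = [f"{p}-T" for p in patients]
    normal_ids = [f"{p}-N" for p in patients]
    values = np.hstack([tumor, normal])
    matrix = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(gene_ids, name="gene_id"),
            columns=tumor_ids + normal_ids,
        )
    )
    stages = [VALID_STAGES[i] for i in stage_idx]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": tumor_ids + normal_ids,
                "patient_id": patients + patients,
                "tissue": ["tumor"] * P + ["normal"] * P,
                "purity": (
                    list(purity) + [np.nan] * P
                    if config.purity_model == "beta"
                    else [np.nan] * (2 * P)
                ),
                "stage": stages + stages,
            }
        )
    )
    truth = GroundTruth(
        affected_genes=frozenset(gene_ids[i] for i in affected_idx),
        patient_activity_p53=pd.Series(act_p53, index=patients, name="activity_p53"),
        patient_activity_immune=pd.Series(act_imm, index=patients, name="activity_immune"),
        patient_purity=pd.Series(purity, index=patients, name="purity"),
    )
    return Cohort(matrix=matrix, sheet=sheet), truth


def with_mean_purity(
    config: SimulationConfig, mean_purity: float, concentration: float = 20.0
) -> SimulationConfig:
    """Derived config with a Beta purity model of the given mean and fixed
    concentration (alpha + beta)."""
    if not 0 < mean_purity < 1:
        raise ValidationError("mean_purity must be in (0, 1)")
    return replace(
        config,
        purity_model="beta",
        purity_alpha=mean_purity * concentration,
        purity_beta=(1.0 - mean_purity) * concentration,
    )
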