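"""Per-gene expression noise and group comparisons.

Population-level expression noise of a gene is its coefficient of variation
across a patient group: sample standard deviation (n-1 denominator, the
spreadsheet STDEV convention) divided by the arithmetic mean.  Two groups are
compared gene-by-gene through the noise ratio ``noise_b / noise_a`` and its
base-10 logarithm; the comparison summary reports the fraction of genes with
strictly increased noise and a two-sided Wilcoxon signed-rank test of whether
the median log-ratio is zero.

A permutation null is provided because the reference distribution such
comparisons are plotted against is otherwise unspecified: group labels are
re-assigned at random (within patient pairs when the two groups form a paired
tumor/normal design) and the log-ratio vector recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort

__all__ = [
    "NoiseTable",
    "ComparisonSummary",
    "gene_noise",
    "noise_table",
    "summarize_comparison",
    "signed_rank_test",
    "permutation_null",
    "log_ratio_histogram",
]

#: sample-size boundary between the exact signed-rank p-value and the
#: tie-corrected normal approximation with continuity correction
EXACT_THRESHOLD_DEFAULT = 25


@dataclass(frozen=True)
class NoiseTable:
    """Per-gene noise in two groups plus ratio and log10 ratio.

    Genes failing the computability filter (mean not > 0 in both groups, or
    zero standard deviation in either group, which leaves the log-ratio
    undefined) are absent from ``table`` and counted in ``n_excluded``.
    """

    table: pd.DataFrame  # columns: gene_id, noise_a, noise_b, ratio, log_ratio
    n_excluded: int
    group_a: str = "A"
    group_b: str = "B"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()

    @property
    def log_ratios(self) -> np.ndarray:
        return self.table["log_ratio"].to_numpy()


@dataclass(frozen=True)
class ComparisonSummary:
    """Cohort-level summary of a two-group noise comparison."""

    group_a: str
    group_b: str
    n_genes: int
    fraction_increased: float
    tie_fraction: float
    median_log_ratio: float
    wilcoxon_statistic: float
    p_value: float
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_genes": self.n_genes,
            "fraction_increased": self.fraction_increased,
            "tie_fraction": self.tie_fraction,
            "median_log_ratio": self.median_log_ratio,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "p_value": self.p_value,
            "n_excluded": self.n_excluded,
        }


def gene_noise(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation: sample SD (ddof=1) over arithmetic mean.

    Requires at least two observations and a strictly positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("gene_noise expects a 1-D sequence")
    if x.size < 2:
        raise ValueError("insufficient samples: need at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError("noise undefined for zero-mean gene")
    return float(x.std(ddof=1) / m)


def _check_groups(cohort: Cohort, group_a: Iterable[str], group_b: Iterable[str]):
    a = list(group_a)
    b = list(group_b)
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group must contain at least 2 samples")
    known = set(cohort.matrix.sample_ids)
    unknown = sorted((set(a) | set(b)) - known)
    if unknown:
        raise ValueError(f"sample ID(s) not in cohort: {', '.join(unknown)}")
    return a, b


def noise_table(
    cohort: Cohort,
    group_a: Iterable[str],
    group_b: Iterable[str],
    *,
    label_a: str = "A",
    label_b: str = "B",
) -> NoiseTable:
    """Per-gene noise in two disjoint sample groups.

    A gene enters the table iff its mean is strictly positive in both groups
    and its noise is non-zero in both (so the ratio and log-ratio exist);
    excluded genes are counted in ``n_excluded``.
    """
    a, b = _check_groups(cohort, group_a, group_b)
    va = cohort.matrix.values_for(a)
    vb = cohort.matrix.values_for(b)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    sd_a = va.std(axis=1, ddof=1)
    sd_b = vb.std(axis=1, ddof=1)
    keep = (mean_a > 0) & (mean_b > 0) & (sd_a > 0) & (sd_b > 0)
    genes = np.asarray(cohort.matrix.gene_ids, dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        noise_a = sd_a[keep] / mean_a[keep]
        noise_b = sd_b[keep] / mean_b[keep]
    ratio = noise_b / noise_a
    df = pd.DataFrame(
        {
            "gene_id": genes[keep],
            "noise_a": noise_a,
            "noise_b": noise_b,
            "ratio": ratio,
            "log_ratio": np.log10(ratio),
        }
    ).reset_index(drop=True)
    return NoiseTable(
        table=df,
        n_excluded=int((~keep).sum()),
        group_a=label_a,
        group_b=label_b,
    )


def summarize_comparison(
    table: NoiseTable, *, exact_threshold: int = EXACT_THRESHOLD_DEFAULT
) -> ComparisonSummary:
    """Fraction of genes with strictly increased noise, median log-ratio and a
    two-sided signed-rank test of the log-ratios against zero (zeros dropped)."""
    if len(table) == 0:
        raise ValueError("empty noise table")
    ratios = table.ratios
    n = len(ratios)
    frac = float((ratios > 1).sum()) / n
    ties = float((ratios == 1).sum()) / n
    stat, p = signed_rank_test(table.log_ratios, exact_threshold=exact_threshold)
    return ComparisonSummary(
        group_a=table.group_a,
        group_b=table.group_b,
        n_genes=n,
        fraction_increased=frac,
        tie_fraction=ties,
        median_log_ratio=float(np.median(table.log_ratios)),
        wilcoxon_statistic=stat,
        p_value=p,
        n_excluded=table.n_excluded,
    )


def _exact_signed_rank_p(ranks: np.ndarray, statistic: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, via dynamic programming.

    Average ranks for ties are multiples of 1/2, so doubled ranks are integers
    and the null distribution of the doubled statistic is the convolution of
    independent {0, d_i} increments — identical to literal enumeration of the
    2^n sign patterns, but polynomial time.  Two-sidedness is distance from
    the null mean n(n+1)/4 (the distribution is symmetric about it even under
    ties, since flipping every sign maps W to T - W).
    """
    d = np.rint(2 * ranks).astype(np.int64)
    total = int(d.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for di in d:
        di = int(di)
        counts[di : top + di + 1] += counts[: top + 1]
        top += di
    s_obs = int(np.rint(2 * statistic))
    dev = abs(2 * s_obs - total)
    s = np.arange(total + 1)
    extreme = np.abs(2 * s - total) >= dev
    return float(counts[extreme].sum() / 2.0 ** len(d))


def signed_rank_test(
    values: Sequence[float] | np.ndarray, *, exact_threshold: int = EXACT_THRESHOLD_DEFAULT
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of median zero.

    Exact zeros are dropped before ranking; tied magnitudes receive average
    ranks.  The statistic is the sum of ranks of the positive values.  The
    p-value is exact (full sign-pattern null) for n <= ``exact_threshold``,
    otherwise a tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    n = x.size
    if n == 0:
        raise ValueError("all values zero after zero-removal")
    ranks = stats.rankdata(np.abs(x))
    w = float(ranks[x > 0].sum())
    if n <= exact_threshold:
        return w, _exact_signed_rank_p(ranks, w)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate variance in signed-rank approximation")
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return w, p


def _paired_structure(
    cohort: Cohort, a: list[str], b: list[str]
) -> list[tuple[str, str]] | None:
    """If groups A and B form one-sample-per-patient pairs, return the
    (a_sample, b_sample) pairs; otherwise None."""
    sheet = cohort.sheet.data
    pat = dict(zip(sheet["sample_id"], sheet["patient_id"]))
    by_patient: dict[str, dict[str, list[str]]] = {}
    for s in a:
        by_patient.setdefault(pat[s], {}).setdefault("a", []).append(s)
    for s in b:
        by_patient.setdefault(pat[s], {}).setdefault("b", []).append(s)
    pairs = []
    for _, groups in sorted(by_patient.items()):
        if len(groups.get("a", [])) != 1 or len(groups.get("b", [])) != 1:
            return None
        pairs.append((groups["a"][0], groups["b"][0]))
    return pairs


def permutation_null(
    cohort: Cohort,
    group_a: Iterable[str],
    group_b: Iterable[str],
    n_perm: int,
    seed: int,
) -> list[pd.Series]:
    """Permutation null log-ratio vectors.

    When the two groups pair up one-to-one within patients (a paired
    tumor/normal design), each patient's two labels are swapped independently
    with probability 1/2; otherwise the pooled labels are shuffled preserving
    group sizes.  Returns one gene-indexed log-ratio Series per permutation.
    """
    a, b = _check_groups(cohort, group_a, group_b)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = _paired_structure(cohort, a, b)
    out: list[pd.Series] = []
    for _ in range(n_perm):
        if pairs is not None:
            swap = rng.random(len(pairs)) < 0.5
            pa = [y if sw else x for (x, y), sw in zip(pairs, swap)]
            pb = [x if sw else y for (x, y), sw in zip(pairs, swap)]
        else:
            pooled = np.asarray(a + b, dtype=object)
            perm = rng.permutation(pooled)
            pa, pb = list(perm[: len(a)]), list(perm[len(a) :])
        nt = noise_table(cohort, pa, pb)
        out.append(pd.Series(nt.log_ratios, index=nt.table["gene_id"].to_numpy()))
    return out


def log_ratio_histogram(
    log_ratios: Sequence[float] | np.ndarray, bin_width: float
) -> pd.DataFrame:
    """Relative-frequency histogram over half-open bins [k*w, (k+1)*w).

    The bin grid is anchored at zero and covers the data range; frequencies
    sum to one.  Returns columns bin_left, bin_right, frequency.
    """
    x = np.asarray(log_ratios, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    k = np.floor(x / bin_width).astype(np.int64)
    kmin, kmax = int(k.min()), int(k.max())
    counts = np.bincount(k - kmin, minlength=kmax - kmin + 1)
    ks = np.arange(kmin, kmax + 1)
    return pd.DataFrame(
        {
            "bin_left": ks * bin_width,
            "bin_right": (ks + 1) * bin_width,
            "frequency": counts / x.size,
        }
    )
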