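"""Cross-cohort gene sets at noise fold-change thresholds.

For each cohort's per-gene noise table, the increased set at threshold t is
{gene : noise ratio > t} and the decreased set at threshold t is
{gene : noise ratio < t} (strict inequalities).  The cross-cohort result is
the intersection: a gene filtered out of any cohort's table cannot qualify.
"Noise decreased above 10%" corresponds to a decreased-set threshold of 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .noise import NoiseTable

__all__ = ["GeneSetResult", "increased_set", "decreased_set", "membership_table"]


@dataclass(frozen=True)
class GeneSetResult:
    cohort_names: tuple[str, ...]
    per_cohort: dict[str, frozenset[str]]
    intersection: frozenset[str]
    threshold: float
    direction: str  # "increased" | "decreased"


def _ratios(table: NoiseTable | pd.DataFrame) -> pd.DataFrame:
    df = table.table if isinstance(table, NoiseTable) else table
    if "gene_id" not in df.columns or "ratio" not in df.columns:
        raise ValueError("noise table needs gene_id and ratio columns")
    return df


def _threshold_sets(
    tables: Mapping[str, NoiseTable | pd.DataFrame],
    threshold: float,
    direction: str,
) -> GeneSetResult:
    if not tables:
        raise ValueError("no cohort tables given")
    per_cohort: dict[str, frozenset[str]] = {}
    for name, table in tables.items():
        df = _ratios(table)
        if direction == "increased":
            sel = df["ratio"] > threshold
        else:
            sel = df["ratio"] < threshold
        per_cohort[name] = frozenset(df.loc[sel, "gene_id"])
    names = tuple(tables)
    inter = frozenset.intersection(*per_cohort.values())
    return GeneSetResult(
        cohort_names=names,
        per_cohort=per_cohort,
        intersection=inter,
        threshold=threshold,
        direction=direction,
    )


def increased_set(
    tables: Mapping[str, NoiseTable | pd.DataFrame], min_ratio: float
) -> GeneSetResult:
    """Genes with noise ratio strictly above ``min_ratio`` in every cohort."""
    if not min_ratio >= 1:
        raise ValueError("min_ratio must be >= 1")
    return _threshold_sets(tables, min_ratio, "increased")


def decreased_set(
    tables: Mapping[str, NoiseTable | pd.DataFrame], max_ratio: float
) -> GeneSetResult:
    """Genes with noise ratio strictly below ``max_ratio`` in every cohort."""
    if not max_ratio <= 1:
        raise ValueError("max_ratio must be <= 1")
    return _threshold_sets(tables, max_ratio, "decreased")


def membership_table(result: GeneSetResult) -> pd.DataFrame:
    """Intersection genes with one membership flag column per cohort
    (all 1 by construction; kept for auditability of per-cohort sets)."""
    genes = sorted(result.intersection)
    out = pd.DataFrame({"gene_id": genes})
    for name in result.cohort_names:
        out[name] = [int(g in result.per_cohort[name]) for g in genes]
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    """One gene symbol per line — the export format enrichment tools ingest."""
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
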