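"""Patient stratification: marker activity scores, quartile splits, purity and stage groups.

p53 pathway output is scored per sample as the geometric mean of CDKN1A (p21)
and MDM2 expression; local cytolytic immune activity as the geometric mean of
GZMA (Granzyme A) and PRF1 (Perforin-1).  Cohorts are contrasted between the
bottom and top score quartiles (k = floor(n/4) samples each, ties broken by
sample ID so splits are deterministic), between tumor-purity subgroups
(strictly greater than a threshold), and between early (stage I) and late
(stage III/IV) diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "ActivityScoreTable",
    "QuartileSplit",
    "activity_score",
    "quartile_split",
    "filter_by_purity",
    "stage_groups",
]


@dataclass(frozen=True)
class ActivityScoreTable:
    """Per-sample marker activity scores (geometric mean of a marker pair)."""

    table: pd.DataFrame  # columns: sample_id, score
    marker_pair: tuple[str, str]

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class QuartileSplit:
    """Bottom / top score quartiles, each of size k = floor(n/4)."""

    bottom_ids: tuple[str, ...]
    top_ids: tuple[str, ...]
    k: int


def activity_score(
    matrix: ExpressionMatrix,
    marker_pair: tuple[str, str],
    sample_ids: Iterable[str],
) -> ActivityScoreTable:
    """Geometric mean sqrt(x1 * x2) of the two marker genes per sample."""
    samples = list(sample_ids)
    for marker in marker_pair:
        if marker not in matrix.data.index:
            raise KeyError(f"marker gene {marker!r} absent from matrix")
    unknown = sorted(set(samples) - set(matrix.sample_ids))
    if unknown:
        raise KeyError(f"sample ID(s) not in matrix: {', '.join(unknown)}")
    x1 = matrix.data.loc[marker_pair[0], samples].to_numpy(dtype=float)
    x2 = matrix.data.loc[marker_pair[1], samples].to_numpy(dtype=float)
    return ActivityScoreTable(
        table=pd.DataFrame({"sample_id": samples, "score": np.sqrt(x1 * x2)}),
        marker_pair=(marker_pair[0], marker_pair[1]),
    )


def quartile_split(scores: ActivityScoreTable) -> QuartileSplit:
    """Bottom and top floor(n/4) samples by ascending (score, sample_id)."""
    n = len(scores)
    if n < 8:
        raise ValueError("cohort too small for quartile comparison (need n >= 8)")
    ordered = scores.table.sort_values(
        ["score", "sample_id"], kind="mergesort"
    )["sample_id"].tolist()
    k = n // 4
    return QuartileSplit(bottom_ids=tuple(ordered[:k]), top_ids=tuple(ordered[-k:]), k=k)


def filter_by_purity(sheet: SampleSheet, threshold: float) -> set[str]:
    """Patients whose tumor sample purity is strictly greater than the
    threshold; patients without a recorded purity are excluded."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    df = sheet.data
    if "purity" not in df.columns:
        return set()
    tum = df[(df["tissue"] == "tumor") & df["purity"].notna()]
    return set(tum.loc[tum["purity"] > threshold, "patient_id"])


def stage_groups(sheet: SampleSheet) -> tuple[set[str], set[str]]:
    """(early, late) patient-ID sets: early = stage I, late = stage III or IV.

    Stage II and unstaged patients belong to neither group.  Raises when both
    groups have fewer than 2 patients (no comparison is possible).
    """
    early: set[str] = set()
    late: set[str] = set()
    for pid in sheet.data["patient_id"].unique():
        stage = sheet.patient_stage(pid)
        if stage == "I":
            early.add(pid)
        elif stage in ("III", "IV"):
            late.add(pid)
    if len(early) < 2 and len(late) < 2:
        raise ValueError("insufficient staged patients for an early/late comparison")
    return early, late
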