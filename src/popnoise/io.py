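"""Reading, validation and writing of expression matrices, sample sheets and result tables.

The on-disk formats are deliberately plain: tab-separated text for matrices
and tables (genes as rows, samples as columns, matching the TCGA level-3
convention), JSON for comparison summaries.  Missing values are not permitted
in the expression matrix; absent metadata (purity, stage) is permitted in the
sample sheet and simply excludes a sample from analyses that need it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "ReconciliationError",
    "ExpressionMatrix",
    "SampleSheet",
    "Cohort",
    "read_expression_matrix",
    "read_sample_sheet",
    "bind_cohort",
    "write_table",
    "write_json",
    "read_json",
    "VALID_TISSUES",
    "VALID_STAGES",
]


class ParseError(ValueError):
    """A file could not be parsed (ragged row, non-numeric cell, ...)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (duplicate ID, negative value, ...)."""


class ReconciliationError(ValueError):
    """Matrix and sample sheet disagree about which samples exist."""


VALID_TISSUES = ("tumor", "normal")
VALID_STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample grid of non-negative, finite abundances.

    ``data`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns.  Row and column order is preserved from the source.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene ID(s): {', '.join(map(str, dup_genes))}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample ID(s): {', '.join(map(str, dup_samples))}")
        values = df.to_numpy()
        if values.size == 0:
            raise ValidationError("expression matrix is empty")
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        neg = values < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {values[g, s]} at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Genes x len(sample_ids) array in the given sample order."""
        return self.data.loc[:, list(sample_ids)].to_numpy(dtype=float)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: patient, tissue (tumor/normal), optional purity and stage."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["sample_id", "patient_id", "tissue"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {', '.join(missing)}")
        dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample ID(s): {', '.join(map(str, dup))}")
        bad_tissue = sorted(set(df["tissue"]) - set(VALID_TISSUES))
        if bad_tissue:
            raise ValidationError(
                f"unknown tissue value(s): {', '.join(map(str, bad_tissue))} "
                f"(expected one of {VALID_TISSUES})"
            )
        if "purity" in df.columns:
            p = df["purity"].dropna()
            out = p[(p < 0) | (p > 1)]
            if not out.empty:
                raise ValidationError(f"purity outside [0,1]: {out.iloc[0]}")
        if "stage" in df.columns:
            s = df["stage"].dropna()
            bad_stage = sorted(set(s) - set(VALID_STAGES))
            if bad_stage:
                raise ValidationError(
                    f"unknown stage token(s): {', '.join(map(str, bad_stage))} "
                    f"(expected one of {VALID_STAGES})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def samples_with_tissue(self, tissue: str) -> list[str]:
        tissue = tissue.lower()
        return list(self.data.loc[self.data["tissue"] == tissue, "sample_id"])

    def purity_of(self, sample_id: str) -> float | None:
        if "purity" not in self.data.columns:
            return None
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        v = row["purity"].iloc[0]
        return None if pd.isna(v) else float(v)

    def paired_patients(self) -> list[tuple[str, str, str]]:
        """(patient_id, tumor_sample, normal_sample) for patients with exactly
        one tumor and one normal sample; all other patients are omitted."""
        out = []
        for pid, grp in self.data.groupby("patient_id", sort=False):
            tum = grp.loc[grp["tissue"] == "tumor", "sample_id"].tolist()
            nrm = grp.loc[grp["tissue"] == "normal", "sample_id"].tolist()
            if len(tum) == 1 and len(nrm) == 1:
                out.append((pid, tum[0], nrm[0]))
        return out

    def patient_stage(self, patient_id: str) -> str | None:
        if "stage" not in self.data.columns:
            return None
        stages = (
            self.data.loc[self.data["patient_id"] == patient_id, "stage"].dropna().unique()
        )
        if len(stages) == 0:
            return None
        if len(stages) > 1:
            raise ValidationError(
                f"patient {patient_id!r} has conflicting stage labels: {sorted(stages)}"
            )
        return str(stages[0])


@dataclass(frozen=True)
class Cohort:
    """An expression matrix bound to its sample sheet; sample sets agree exactly."""

    matrix: ExpressionMatrix
    sheet: SampleSheet


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: header ``gene_id<TAB>sample1<TAB>...``,
    one gene per row, non-negative numeric cells.

    Raises :class:`ParseError` on ragged rows or non-numeric cells (with the
    offending position) and :class:`ValidationError` on duplicate IDs or
    negative values.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: header must name a gene-ID column and at least one sample")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: ragged row at line {lineno}: "
                    f"{len(row)} fields, expected {len(header)}"
                )
            gene_ids.append(row[0])
            rows.append(row[1:])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError:
        # locate the offending cell for the error message
        for i, r in enumerate(rows):
            for j, cell in enumerate(r):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at line {i + 2}, "
                        f"column {sample_ids[j]!r} (gene {gene_ids[i]!r})"
                    ) from None
        raise
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(df)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet with columns sample_id, patient_id, tissue and
    optional purity / stage.  Empty cells mean absent; tissue and stage tokens
    are case-insensitive."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "patient_id", "tissue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df["tissue"] = df["tissue"].str.strip().str.lower()
    if "purity" in df.columns:
        raw = df["purity"].str.strip()
        try:
            df["purity"] = pd.to_numeric(raw.replace("", None))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric purity value ({exc})") from None
    if "stage" in df.columns:
        df["stage"] = df["stage"].str.strip().str.upper().replace("", None)
    return SampleSheet(df)


def bind_cohort(matrix: ExpressionMatrix, sheet: SampleSheet) -> Cohort:
    """Pair a matrix with its sheet; the two sample-ID sets must agree exactly."""
    m = set(matrix.sample_ids)
    s = set(sheet.sample_ids)
    if not m and not s:
        raise ValidationError("empty cohort")
    only_m = sorted(m - s)
    only_s = sorted(s - m)
    if only_m or only_s:
        parts = []
        if only_m:
            parts.append(f"in matrix but not sheet: {', '.join(only_m)}")
        if only_s:
            parts.append(f"in sheet but not matrix: {', '.join(only_s)}")
        raise ReconciliationError("sample sets disagree — " + "; ".join(parts))
    return Cohort(matrix=matrix, sheet=sheet)


def write_table(table: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    """Write a result table as TSV with header; floats rendered with 8
    significant digits so a read-back reproduces values to ~1e-6 relative."""
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write empty table")
    table.to_csv(path, sep="\t", float_format="%.8g", index=index)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix in the TSV layout read_expression_matrix expects."""
    write_table(matrix.data, path, index=True)


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
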