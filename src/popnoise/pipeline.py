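"""End-to-end orchestration of the cohort noise analyses.

``run_all`` executes a requested list of analyses against one expression
matrix + sample sheet and writes, per analysis, the per-gene noise table
(TSV), the comparison summary (JSON), the log-ratio histogram (TSV) and —
when ``n_perm > 0`` — a pooled permutation-null histogram labelled as such.
A manifest records the configuration, seed, package version and input
checksums; identical config and inputs give identical outputs.

Per-analysis seeds are derived from the single config seed by a fixed
counter scheme (seed + 7919 * stage index, modulo 2^31) so toggling one
analysis never changes another's randomness.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    Cohort,
    bind_cohort,
    read_expression_matrix,
    read_sample_sheet,
    write_json,
    write_table,
)
from .noise import (
    NoiseTable,
    log_ratio_histogram,
    noise_table,
    permutation_null,
    summarize_comparison,
)
from .stratify import activity_score, filter_by_purity, quartile_split, stage_groups
from .gene_sets import decreased_set, increased_set, membership_table, write_gene_list

__all__ = ["ANALYSES", "AnalysisConfig", "validate_config", "run_all"]

ANALYSES = (
    "tumor_vs_normal",
    "purity",
    "p53_quartiles",
    "immune_quartiles",
    "stage",
    "gene_sets",
)

#: group-size below which a warning (not an error) is logged — noise estimates
#: from fewer than ~10 samples are unstable
SMALL_GROUP_WARN = 10


@dataclass
class AnalysisConfig:
    matrix_path: str
    sheet_path: str
    out_dir: str
    analyses: tuple[str, ...] = ANALYSES
    p53_markers: tuple[str, str] = ("CDKN1A", "MDM2")
    immune_markers: tuple[str, str] = ("GZMA", "PRF1")
    score_tissue: str = "tumor"  # which samples feed the activity score
    noise_tissue: str = "tumor"  # which samples feed quartile/stage noise
    purity_thresholds: tuple[float, ...] = (0.8, 0.9)
    increased_thresholds: tuple[float, ...] = (1.5, 2.0)
    decreased_threshold: float = 0.9
    n_perm: int = 0
    bin_width: float = 0.05
    seed: int = 0


def validate_config(config: AnalysisConfig) -> list[str]:
    """Return a list of problems; empty iff run_all would start."""
    problems: list[str] = []
    for name in config.analyses:
        if name not in ANALYSES:
            problems.append(
                f"analyses: unknown analysis {name!r} (allowed: {', '.join(ANALYSES)})"
            )
    if not Path(config.matrix_path).is_file():
        problems.append(f"matrix_path: no such file {config.matrix_path!r}")
    if not Path(config.sheet_path).is_file():
        problems.append(f"sheet_path: no such file {config.sheet_path!r}")
    else:
        header = pd.read_csv(config.sheet_path, sep="\t", nrows=0).columns
        if "stage" in config.analyses and "stage" not in header:
            problems.append("stage: sample sheet has no stage column")
        if "purity" in config.analyses and "purity" not in header:
            problems.append("purity: sample sheet has no purity column")
    if config.n_perm < 0:
        problems.append("n_perm: must be >= 0")
    if not config.bin_width > 0:
        problems.append("bin_width: must be > 0")
    if config.score_tissue not in ("tumor", "normal"):
        problems.append("score_tissue: must be 'tumor' or 'normal'")
    if config.noise_tissue not in ("tumor", "normal"):
        problems.append("noise_tissue: must be 'tumor' or 'normal'")
    for t in config.purity_thresholds:
        if not 0 <= t <= 1:
            problems.append(f"purity_thresholds: {t} outside [0, 1]")
    for t in config.increased_thresholds:
        if not t >= 1:
            problems.append(f"increased_thresholds: {t} below 1")
    if not config.decreased_threshold <= 1:
        problems.append("decreased_threshold: must be <= 1")
    return problems


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, analysis: str) -> int:
    return (seed + 7919 * (ANALYSES.index(analysis) + 1)) % 2**31


def _emit_comparison(
    cohort: Cohort,
    group_a: list[str],
    group_b: list[str],
    label_a: str,
    label_b: str,
    out: Path,
    *,
    n_perm: int,
    bin_width: float,
    seed: int,
    log,
) -> tuple[NoiseTable, dict]:
    nt = noise_table(cohort, group_a, group_b, label_a=label_a, label_b=label_b)
    summary = summarize_comparison(nt)
    out.mkdir(parents=True, exist_ok=True)
    write_table(nt.table, out / "noise_table.tsv")
    write_json(summary.to_dict(), out / "summary.json")
    write_table(log_ratio_histogram(nt.log_ratios, bin_width), out / "histogram.tsv")
    files = ["noise_table.tsv", "summary.json", "histogram.tsv"]
    if n_perm > 0:
        null = permutation_null(cohort, group_a, group_b, n_perm, seed)
        pooled = np.concatenate([s.to_numpy() for s in null])
        hist = log_ratio_histogram(pooled, bin_width)
        # labelled as a permutation null: the reference distribution here is a
        # patient-label permutation, not an analytic form
        write_table(hist, out / "null_histogram_permutation.tsv")
        files.append("null_histogram_permutation.tsv")
    for label, grp in ((label_a, group_a), (label_b, group_b)):
        if len(grp) < SMALL_GROUP_WARN:
            log(f"warning: group {label!r} has only {len(grp)} samples; noise unstable")
    log(
        f"groups {label_a}(n={len(group_a)}) vs {label_b}(n={len(group_b)}): "
        f"{summary.n_genes} genes, {summary.n_excluded} excluded, "
        f"fraction_increased={summary.fraction_increased:.4f}"
    )
    return nt, {"files": files, "summary": summary.to_dict()}


def _quartile_groups(
    cohort: Cohort, markers: tuple[str, str], score_tissue: str, noise_tissue: str
) -> tuple[list[str], list[str]]:
    """(top/high-activity samples, bottom/low-activity samples) for the noise
    comparison, mapped patient-wise when scoring and noise tissues differ."""
    score_samples = cohort.sheet.samples_with_tissue(score_tissue)
    split = quartile_split(activity_score(cohort.matrix, markers, score_samples))
    if score_tissue == noise_tissue:
        return list(split.top_ids), list(split.bottom_ids)
    df = cohort.sheet.data
    pat = dict(zip(df["sample_id"], df["patient_id"]))
    noise_of = {
        pat[s]: s for s in cohort.sheet.samples_with_tissue(noise_tissue)
    }
    top = [noise_of[pat[s]] for s in split.top_ids if pat[s] in noise_of]
    bottom = [noise_of[pat[s]] for s in split.bottom_ids if pat[s] in noise_of]
    return top, bottom


def run_all(config: AnalysisConfig, *, log=print) -> dict:
    """Run every requested analysis; returns (and writes) the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cohort = bind_cohort(
        read_expression_matrix(config.matrix_path), read_sample_sheet(config.sheet_path)
    )
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            "matrix": _sha256(config.matrix_path),
            "sheet": _sha256(config.sheet_path),
        },
        "analyses": {},
    }
    pairs = cohort.sheet.paired_patients()
    tumor_vs_normal_table: NoiseTable | None = None

    for name in config.analyses:
        out = out_root / name
        try:
            log(f"[{name}] starting")
            if name == "tumor_vs_normal":
                normals = [n for _, _, n in pairs]
                tumors = [t for _, t, _ in pairs]
                nt, rec = _emit_comparison(
                    cohort, normals, tumors, "normal", "tumor", out,
                    n_perm=config.n_perm, bin_width=config.bin_width,
                    seed=_stage_seed(config.seed, name), log=log,
                )
                tumor_vs_normal_table = nt
                manifest["analyses"][name] = rec
            elif name == "purity":
                recs = {}
                for thr in config.purity_thresholds:
                    keep = filter_by_purity(cohort.sheet, thr)
                    sub = [(p, t, n) for p, t, n in pairs if p in keep]
                    sub_out = out / f"purity_gt_{int(round(thr * 100))}"
                    _, rec = _emit_comparison(
                        cohort,
                        [n for _, _, n in sub],
                        [t for _, t, _ in sub],
                        "normal", "tumor", sub_out,
                        n_perm=config.n_perm, bin_width=config.bin_width,
                        seed=_stage_seed(config.seed, name), log=log,
                    )
                    recs[f"purity_gt_{int(round(thr * 100))}"] = rec
                manifest["analyses"][name] = recs
            elif name in ("p53_quartiles", "immune_quartiles"):
                markers = (
                    config.p53_markers if name == "p53_quartiles" else config.immune_markers
                )
                top, bottom = _quartile_groups(
                    cohort, markers, config.score_tissue, config.noise_tissue
                )
                short = name.split("_")[0]
                _, rec = _emit_comparison(
                    cohort, top, bottom, f"{short}_high", f"{short}_low", out,
                    n_perm=config.n_perm, bin_width=config.bin_width,
                    seed=_stage_seed(config.seed, name), log=log,
                )
                manifest["analyses"][name] = rec
            elif name == "stage":
                early, late = stage_groups(cohort.sheet)
                df = cohort.sheet.data
                tissue_samples = df[df["tissue"] == config.noise_tissue]
                early_s = tissue_samples.loc[
                    tissue_samples["patient_id"].isin(early), "sample_id"
                ].tolist()
                late_s = tissue_samples.loc[
                    tissue_samples["patient_id"].isin(late), "sample_id"
                ].tolist()
                _, rec = _emit_comparison(
                    cohort, early_s, late_s, "early", "late", out,
                    n_perm=config.n_perm, bin_width=config.bin_width,
                    seed=_stage_seed(config.seed, name), log=log,
                )
                manifest["analyses"][name] = rec
            elif name == "gene_sets":
                if tumor_vs_normal_table is None:
                    normals = [n for _, _, n in pairs]
                    tumors = [t for _, t, _ in pairs]
                    tumor_vs_normal_table = noise_table(
                        cohort, normals, tumors, label_a="normal", label_b="tumor"
                    )
                out.mkdir(parents=True, exist_ok=True)
                tables = {"cohort": tumor_vs_normal_table}
                counts, files = {}, []
                for thr in config.increased_thresholds:
                    res = increased_set(tables, thr)
                    fname = f"increased_gt_{thr:g}.txt"
                    write_gene_list(sorted(res.intersection), out / fname)
                    counts[f"increased_gt_{thr:g}"] = len(res.intersection)
                    files.append(fname)
                res = decreased_set(tables, config.decreased_threshold)
                fname = f"decreased_lt_{config.decreased_threshold:g}.txt"
                write_gene_list(sorted(res.intersection), out / fname)
                counts[f"decreased_lt_{config.decreased_threshold:g}"] = len(
                    res.intersection
                )
                files.append(fname)
                if len(res.intersection) > 0:
                    write_table(membership_table(res), out / "decreased_membership.tsv")
                    files.append("decreased_membership.tsv")
                write_json(counts, out / "gene_set_counts.json")
                files.append("gene_set_counts.json")
                log(f"[{name}] counts: {counts}")
                manifest["analyses"][name] = {"files": files, "counts": counts}
        except Exception as exc:
            shutil.rmtree(out, ignore_errors=True)
            raise RuntimeError(f"analysis {name!r} failed: {exc}") from exc
    write_json(manifest, out_root / "manifest.json")
    return manifest
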