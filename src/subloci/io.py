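"""Readers and writers for the text formats the pipeline consumes.

BED for interval annotations, bedGraph for signal tracks, and TSV for the
tabular inputs (variant tables, GWAS summary statistics, expression
matrices, allele-specific read counts, 4C fragment-end profiles).

Variant positions are 1-based in all tables; BED/bedGraph coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, SignalTrack


@dataclass
class VariantRecord:
    """One SNP with the covariates used for matched-control sampling.

    ``pvalue`` may be ``None``: a small number of LD partners in real
    summary files lack computed p-values and remain valid locus members.
    """

    id: str
    chrom: str
    pos: int  # 1-based
    maf: float
    pvalue: float | None = None
    on_array: bool = False
    dist_to_nearest_gene: int = 0  # bp; 0 if inside a gene
    n_genes_500kb: int = 0
    block_size: int = 1  # number of SNPs in LD (r2>0.8) incl. self

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf} ({self.id})")
        if self.pvalue is not None and not 0 < self.pvalue <= 1:
            raise ValueError(f"pvalue must be in (0,1], got {self.pvalue} ({self.id})")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


# required columns per table schema; extra columns are preserved
TABLE_SCHEMAS: dict[str, list[str]] = {
    "variants": ["id", "chrom", "pos", "maf", "on_array",
                 "dist_to_nearest_gene", "n_genes_500kb"],
    "summary_stats": ["id", "chrom", "pos", "pvalue"],
    "expression": [],  # matrix: first column gene id, remaining tissues
    "allele_counts": ["snp_id", "ref_reads", "alt_reads",
                      "ref_unique_pos", "alt_unique_pos"],
    "fragends": ["position", "count"],
}


def read_intervals(path: str | Path, label: str | None = None) -> AnnotationSet:
    """Parse a BED file (>=3 columns) into an :class:`AnnotationSet`.

    Track lines, comments and blank lines are skipped.  Malformed lines
    raise with their line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationSet(label or path.stem, intervals)


def write_intervals(annotation: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotation:
            name = iv.name if iv.name is not None else "."
            if iv.strand is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    path = Path(path)
    segments: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            segments.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return SignalTrack(segments, name=name or path.stem)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.segments(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV table and validate it against a named schema.

    ``expression`` returns a genes x tissues matrix (gene ids as index);
    all other schemas return a flat frame with typed columns.  Empty
    p-value cells become NaN (an allowed absence); non-numeric p-values
    raise.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    if schema == "expression":
        mat = pd.read_csv(path, sep="\t", index_col=0)
        if (mat.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if mat.columns.duplicated().any():
            raise ValueError("duplicate tissue labels in expression matrix")
        return mat
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "snp_id": str, "chrom": str})
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "pvalue" in df.columns:
        try:
            df["pvalue"] = pd.to_numeric(df["pvalue"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric p-value") from exc
        bad = df["pvalue"].dropna()
        if ((bad <= 0) | (bad > 1)).any():
            raise ValueError(f"{path}: p-values outside (0, 1]")
    if "maf" in df.columns:
        if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
            raise ValueError(f"{path}: maf outside (0, 0.5]")
    if "on_array" in df.columns:
        df["on_array"] = df["on_array"].astype(bool)
    for col in ("pos", "ref_reads", "alt_reads", "ref_unique_pos",
                "alt_unique_pos", "position", "count",
                "dist_to_nearest_gene", "n_genes_500kb", "block_size"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(np.int64)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def variant_records(df: pd.DataFrame) -> list[VariantRecord]:
    """Convert a validated variants frame to :class:`VariantRecord` objects."""
    records = []
    has_p = "pvalue" in df.columns
    has_block = "block_size" in df.columns
    for row in df.itertuples(index=False):
        p = getattr(row, "pvalue", None) if has_p else None
        if p is not None and np.isnan(p):
            p = None
        records.append(
            VariantRecord(
                id=row.id,
                chrom=row.chrom,
                pos=int(row.pos),
                maf=float(row.maf),
                pvalue=p,
                on_array=bool(row.on_array),
                dist_to_nearest_gene=int(row.dist_to_nearest_gene),
                n_genes_500kb=int(row.n_genes_500kb),
                block_size=int(row.block_size) if has_block else 1,
            )
        )
    return records


def read_ld_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a pairwise r-squared table (columns: id_a, id_b, r2)."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    for col in ("id_a", "id_b", "r2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise ValueError(f"{path}: r2 outside [0, 1]")
    table: dict[tuple[str, str], float] = {}
    for a, b, r2 in zip(df["id_a"], df["id_b"], df["r2"]):
        table[(a, b)] = float(r2)
        table[(b, a)] = float(r2)
    return table


def write_ld_table(pairs: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\n")
        for a, b, r2 in pairs:
            fh.write(f"{a}\t{b}\t{r2:g}\n")
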