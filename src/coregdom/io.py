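"""Readers and writers for the tabular and matrix formats used throughout.

Internal coordinates are 0-based half-open; BED is written natively and
GTF-style 1-based inclusive coordinates are converted on input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hic import ContactMatrix


class ParseError(ValueError):
    """Malformed input row; the message carries the 1-based line number."""


GENE_COLUMNS = [
    "chrom", "start", "end", "strand", "gene_id", "tss", "expressed",
    "log2fc_2h", "log2fc_12h", "log2fc_12v2", "p", "p_adj",
]


def _validate_intervals(df: pd.DataFrame, path, header_lines: int = 1) -> None:
    bad = np.flatnonzero((df["end"] <= df["start"]).to_numpy())
    if len(bad):
        line = int(bad[0]) + header_lines + 1
        raise ParseError(f"{path}: end <= start at line {line}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
    if {"start", "end"} <= set(df.columns):
        _validate_intervals(df, path)
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    cols = [c for c in GENE_COLUMNS if c in genes.columns]
    write_table(genes[cols], path)


def read_gene_table(path) -> pd.DataFrame:
    genes = read_table(path, required=["chrom", "start", "end", "gene_id"])
    if "expressed" in genes.columns:
        genes["expressed"] = genes["expressed"].astype(bool)
    return genes


def write_peaks(peaks: pd.DataFrame, path) -> None:
    write_table(peaks, path)


def read_peaks(path) -> pd.DataFrame:
    return read_table(path, required=["chrom", "start", "end", "summit"])


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    """Headerless BED3+ (chrom, start, end, then any extra columns)."""
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, extra_cols=()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_cols]
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     usecols=range(len(names)))
    _validate_intervals(df, path, header_lines=0)
    return df


def write_matrix(cm: ContactMatrix, path) -> None:
    """Dense delimited text with a bin-start header row and column."""
    n = cm.n_bins
    bins = np.arange(n) * cm.bin_size
    with open(path, "w") as fh:
        fh.write(f"# chrom={cm.chrom} bin_size={cm.bin_size} "
                 f"normalization={cm.normalization}\n")
        fh.write("bin\t" + "\t".join(map(str, bins)) + "\n")
        for b, row in zip(bins, cm.matrix):
            fh.write(str(b) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def read_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        meta_line = fh.readline().strip()
    meta = dict(
        kv.split("=") for kv in meta_line.lstrip("# ").split() if "=" in kv
    )
    body = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    return ContactMatrix(
        chrom=meta.get("chrom", "chr?"),
        bin_size=int(meta.get("bin_size", 10000)),
        matrix=body.to_numpy(dtype=float),
        normalization=meta.get("normalization", "raw"),
    )


def read_gtf_genes(path) -> pd.DataFrame:
    """Minimal GTF reader: gene feature rows to a 0-based gene table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}: fewer than 9 GTF fields at line {ln}")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature != "gene":
                continue
            gene_id = None
            for field in attrs.split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gene_id = field.split(" ", 1)[1].strip().strip('"')
            start0 = int(start) - 1  # GTF is 1-based inclusive
            end0 = int(end)
            if end0 <= start0:
                raise ParseError(f"{path}: end <= start at line {ln}")
            rows.append(
                {
                    "chrom": chrom, "start": start0, "end": end0,
                    "strand": strand, "gene_id": gene_id,
                    "tss": start0 if strand == "+" else end0 - 1,
                }
            )
    return pd.DataFrame(rows)


def read_config(path) -> dict:
    """Flat key: value configuration (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a key:value mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
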