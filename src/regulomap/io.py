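"""Readers and writers for the plain-text genomics formats the pipeline consumes.

BED family files are 0-based half-open; GFF3 is 1-based closed and converted
at this boundary. All writers emit records sorted by (chrom, start).
"""
from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .intervals import regions, sort_regions

GENE_COLS = ["chrom", "start", "end", "strand", "gene_id", "confidence"]


class ParseError(ValueError):
    pass


def read_bed(path, extra_names: list[str] | None = None) -> pd.DataFrame:
    """Read BED3+ into a region DataFrame.

    ``extra_names`` names columns 4, 5, ... in order; unnamed extra columns
    are dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return regions(extra_cols=extra_names)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns, found {df.shape[1]}")
    names = ["chrom", "start", "end"] + (extra_names or [])
    df = df.iloc[:, : len(names)].copy()
    df.columns = names[: df.shape[1]]
    for col in extra_names or []:
        if col not in df.columns:
            df[col] = np.nan
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, cols: list[str] | None = None) -> None:
    out = sort_regions(df)
    extra = cols if cols is not None else [c for c in out.columns if c not in ("chrom", "start", "end")]
    out[["chrom", "start", "end"] + extra].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Extract ``gene`` features from a GFF3 file into a gene table.

    Returns columns chrom, start, end, strand, gene_id, confidence, tss, tes.
    Confidence defaults to "high"; a ``confidence=low`` (or ``HC``/``LC``
    ``primary_confidence_class``) attribute overrides it.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: gene without strand")
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = dict(
                (m.group(1), m.group(2))
                for m in re.finditer(r"([^;=\s]+)=([^;]*)", attrs)
            )
            gene_id = attr.get("ID", f"gene_{lineno}")
            conf = attr.get("confidence", attr.get("primary_confidence_class", "high"))
            conf = {"HC": "high", "LC": "low"}.get(conf, conf)
            rows.append((chrom, s1 - 1, e1, strand, gene_id, conf))
    return annotate_gene_ends(pd.DataFrame(rows, columns=GENE_COLS))


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    out = sort_regions(genes)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in out.itertuples(index=False):
            attrs = f"ID={row.gene_id};confidence={row.confidence}"
            fh.write(
                f"{row.chrom}\tregulomap\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_bed12_genes(path) -> pd.DataFrame:
    """Read gene models from BED12 (or BED6); name column is the gene id."""
    df = read_bed(path, ["gene_id", "score", "strand"])
    if df["strand"].isna().any():
        raise ParseError(f"{path}: BED gene models need a strand column")
    genes = df[["chrom", "start", "end", "strand", "gene_id"]].copy()
    genes["confidence"] = "high"
    return annotate_gene_ends(genes)


def annotate_gene_ends(genes: pd.DataFrame) -> pd.DataFrame:
    """Add tss/tes columns (bp positions) from the interval and strand."""
    genes = genes.copy()
    if genes.empty:
        genes["tss"] = pd.Series(dtype=np.int64)
        genes["tes"] = pd.Series(dtype=np.int64)
        return genes
    if not genes["strand"].isin(["+", "-"]).all():
        raise ParseError("gene with missing or invalid strand")
    plus = genes["strand"] == "+"
    genes["tss"] = np.where(plus, genes["start"], genes["end"] - 1).astype(np.int64)
    genes["tes"] = np.where(plus, genes["end"] - 1, genes["start"]).astype(np.int64)
    return genes


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)
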