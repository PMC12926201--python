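"""Whole-genome bisulfite methylome summaries and unmethylated-region (UMR) calling.

A UMR is a run of consecutive 300-bp windows in which the coverage-weighted
methylation level is at most 1% in each of the CpG, CHG and CHH contexts,
restricted to the intergenic compartment. Only cytosines with read coverage
of at least ``min_cov`` contribute. This follows the windowed-UMR approach
used for plant methylomes, where stable lack of methylation marks candidate
regulatory sequence regardless of the element's activity window.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv

CONTEXTS = ("CpG", "CHG", "CHH")

CX_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]

#: how a window with zero covered cytosines in a context is treated:
#: that context passes vacuously, but a window with no covered cytosine in
#: ANY context is "no-data" and never part of a UMR.

_CONTEXT_ALIASES = {"CPG": "CpG", "CG": "CpG", "CHG": "CHG", "CHH": "CHH"}


def normalize_context(values: pd.Series) -> pd.Series:
    mapped = values.astype(str).str.upper().map(_CONTEXT_ALIASES)
    if mapped.isna().any():
        bad = values[mapped.isna()].iloc[0]
        raise ValueError(f"unknown methylation context {bad!r}")
    return mapped


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report (1-based positions on disk).

    Columns: chrom, pos, strand, count-methylated, count-unmethylated,
    context, trinucleotide. Positions are converted to 0-based; an
    ``n_total`` column is added.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=CX_COLS, dtype={0: str})
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["context"] = normalize_context(df["context"])
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    if (df["n_meth"] > df["n_total"]).any() or (df["n_meth"] < 0).any():
        raise ValueError("methylated read count outside [0, total]")
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    out = df.sort_values(["chrom", "pos"], kind="mergesort")[CX_COLS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def global_methylation(records: pd.DataFrame, min_cov: int = 5) -> dict[str, float | None]:
    """Genome-wide weighted methylation percent per context.

    level(context) = 100 * sum(n_meth) / sum(n_total) over cytosines with
    n_total >= min_cov. A context with no covered cytosine is reported as
    None (missing), not 0.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    covered = records[records["n_total"] >= min_cov]
    sums = covered.groupby("context")[["n_meth", "n_total"]].sum()
    out: dict[str, float | None] = {}
    for ctx in CONTEXTS:
        if ctx in sums.index and sums.loc[ctx, "n_total"] > 0:
            out[ctx] = 100.0 * float(sums.loc[ctx, "n_meth"]) / float(sums.loc[ctx, "n_total"])
        else:
            out[ctx] = None
    return out


def window_methylation(
    records: pd.DataFrame, window: int = 300, min_cov: int = 5
) -> pd.DataFrame:
    """Per-window, per-context weighted methylation over a fixed genome-anchored grid.

    Returns one row per (chrom, window index) that has at least one covered
    cytosine in at least one context, with columns ``meth_<ctx>`` (fraction,
    NaN when that context has no covered cytosine) and ``total_<ctx>``.
    """
    covered = records[records["n_total"] >= min_cov].copy()
    if covered.empty:
        return pd.DataFrame(columns=["chrom", "widx"])
    covered["widx"] = covered["pos"] // window
    agg = (
        covered.groupby(["chrom", "widx", "context"], observed=True)[["n_meth", "n_total"]]
        .sum()
        .unstack("context")
    )
    out = pd.DataFrame(index=agg.index)
    for ctx in CONTEXTS:
        meth = agg.get(("n_meth", ctx))
        total = agg.get(("n_total", ctx))
        if meth is None:
            out[f"meth_{ctx}"] = np.nan
            out[f"total_{ctx}"] = 0
        else:
            total = total.fillna(0)
            out[f"meth_{ctx}"] = np.where(total > 0, meth.fillna(0) / total.replace(0, np.nan), np.nan)
            out[f"total_{ctx}"] = total.astype(np.int64)
    return out.reset_index()


def call_umrs(
    records: pd.DataFrame,
    intergenic: pd.DataFrame,
    window: int = 300,
    max_meth: float = 0.01,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Call intergenic UMRs.

    A window is unmethylated iff every context with covered cytosines is at
    or below ``max_meth`` and at least one context has data. Adjacent
    unmethylated windows are merged; merged blocks are intersected with the
    intergenic set. Returns a region DataFrame with an ``n_windows`` column
    (number of 300-bp fragments in the parent block).
    """
    if not (0 <= max_meth <= 1):
        raise ValueError("max_meth must be in [0, 1]")
    wm = window_methylation(records, window=window, min_cov=min_cov)
    if wm.empty:
        return iv.regions(extra_cols=["n_windows"])
    ok = np.ones(len(wm), dtype=bool)
    has_data = np.zeros(len(wm), dtype=bool)
    for ctx in CONTEXTS:
        meth = wm[f"meth_{ctx}"].to_numpy()
        defined = ~np.isnan(meth)
        has_data |= defined
        ok &= ~defined | (meth <= max_meth)
    unmeth = wm[ok & has_data]

    # merge runs of consecutive window indices into blocks
    blocks = []
    for chrom, sub in unmeth.groupby("chrom", sort=True):
        widx = np.sort(sub["widx"].to_numpy(np.int64))
        if len(widx) == 0:
            continue
        breaks = np.nonzero(np.diff(widx) > 1)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(widx) - 1]])
        for a, b in zip(run_starts, run_ends):
            blocks.append((chrom, widx[a] * window, (widx[b] + 1) * window, b - a + 1))
    block_df = iv.regions(blocks, extra_cols=["n_windows"])
    if block_df.empty:
        return block_df

    # clip each block to intergenic space, keeping the parent window count
    out = []
    for row in block_df.itertuples(index=False):
        piece = iv.intersect(
            iv.regions([(row.chrom, row.start, row.end)]), intergenic
        )
        for p in piece.itertuples(index=False):
            out.append((p.chrom, p.start, p.end, row.n_windows))
    return iv.regions(out, extra_cols=["n_windows"])


def permanent_umrs(
    umrs_a: pd.DataFrame, umrs_b: pd.DataFrame, mode: str = "a_anchored"
) -> pd.DataFrame:
    """UMRs supported in both samples.

    mode "a_anchored" (default): each UMR of A overlapping >= 1 bp of B;
    "b_anchored": the converse; "intersection": base-level intersection.
    """
    if mode == "a_anchored":
        return umrs_a[iv.overlaps_any(umrs_a, umrs_b)].reset_index(drop=True)
    if mode == "b_anchored":
        return umrs_b[iv.overlaps_any(umrs_b, umrs_a)].reset_index(drop=True)
    if mode == "intersection":
        return iv.intersect(umrs_a, umrs_b)
    raise ValueError(f"unknown mode {mode!r}")
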