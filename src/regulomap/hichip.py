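"""Hierarchical annotation of significant HiChIP loops and interaction summaries.

Loops are pairs of fixed-resolution bins ("anchors") with an FDR q-value,
as emitted by FitHiChIP. Each anchor receives the single highest-priority
overlapping feature label from a prioritized library — active promoters,
silent promoters, terminators, introns, the open intergenic chromatin state
(E7), the intergenic polycomb state (E4), then transposable elements — and
an unordered pair of anchor labels defines the interaction class.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv

#: fixed hierarchical annotation order
PRIORITY = ["active_promoter", "silent_promoter", "terminator", "intron", "E7", "E4", "TE"]

LOOP_COLS = ["chrom", "start1", "end1", "start2", "end2", "qvalue"]


class FeatureLibrary:
    """Prioritized (label, region set) list for hierarchical anchor annotation.

    Tracks may be omitted; order follows :data:`PRIORITY` with unknown
    labels appended in insertion order.
    """

    def __init__(self, tracks: dict[str, pd.DataFrame]):
        known = [l for l in PRIORITY if l in tracks]
        extra = [l for l in tracks if l not in PRIORITY]
        self.labels = known + extra
        self.tracks = {label: tracks[label] for label in self.labels}

    def annotate(self, anchors: pd.DataFrame) -> np.ndarray:
        """Highest-priority overlapping label per anchor row, or "other"."""
        labels = np.full(len(anchors), "other", dtype=object)
        unassigned = np.ones(len(anchors), dtype=bool)
        for label in self.labels:
            track = self.tracks[label]
            if track.empty or not unassigned.any():
                continue
            hit = iv.overlaps_any(anchors, track) & unassigned
            labels[hit] = label
            unassigned &= ~hit
        return labels


def read_bedpe(path, qvalue_col: str | int = "Q-Value_Bias") -> pd.DataFrame:
    """Read a FitHiChIP-style loop table (TSV with header).

    The first six columns are chr1,s1,e1,chr2,s2,e2; ``qvalue_col`` names
    (or indexes) the q-value column. Inter-chromosomal rows are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    cols = df.columns
    if isinstance(qvalue_col, int):
        qvalue_col = cols[qvalue_col]
    if qvalue_col not in cols:
        raise ValueError(f"{path}: no q-value column {qvalue_col!r}")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0].astype(str),
            "start1": df.iloc[:, 1].astype(np.int64),
            "end1": df.iloc[:, 2].astype(np.int64),
            "chrom2": df.iloc[:, 3].astype(str),
            "start2": df.iloc[:, 4].astype(np.int64),
            "end2": df.iloc[:, 5].astype(np.int64),
            "qvalue": df[qvalue_col].astype(float),
        }
    )
    if (out["chrom"] != out["chrom2"]).any():
        raise ValueError(f"{path}: inter-chromosomal loop found; loops must be intra-chromosomal")
    return out.drop(columns="chrom2")


def snap_to_grid(loops: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Snap anchors onto the fixed resolution grid and orient anchor1 <= anchor2.

    Inputs already binned at ``resolution`` pass through unchanged.
    Duplicate bin pairs keep the smallest q-value.
    """
    out = loops.copy()
    for side in ("1", "2"):
        s = (out[f"start{side}"].to_numpy(np.int64) // resolution) * resolution
        out[f"start{side}"] = s
        out[f"end{side}"] = s + resolution
    swap = out["start1"] > out["start2"]
    out.loc[swap, ["start1", "end1", "start2", "end2"]] = out.loc[
        swap, ["start2", "end2", "start1", "end1"]
    ].to_numpy()
    out = (
        out.sort_values("qvalue", kind="mergesort")
        .drop_duplicates(["chrom", "start1", "start2"], keep="first")
        .sort_values(["chrom", "start1", "start2"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def filter_loops(loops: pd.DataFrame, fdr: float = 0.05, max_dist: float = 2e6) -> pd.DataFrame:
    if not (0 < fdr <= 1):
        raise ValueError("fdr must be in (0, 1]")
    dist = _midpoint_distance(loops)
    keep = (loops["qvalue"] <= fdr) & (dist <= max_dist)
    return loops[keep].reset_index(drop=True)


def _anchors(loops: pd.DataFrame, side: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": loops["chrom"], "start": loops[f"start{side}"], "end": loops[f"end{side}"]}
    )


def _midpoint_distance(loops: pd.DataFrame) -> np.ndarray:
    m1 = (loops["start1"].to_numpy(np.int64) + loops["end1"].to_numpy(np.int64)) // 2
    m2 = (loops["start2"].to_numpy(np.int64) + loops["end2"].to_numpy(np.int64)) // 2
    return np.abs(m2 - m1)


def annotate_loops(loops: pd.DataFrame, library: FeatureLibrary) -> pd.DataFrame:
    """Add label1, label2, class (sorted unordered pair) and distance columns."""
    out = loops.copy()
    out["label1"] = library.annotate(_anchors(loops, "1"))
    out["label2"] = library.annotate(_anchors(loops, "2"))
    out["klass"] = [
        "|".join(sorted((a, b))) for a, b in zip(out["label1"], out["label2"])
    ]
    out["distance"] = _midpoint_distance(out)
    return out


def class_composition(
    loops: pd.DataFrame,
    library: FeatureLibrary,
    centric: str | None = None,
    fdr: float = 0.05,
    max_dist: float = 2e6,
) -> pd.DataFrame:
    """Interaction-class counts and percents.

    ``centric`` restricts to loops with at least one anchor of that label
    (e.g. active-promoter-centric analysis); percents are over the
    restricted set and sum to 100.
    """
    annotated = annotate_loops(filter_loops(loops, fdr=fdr, max_dist=max_dist), library)
    if centric is not None:
        annotated = annotated[
            (annotated["label1"] == centric) | (annotated["label2"] == centric)
        ]
    counts = annotated.groupby("klass").size().sort_values(ascending=False)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "klass": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total if total else 0.0,
        }
    ).reset_index(drop=True)


def spanned_genes(loops: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Genes lying strictly within the open gap between the two anchors.

    A gene is counted when its interval fits inside the half-open gap
    [anchor1.end, anchor2.start); genes overlapping either anchor are
    excluded. Adjacent
    or overlapping anchors span 0 genes.
    """
    counts = np.zeros(len(loops), dtype=np.int64)
    genes_by_chrom = {
        chrom: sub.sort_values("start")[["start", "end"]].to_numpy(np.int64)
        for chrom, sub in genes.groupby("chrom", sort=False)
    }
    for k, row in enumerate(loops.itertuples(index=False)):
        arr = genes_by_chrom.get(row.chrom)
        if arr is None:
            continue
        gap_lo, gap_hi = row.end1, row.start2
        if gap_hi <= gap_lo:
            continue
        inside = (arr[:, 0] >= gap_lo) & (arr[:, 1] <= gap_hi)
        counts[k] = int(inside.sum())
    return counts


def interactions_per_promoter(
    loops: pd.DataFrame, promoters: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Number of distinct significant loops touching each promoter.

    A loop with both anchors on the same promoter counts once. Returns
    (per-promoter degrees with gene ids, degree histogram including bin 0).
    """
    prom = promoters.reset_index(drop=True)
    degree = np.zeros(len(prom), dtype=np.int64)
    a1, a2 = _anchors(loops, "1"), _anchors(loops, "2")
    for i in range(len(loops)):
        hits1 = iv.overlaps_any(prom, a1.iloc[[i]])
        hits2 = iv.overlaps_any(prom, a2.iloc[[i]])
        degree += (hits1 | hits2).astype(np.int64)
    per_prom = prom.copy()
    per_prom["degree"] = degree
    hist = (
        per_prom.groupby("degree").size().rename("n_promoters").reset_index().sort_values("degree")
    )
    return per_prom, hist.reset_index(drop=True)


def promoter_terminator_tracks(
    genes: pd.DataFrame,
    resolution: int,
    active_marks: pd.DataFrame | None = None,
    silent_marks: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Build promoter/terminator tracks as TSS/TES +- half-resolution windows.

    Promoters are split into active (overlapping H3K4me3 peaks) and silent
    (overlapping H3K27me3 peaks, not active). Windows are clipped at 0.
    """
    half = resolution // 2
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["tss"].to_numpy(np.int64) - half, 0),
            "end": genes["tss"].to_numpy(np.int64) + half,
            "gene_id": genes["gene_id"],
        }
    )
    term = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["tes"].to_numpy(np.int64) - half, 0),
            "end": genes["tes"].to_numpy(np.int64) + half,
            "gene_id": genes["gene_id"],
        }
    )
    tracks: dict[str, pd.DataFrame] = {"terminator": term}
    if active_marks is not None:
        active = iv.overlaps_any(prom, active_marks)
    else:
        active = np.zeros(len(prom), dtype=bool)
    if silent_marks is not None:
        silent = iv.overlaps_any(prom, silent_marks) & ~active
    else:
        silent = np.zeros(len(prom), dtype=bool)
    tracks["active_promoter"] = prom[active].reset_index(drop=True)
    tracks["silent_promoter"] = prom[silent].reset_index(drop=True)
    return tracks


def self_loops(loops: pd.DataFrame, genes: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Loops joining a gene's promoter bin to the same gene's terminator bin.

    Promoter/terminator regions are TSS/TES +- half-resolution windows; a
    loop within a single bin (distance 0) is not a self-loop. Returns one
    row per (loop, gene) match with the gene id.
    """
    half = resolution // 2
    rows = []
    loops_idx = loops.reset_index(drop=True)
    for g in genes.itertuples(index=False):
        prom = (max(g.tss - half, 0), g.tss + half)
        term = (max(g.tes - half, 0), g.tes + half)
        sub = loops_idx[loops_idx["chrom"] == g.chrom]
        for row in sub.itertuples():
            if row.start1 == row.start2:
                continue
            a1 = (row.start1, row.end1)
            a2 = (row.start2, row.end2)

            def hits(anchor, window):
                return anchor[0] < window[1] and anchor[1] > window[0]

            if (hits(a1, prom) and hits(a2, term)) or (hits(a1, term) and hits(a2, prom)):
                rows.append(
                    (g.gene_id, g.chrom, row.start1, row.end1, row.start2, row.end2, row.qvalue)
                )
    return pd.DataFrame(rows, columns=["gene_id"] + LOOP_COLS)


def bivalent_interactions(
    k4_loops: pd.DataFrame, k27_loops: pd.DataFrame, resolution: int
) -> pd.DataFrame:
    """Loops whose both anchors are present in the H3K4me3 AND H3K27me3 sets
    at the same resolution (bin identity after grid snapping). Symmetric in
    its two inputs."""
    for df in (k4_loops, k27_loops):
        widths = pd.concat([df["end1"] - df["start1"], df["end2"] - df["start2"]])
        if not widths.empty and not (widths == resolution).all():
            raise ValueError("loop sets are not binned at the stated resolution")
    a = snap_to_grid(k4_loops, resolution)
    b = snap_to_grid(k27_loops, resolution)
    keys_b = set(zip(b["chrom"], b["start1"], b["start2"]))
    shared = a[[k in keys_b for k in zip(a["chrom"], a["start1"], a["start2"])]]
    return shared.reset_index(drop=True)


def distance_stats(loops: pd.DataFrame) -> dict[str, float | None]:
    """Mean and median anchor midpoint separation in bp (None when empty)."""
    if loops.empty:
        return {"mean": None, "median": None}
    d = _midpoint_distance(loops)
    return {"mean": float(np.mean(d)), "median": float(np.median(d))}
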