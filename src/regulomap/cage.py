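"""NET-CAGE tag-cluster pruning, bidirectional merging and U/BU/BB classification.

Strictly intergenic tag clusters are tested for an antisense partner: two
clusters of opposite strand whose dominant TSSs lie within ``max_dist`` bp
are linked when the antisense partner is expressed above
``partner_min_tpm`` and is not a singleton (a cluster with a single CTSS
position). Connected components containing both strands become one
bidirectional unit delimited by the minus-strand and plus-strand dominant
TSSs; everything else stays unidirectional (U). Bidirectional units are
balanced (BB) when |log2(plus TPM / minus TPM)| <= 1, else unbalanced (BU) —
the balanced configuration is the canonical animal eRNA signature.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv

CLUSTER_COLS = ["chrom", "start", "end", "strand", "dominant_tss", "tpm", "n_ctss", "iqw"]

UNIT_COLS = ["chrom", "start", "end", "klass", "plus_tpm", "minus_tpm", "log2fc", "members"]


def read_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CLUSTER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cluster table missing columns {sorted(missing)}")
    bad = (df["dominant_tss"] < df["start"]) | (df["dominant_tss"] >= df["end"])
    if bad.any():
        raise ValueError("dominant TSS outside its cluster interval")
    return df


def write_clusters(df: pd.DataFrame, path) -> None:
    df[CLUSTER_COLS].to_csv(path, sep="\t", index=False)


def _min_gap(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Gap in bp between each query interval and its nearest feature
    (0 when overlapping; large sentinel when the chromosome has none)."""
    big = np.int64(10**15)
    out = np.full(len(query), big)
    feats = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in iv.merge(features).groupby("chrom", sort=False)
    }
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in feats:
            continue
        fs, fe = feats[chrom]
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        i = np.searchsorted(fs, qe, side="left")  # first feature starting at/after qe
        gap_right = np.where(i < len(fs), fs[np.minimum(i, len(fs) - 1)] - qe, big)
        j = np.maximum(i - 1, 0)
        gap_left = np.where(i > 0, np.maximum(qs - fe[j], 0), big)
        overlap = (i > 0) & (fe[j] > qs)
        gap = np.where(overlap, 0, np.minimum(gap_right, gap_left))
        out[sub.index.to_numpy()] = gap
    return out


def prune_intergenic(
    clusters: pd.DataFrame,
    genes: pd.DataFrame,
    rnaseq_signal: pd.DataFrame,
    lncrna: pd.DataFrame,
    gene_margin: int = 500,
    rna_margin: int = 500,
) -> pd.DataFrame:
    """Keep clusters > ``gene_margin`` bp from every gene, > ``rna_margin``
    bp from every RNA-seq signal region, and not overlapping any lncRNA."""
    if clusters.empty:
        return clusters
    keep = np.ones(len(clusters), dtype=bool)
    cl = clusters.reset_index(drop=True)
    if not genes.empty:
        keep &= _min_gap(cl, genes) > gene_margin
    if not rnaseq_signal.empty:
        keep &= _min_gap(cl, rnaseq_signal) > rna_margin
    if not lncrna.empty:
        keep &= ~iv.overlaps_any(cl, lncrna)
    return cl[keep].reset_index(drop=True)


def _components(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Union-find connected-component labels for n nodes."""
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    return np.array([find(i) for i in range(n)])


def merge_bidirectional(
    clusters: pd.DataFrame,
    max_dist: int = 600,
    partner_min_tpm: float = 0.1,
) -> pd.DataFrame:
    """Merge antisense cluster pairs into directional units.

    A pair of opposite-strand clusters is linked when their dominant TSSs
    are <= ``max_dist`` bp apart and at least one of them — viewed as the
    other's antisense partner — has tpm > ``partner_min_tpm`` and more than
    one CTSS position. Linked components spanning both strands become one
    bidirectional unit delimited by the component's minus-strand and
    plus-strand dominant TSSs; unlinked clusters become U units with their
    original interval. Output is independent of input row order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    cl = cl_sorted = clusters.sort_values(
        ["chrom", "dominant_tss", "strand", "start"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(cl)
    eligible = (cl["tpm"].to_numpy() > partner_min_tpm) & (cl["n_ctss"].to_numpy() > 1)
    edges: list[tuple[int, int]] = []
    chroms = cl["chrom"].to_numpy()
    dtss = cl["dominant_tss"].to_numpy(np.int64)
    strands = cl["strand"].to_numpy()
    for i in range(n):
        j = i + 1
        while j < n and chroms[j] == chroms[i] and dtss[j] - dtss[i] <= max_dist:
            if strands[j] != strands[i] and (eligible[i] or eligible[j]):
                edges.append((i, j))
            j += 1
    labels = _components(n, edges)

    rows = []
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        members = cl_sorted.iloc[idx]
        member_ids = ",".join(
            members["cluster_id"].astype(str) if "cluster_id" in members else members.index.astype(str)
        )
        plus = members[members["strand"] == "+"]
        minus = members[members["strand"] == "-"]
        chrom = members["chrom"].iloc[0]
        if len(plus) and len(minus):
            plus_tpm = float(plus["tpm"].sum())
            minus_tpm = float(minus["tpm"].sum())
            lo = int(minus["dominant_tss"].min())
            hi = int(plus["dominant_tss"].max())
            if lo > hi:  # convergent geometry: fall back to the coordinate span
                lo = int(members["dominant_tss"].min())
                hi = int(members["dominant_tss"].max())
            rows.append((chrom, lo, hi + 1, "B", plus_tpm, minus_tpm, np.nan, member_ids))
        else:
            strand_tpm = float(members["tpm"].sum())
            plus_tpm = strand_tpm if len(plus) else 0.0
            minus_tpm = strand_tpm if len(minus) else 0.0
            rows.append(
                (
                    chrom,
                    int(members["start"].min()),
                    int(members["end"].max()),
                    "U",
                    plus_tpm,
                    minus_tpm,
                    np.nan,
                    member_ids,
                )
            )
    units = pd.DataFrame(rows, columns=UNIT_COLS)
    return units.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def classify(units: pd.DataFrame, balance_bound: float = 1.0) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign U / BU / BB labels and the log2 plus/minus TPM ratio.

    BB iff -balance_bound <= log2fc <= balance_bound (bounds inclusive);
    a bidirectional unit with zero TPM on one strand is BU with an infinite
    log2fc sentinel. Returns (labelled units, per-class counts).
    """
    units = units.copy()
    klass = []
    log2fc = []
    for row in units.itertuples(index=False):
        if row.klass == "U":
            klass.append("U")
            log2fc.append(np.nan)
            continue
        if row.minus_tpm == 0 or row.plus_tpm == 0:
            lfc = np.inf if row.minus_tpm == 0 else -np.inf
        else:
            lfc = float(np.log2(row.plus_tpm / row.minus_tpm))
        log2fc.append(lfc)
        klass.append("BB" if -balance_bound <= lfc <= balance_bound else "BU")
    units["klass"] = klass
    units["log2fc"] = log2fc
    counts = {
        "U": int((units["klass"] == "U").sum()),
        "BU": int((units["klass"] == "BU").sum()),
        "BB": int((units["klass"] == "BB").sum()),
    }
    counts["B"] = counts["BU"] + counts["BB"]
    return units, counts
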