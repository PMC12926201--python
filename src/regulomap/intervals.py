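"""Interval-set arithmetic on genomic regions.

Region sets are pandas DataFrames with at least the columns
``chrom`` (str), ``start`` (int) and ``end`` (int), 0-based half-open.
All set operations return sets sorted by (chrom, start); ``merge`` and
``complement`` drop any extra columns because the output rows no longer
correspond one-to-one to input rows.

The overlap predicate everywhere is "shares at least one base" unless an
operation documents otherwise.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Genome

REGION_COLS = ["chrom", "start", "end"]


def regions(rows: Iterable[tuple] | None = None, extra_cols: list[str] | None = None) -> pd.DataFrame:
    """Build a region DataFrame from (chrom, start, end, *extra) tuples."""
    cols = REGION_COLS + (extra_cols or [])
    df = pd.DataFrame(list(rows or []), columns=cols)
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "chrom": object})
    return df


def validate(df: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """Check interval invariants; returns the input unchanged."""
    if df.empty:
        return df
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if (df["start"] < 0).any():
        raise ValueError("negative start coordinate")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise KeyError(f"unknown chromosome {chrom!r}")
            if int(sub["end"].max()) > genome.length(chrom):
                raise ValueError(f"interval beyond end of {chrom} (length {genome.length(chrom)})")
    return df


def sort_regions(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge(df: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Touching intervals (end == next start) are merged. Idempotent.
    """
    validate(df, genome)
    if df.empty:
        return regions()
    out = []
    for chrom, sub in sort_regions(df).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return regions(out)


def complement(df: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Disjoint intervals covering exactly the bases NOT in ``df``."""
    merged = merge(df, genome)
    out = []
    by_chrom = dict(tuple(merged.groupby("chrom", sort=False))) if not merged.empty else {}
    for chrom in genome.names:
        length = genome.length(chrom)
        pos = 0
        sub = by_chrom.get(chrom)
        if sub is not None:
            for s, e in zip(sub["start"], sub["end"]):
                if s > pos:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
        if pos < length:
            out.append((chrom, pos, length))
    return regions(out)


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Piecewise intersection of the base sets of ``a`` and ``b``."""
    am, bm = merge(a), merge(b)
    out = []
    b_by_chrom = dict(tuple(bm.groupby("chrom", sort=False))) if not bm.empty else {}
    for chrom, sub in am.groupby("chrom", sort=False):
        other = b_by_chrom.get(chrom)
        if other is None:
            continue
        bs = other["start"].to_numpy(np.int64)
        be = other["end"].to_numpy(np.int64)
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                out.append((chrom, max(s, bs[j]), min(e, be[j])))
    return regions(out)


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bases of ``a`` not covered by ``b`` (a \\ b)."""
    am, bm = merge(a), merge(b)
    out = []
    b_by_chrom = dict(tuple(bm.groupby("chrom", sort=False))) if not bm.empty else {}
    for chrom, sub in am.groupby("chrom", sort=False):
        other = b_by_chrom.get(chrom)
        if other is None:
            out.extend((chrom, s, e) for s, e in zip(sub["start"], sub["end"]))
            continue
        bs = other["start"].to_numpy(np.int64)
        be = other["end"].to_numpy(np.int64)
        for s, e in zip(sub["start"], sub["end"]):
            pos = s
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                if bs[j] > pos:
                    out.append((chrom, pos, bs[j]))
                pos = max(pos, be[j])
            if pos < e:
                out.append((chrom, pos, e))
    return regions(out)


def _ref_arrays(ref: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge(ref)
    return {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in merged.groupby("chrom", sort=False)
    }


def overlaps_any(query: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query row share >= 1 base with ``ref``?"""
    result = np.zeros(len(query), dtype=bool)
    if query.empty or ref.empty:
        return result
    arrays = _ref_arrays(ref)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in arrays:
            continue
        rs, re = arrays[chrom]
        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        # merged ref: starts and ends are both increasing
        idx = np.searchsorted(rs, qe, side="left")
        hit = (idx > 0) & (re[np.maximum(idx - 1, 0)] > qs)
        result[sub.index.to_numpy()] = hit
    return result


def overlap_bases(query: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Number of bases each query row shares with the merged ``ref`` set."""
    result = np.zeros(len(query), dtype=np.int64)
    if query.empty or ref.empty:
        return result
    arrays = _ref_arrays(ref)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in arrays:
            continue
        rs, re = arrays[chrom]
        # cumulative covered bases up to each ref start/end
        cum = np.concatenate([[0], np.cumsum(re - rs)])

        def covered_upto(pos: np.ndarray) -> np.ndarray:
            i = np.maximum(np.searchsorted(rs, pos, side="right") - 1, 0)
            inside = np.clip(pos - rs[i], 0, re[i] - rs[i])
            return np.where(pos >= rs[0], cum[i] + inside, 0)

        qs = sub["start"].to_numpy(np.int64)
        qe = sub["end"].to_numpy(np.int64)
        result[sub.index.to_numpy()] = covered_upto(qe) - covered_upto(qs)
    return result


def total_bases(df: pd.DataFrame) -> int:
    """Bases covered by the merged set."""
    m = merge(df)
    if m.empty:
        return 0
    return int((m["end"] - m["start"]).sum())


def midpoints_in(query: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval's midpoint fall in ``ref``?"""
    if query.empty:
        return np.zeros(0, dtype=bool)
    mid = (query["start"].to_numpy(np.int64) + query["end"].to_numpy(np.int64)) // 2
    points = query.copy()
    points["start"] = mid
    points["end"] = mid + 1
    return overlaps_any(points, ref)


def place_uniform(template: pd.DataFrame, universe: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Place one random interval per template row, same length and chromosome,
    uniformly over all valid start positions inside the merged universe.

    Raises ValueError if a template is longer than every universe piece on
    its chromosome.
    """
    uni = merge(universe)
    pieces = {
        chrom: (sub["start"].to_numpy(np.int64), (sub["end"] - sub["start"]).to_numpy(np.int64))
        for chrom, sub in uni.groupby("chrom", sort=False)
    }
    out = []
    for row in template.itertuples(index=False):
        chrom, length = row.chrom, row.end - row.start
        if chrom not in pieces:
            raise ValueError(f"no universe space on chromosome {chrom!r}")
        starts, plens = pieces[chrom]
        cap = np.maximum(plens - length + 1, 0)
        total = int(cap.sum())
        if total == 0:
            raise ValueError(
                f"template interval {chrom}:{row.start}-{row.end} (len {length}) "
                f"does not fit in any universe piece on {chrom}"
            )
        r = int(rng.integers(0, total))
        cum = np.cumsum(cap)
        j = int(np.searchsorted(cum, r, side="right"))
        offset = r - (cum[j - 1] if j > 0 else 0)
        s = int(starts[j] + offset)
        out.append((chrom, s, s + length))
    return regions(out)
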