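"""Per-base conservation (PhastCons-style) score averaging over interval sets.

The track is sparse: positions without alignment support carry no score
("missing data"). Two averaging modes are provided, mirroring the two ways
missing data can be handled when summarizing element conservation:

* ``aligned-only``: the mean over defined bases only; an interval with no
  defined base has no mean (reported as missing).
* ``missing-as-zero``: the sum of defined scores divided by the full
  interval length, i.e. missing bases count as 0.

For any interval the missing-as-zero mean is <= the aligned-only mean,
because defined scores are non-negative.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv


class ConservationTrack:
    """Sparse per-base scores in [0, 1] stored as scored intervals."""

    def __init__(self, segments: pd.DataFrame):
        """``segments``: region DataFrame with a ``score`` column; regions
        must be disjoint after sorting (overlaps are rejected)."""
        seg = iv.sort_regions(segments)
        if not seg.empty:
            if ((seg["score"] < 0) | (seg["score"] > 1)).any():
                raise ValueError("conservation scores must be in [0, 1]")
            for _, sub in seg.groupby("chrom", sort=False):
                e = sub["end"].to_numpy(np.int64)
                s = sub["start"].to_numpy(np.int64)
                if (s[1:] < e[:-1]).any():
                    raise ValueError("overlapping scored segments")
        self._by_chrom = {
            chrom: (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["score"].to_numpy(float),
            )
            for chrom, sub in seg.groupby("chrom", sort=False)
        }

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
            comment="#", dtype={0: str},
        )
        return cls(df)

    @classmethod
    def from_wiggle(cls, path) -> "ConservationTrack":
        """Read fixedStep wiggle (1-based starts on disk)."""
        rows = []
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    continue
                rows.append((chrom, pos, pos + span, float(line)))
                pos += step
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))

    def interval_sums(self, intervals: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-interval (sum of defined scores, count of defined bases)."""
        sums = np.zeros(len(intervals))
        defined = np.zeros(len(intervals), dtype=np.int64)
        for k, row in enumerate(intervals.itertuples(index=False)):
            if row.chrom not in self._by_chrom:
                continue
            ts, te, sc = self._by_chrom[row.chrom]
            lo = np.searchsorted(te, row.start, side="right")
            hi = np.searchsorted(ts, row.end, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(te[lo:hi], row.end) - np.maximum(ts[lo:hi], row.start)
            sums[k] = float((sc[lo:hi] * ov).sum())
            defined[k] = int(ov.sum())
        return sums, defined


def interval_mean(
    track: ConservationTrack, intervals: pd.DataFrame, missing_as_zero: bool = False
) -> tuple[pd.DataFrame, float | None]:
    """Per-interval conservation means plus the set-level mean.

    The set-level mean is the unweighted mean of per-interval means over
    intervals that have one (element-level summary; in missing-as-zero mode
    every interval has a mean).
    """
    if intervals.empty:
        raise ValueError("empty interval set")
    sums, defined = track.interval_sums(intervals)
    lengths = (intervals["end"] - intervals["start"]).to_numpy(np.int64)
    if missing_as_zero:
        means = sums / lengths
    else:
        means = np.where(defined > 0, sums / np.maximum(defined, 1), np.nan)
    out = intervals[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["mean_score"] = means
    out["defined_bases"] = defined
    valid = means[~np.isnan(means)]
    set_mean = float(valid.mean()) if valid.size else None
    return out, set_mean


def random_matched_regions(
    template: pd.DataFrame, universe: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """One random region per template interval — same length, same
    chromosome, uniform within the universe. Reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    return iv.place_uniform(template, universe, rng)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    iv.sort_regions(df)[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )
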