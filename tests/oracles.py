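"""Brute-force per-base oracles for interval arithmetic, independent of the
implementation under test. Only usable on small genomes (<= a few 100 kb)."""
from __future__ import annotations

import numpy as np
import pandas as pd

from regulomap.genome import Genome
from regulomap.intervals import regions


def mask_of(df: pd.DataFrame, genome: Genome) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.names}
    for row in df.itertuples(index=False):
        masks[row.chrom][row.start:row.end] = True
    return masks


def regions_of(masks: dict[str, np.ndarray]) -> pd.DataFrame:
    out = []
    for chrom in masks:
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return regions(out)


def mask_merge(df: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    return regions_of(mask_of(df, genome))


def mask_complement(df: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    return regions_of({c: ~m for c, m in mask_of(df, genome).items()})


def mask_intersect(a: pd.DataFrame, b: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    ma, mb = mask_of(a, genome), mask_of(b, genome)
    return regions_of({c: ma[c] & mb[c] for c in ma})


def mask_subtract(a: pd.DataFrame, b: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    ma, mb = mask_of(a, genome), mask_of(b, genome)
    return regions_of({c: ma[c] & ~mb[c] for c in ma})


def brute_overlaps_any(query: pd.DataFrame, ref: pd.DataFrame, genome: Genome) -> np.ndarray:
    masks = mask_of(ref, genome)
    return np.array(
        [bool(masks[r.chrom][r.start:r.end].any()) for r in query.itertuples(index=False)]
    )


def random_regions(rng: np.random.Generator, genome: Genome, n: int, max_len: int = 500) -> pd.DataFrame:
    rows = []
    names = genome.names
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome.length(chrom) - length + 1))
        rows.append((chrom, start, start + length))
    return regions(rows)
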