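"""Robust cCRE calling and chromatin-state (E7) summaries.

A "robust cCRE" is an intergenic ATAC-seq peak that overlaps both a UMR and
an H3K9ac peak in the same stage; the element geometry is the ATAC peak.
"weak E7" segments are open-chromatin-state segments lacking all three of
those supports. E7 segments from multiple stages are pooled by union and
their stage dynamics summarized as Venn-cell counts.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .genome import Genome
from . import intervals as iv

INTERGENIC_MODES = ("midpoint", "any", "contained")


def _is_intergenic(peaks: pd.DataFrame, intergenic: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "midpoint":
        return iv.midpoints_in(peaks, intergenic)
    if mode == "any":
        return iv.overlaps_any(peaks, intergenic)
    if mode == "contained":
        return iv.overlap_bases(peaks, intergenic) == (peaks["end"] - peaks["start"]).to_numpy()
    raise ValueError(f"intergenic_mode must be one of {INTERGENIC_MODES}")


def call_robust_ccres(
    atac: pd.DataFrame,
    umrs: pd.DataFrame,
    k9ac: pd.DataFrame,
    intergenic: pd.DataFrame,
    e7: pd.DataFrame | None = None,
    intergenic_mode: str = "midpoint",
) -> pd.DataFrame:
    """Intersect intergenic ATAC peaks with UMRs and H3K9ac peaks.

    Returns the qualifying ATAC peaks with boolean flag columns
    ``overlaps_umr``, ``overlaps_k9ac`` and (when ``e7`` is given)
    ``overlaps_e7``.
    """
    if atac.empty:
        cols = ["overlaps_umr", "overlaps_k9ac"] + (["overlaps_e7"] if e7 is not None else [])
        return iv.regions(extra_cols=cols)
    keep = _is_intergenic(atac, intergenic, intergenic_mode)
    candidates = atac.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    candidates["overlaps_umr"] = iv.overlaps_any(candidates, umrs)
    candidates["overlaps_k9ac"] = iv.overlaps_any(candidates, k9ac)
    robust = candidates[candidates["overlaps_umr"] & candidates["overlaps_k9ac"]].reset_index(drop=True)
    if e7 is not None:
        robust["overlaps_e7"] = iv.overlaps_any(robust, e7)
    return robust


def weak_e7(
    e7: pd.DataFrame, atac: pd.DataFrame, umrs: pd.DataFrame, k9ac: pd.DataFrame
) -> pd.DataFrame:
    """E7 segments with zero overlap against UMRs, ATAC and H3K9ac peaks."""
    if e7.empty:
        return iv.regions()
    hit = (
        iv.overlaps_any(e7, atac) | iv.overlaps_any(e7, umrs) | iv.overlaps_any(e7, k9ac)
    )
    return e7.loc[~hit, ["chrom", "start", "end"]].reset_index(drop=True)


def pool_and_venn(e7_by_stage: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool stage E7 sets by merged union and tabulate stage membership.

    Returns (pooled elements with one boolean column per stage,
    Venn table with columns stages/count/fraction, one row per non-empty
    membership combination).
    """
    stages = list(e7_by_stage)
    if len(stages) < 2:
        raise ValueError("pooling needs at least 2 stages")
    pooled = iv.merge(pd.concat([e7_by_stage[s] for s in stages], ignore_index=True))
    for stage in stages:
        pooled[stage] = iv.overlaps_any(pooled, e7_by_stage[stage])
    total = len(pooled)
    rows = []
    for r in range(1, len(stages) + 1):
        for combo in combinations(stages, r):
            in_combo = np.ones(total, dtype=bool)
            for stage in stages:
                flag = pooled[stage].to_numpy()
                in_combo &= flag if stage in combo else ~flag
            count = int(in_combo.sum())
            rows.append(("+".join(combo), count, count / total if total else 0.0))
    venn = pd.DataFrame(rows, columns=["stages", "count", "fraction"])
    assert venn["count"].sum() == total, "Venn cells must sum to pooled elements"
    return pooled, venn


def coverage_fraction(elements: pd.DataFrame, genome: Genome) -> float:
    """Percent of the genome covered by the merged element set."""
    return 100.0 * iv.total_bases(elements) / genome.size


def read_state_segments(path) -> pd.DataFrame:
    """Read a ChromHMM-style segmentation BED (4th column = state label)."""
    from .io import read_bed

    df = read_bed(path, ["state"])
    if df["state"].isna().any():
        raise ValueError(f"{path}: segmentation BED needs a state column")
    return df


def state_subset(segments: pd.DataFrame, state: str) -> pd.DataFrame:
    return segments.loc[segments["state"] == state, ["chrom", "start", "end"]].reset_index(drop=True)
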