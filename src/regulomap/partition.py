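"""Genic/intergenic "coding-potential" partition of the genome.

The genic compartment is the union of
  * every annotated gene (high and low confidence), extended upstream of
    its TSS only, strand-aware, by ``tss_ext`` bp, and
  * every externally derived transcribed region (RNA-seq signal with
    TPM > 1) and lncRNA region, extended by ``transcribed_ext`` bp in both
    directions.
The intergenic compartment is its complement; the two tile the genome.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from . import intervals as iv


@dataclass(frozen=True)
class GenomePartition:
    genic: pd.DataFrame
    intergenic: pd.DataFrame

    def check_tiling(self, genome: Genome) -> None:
        """Assert genic + intergenic tile each chromosome exactly."""
        for chrom in genome.names:
            g = iv.total_bases(self.genic[self.genic["chrom"] == chrom])
            i = iv.total_bases(self.intergenic[self.intergenic["chrom"] == chrom])
            if g + i != genome.length(chrom):
                raise AssertionError(
                    f"partition does not tile {chrom}: {g} genic + {i} intergenic "
                    f"!= {genome.length(chrom)}"
                )


def extend_upstream(genes: pd.DataFrame, genome: Genome, ext: int) -> pd.DataFrame:
    """Extend each gene by ``ext`` bp upstream of its TSS on its own strand,
    clipped to chromosome bounds."""
    if genes.empty:
        return iv.regions()
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("gene with missing strand")
    plus = (genes["strand"] == "+").to_numpy()
    starts = genes["start"].to_numpy(np.int64)
    ends = genes["end"].to_numpy(np.int64)
    new_starts = np.where(plus, np.maximum(starts - ext, 0), starts)
    lengths = genes["chrom"].map(genome.lengths).to_numpy(np.int64)
    new_ends = np.where(plus, ends, np.minimum(ends + ext, lengths))
    out = genes[["chrom"]].copy()
    out["start"] = new_starts
    out["end"] = new_ends
    return out


def extend_both(df: pd.DataFrame, genome: Genome, ext: int) -> pd.DataFrame:
    if df.empty:
        return iv.regions()
    out = df[["chrom"]].copy()
    out["start"] = np.maximum(df["start"].to_numpy(np.int64) - ext, 0)
    lengths = df["chrom"].map(genome.lengths).to_numpy(np.int64)
    out["end"] = np.minimum(df["end"].to_numpy(np.int64) + ext, lengths)
    return out


def build_partition(
    genes: pd.DataFrame,
    transcribed: pd.DataFrame,
    lncrna: pd.DataFrame,
    genome: Genome,
    tss_ext: int = 500,
    transcribed_ext: int = 500,
) -> GenomePartition:
    """Build the genic/intergenic partition.

    ``transcribed`` must already be thresholded (TPM > 1 regions); lncRNA
    regions are treated like transcribed regions.
    """
    pieces = [
        extend_upstream(genes, genome, tss_ext),
        extend_both(transcribed, genome, transcribed_ext),
        extend_both(lncrna, genome, transcribed_ext),
    ]
    genic = iv.merge(pd.concat(pieces, ignore_index=True), genome)
    intergenic = iv.complement(genic, genome)
    return GenomePartition(genic=genic, intergenic=intergenic)
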