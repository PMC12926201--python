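"""CAGE cluster pruning, bidirectional merging and U/BU/BB classification."""
import numpy as np
import pandas as pd
import pytest

from regulomap import cage
from regulomap import intervals as iv
from regulomap.io import annotate_gene_ends


def clusters(rows):
    """rows: (chrom, start, end, strand, dominant_tss, tpm, n_ctss)"""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "dominant_tss", "tpm", "n_ctss"]
    )
    df["iqw"] = 25
    df["cluster_id"] = [f"c{i}" for i in range(len(df))]
    return df


def genes(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "confidence"])
    return annotate_gene_ends(df)


class TestPruneIntergenic:
    GENES = genes([("c1", 10_000, 12_000, "+", "g1", "high")])

    def prune(self, cl, **kw):
        return cage.prune_intergenic(cl, self.GENES, iv.regions(), iv.regions(), **kw)

    def test_cluster_400bp_from_gene_removed(self):
        cl = clusters([("c1", 9_500, 9_600, "+", 9_550, 1.0, 3)])  # gap 400
        assert self.prune(cl).empty

    def test_cluster_501bp_away_kept(self):
        cl = clusters([("c1", 9_400, 9_499, "+", 9_450, 1.0, 3)])  # gap 501
        assert len(self.prune(cl)) == 1

    def test_cluster_exactly_500bp_away_removed(self):
        cl = clusters([("c1", 9_400, 9_500, "+", 9_450, 1.0, 3)])  # gap 500
        assert self.prune(cl).empty

    def test_rna_signal_margin_applies(self):
        cl = clusters([("c1", 50_000, 50_100, "+", 50_050, 1.0, 3)])
        rna = iv.regions([("c1", 50_200, 50_400)])
        pruned = cage.prune_intergenic(cl, self.GENES, rna, iv.regions())
        assert pruned.empty

    def test_lncrna_overlap_removed(self):
        cl = clusters([("c1", 50_000, 50_100, "+", 50_050, 1.0, 3)])
        lnc = iv.regions([("c1", 50_050, 50_250)])
        assert cage.prune_intergenic(cl, self.GENES, iv.regions(), lnc).empty

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(150):
            s = int(rng.integers(0, 99_000))
            rows.append(("c1", s, s + 80, "+", s + 40, 1.0, 3))
        cl = clusters(rows)
        pruned = self.prune(cl)
        kept_ids = set(pruned["cluster_id"])
        for row in cl.itertuples(index=False):
            gaps = []
            for g in self.GENES.itertuples(index=False):
                if row.end <= g.start:
                    gaps.append(g.start - row.end)
                elif g.end <= row.start:
                    gaps.append(row.start - g.end)
                else:
                    gaps.append(0)
            assert (min(gaps) > 500) == (row.cluster_id in kept_ids)


class TestMergeBidirectional:
    def test_divergent_pair_merges_between_dominant_tss(self):
        cl = clusters(
            [
                ("c1", 9_950, 10_050, "-", 10_000, 2.0, 4),
                ("c1", 10_350, 10_450, "+", 10_400, 1.0, 4),
            ]
        )
        units = cage.merge_bidirectional(cl)
        assert len(units) == 1
        u = units.iloc[0]
        assert (u["start"], u["end"], u["klass"]) == (10_000, 10_401, "B")
        assert (u["plus_tpm"], u["minus_tpm"]) == (1.0, 2.0)

    def test_singleton_partner_blocks_merge_of_two_singletons(self):
        cl = clusters(
            [
                ("c1", 9_950, 10_050, "-", 10_000, 2.0, 1),
                ("c1", 10_350, 10_450, "+", 10_400, 1.0, 1),
            ]
        )
        units = cage.merge_bidirectional(cl)
        assert list(units["klass"]) == ["U", "U"]

    def test_one_eligible_partner_suffices(self):
        # the singleton may nucleate a merge when its antisense partner passes
        cl = clusters(
            [
                ("c1", 9_950, 10_050, "-", 10_000, 0.05, 1),
                ("c1", 10_350, 10_450, "+", 10_400, 1.0, 4),
            ]
        )
        units = cage.merge_bidirectional(cl)
        assert list(units["klass"]) == ["B"]

    def test_distance_beyond_max_keeps_separate(self):
        cl = clusters(
            [
                ("c1", 9_950, 10_050, "-", 10_000, 2.0, 4),
                ("c1", 10_550, 10_700, "+", 10_601, 1.0, 4),
            ]
        )
        assert list(cage.merge_bidirectional(cl, max_dist=600)["klass"]) == ["U", "U"]

    def test_distance_exactly_max_merges(self):
        cl = clusters(
            [
                ("c1", 9_950, 10_050, "-", 10_000, 2.0, 4),
                ("c1", 10_550, 10_650, "+", 10_600, 1.0, 4),
            ]
        )
        assert list(cage.merge_bidirectional(cl, max_dist=600)["klass"]) == ["B"]

    def test_chain_forms_single_component(self):
        cl = clusters(
            [
                ("c1", 9_900, 10_000, "+", 9_950, 1.0, 4),
                ("c1", 10_300, 10_400, "-", 10_350, 1.0, 4),
                ("c1", 10_700, 10_800, "+", 10_750, 1.0, 4),
            ]
        )
        units = cage.merge_bidirectional(cl)
        assert len(units) == 1
        assert len(units.iloc[0]["members"].split(",")) == 3
        # span delimited by minus dTSS .. max plus dTSS is empty here
        # (minus is between the plus clusters): falls back to coordinate span
        assert units.iloc[0]["start"] == 9_950 or units.iloc[0]["start"] == 10_350

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            d = int(rng.integers(0, 50_000))
            rows.append(("c1", d, d + 100, "+" if rng.random() < 0.5 else "-", d + 50,
                         float(rng.uniform(0.05, 3)), int(rng.integers(1, 6))))
        cl = clusters(rows)
        a = cage.merge_bidirectional(cl)
        b = cage.merge_bidirectional(cl.sample(frac=1, random_state=5).reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_unit_count_equals_component_count(self):
        cl = clusters(
            [
                ("c1", 1_000, 1_100, "+", 1_050, 1.0, 4),
                ("c1", 1_200, 1_300, "-", 1_250, 1.0, 4),
                ("c1", 30_000, 30_100, "+", 30_050, 1.0, 4),
            ]
        )
        units = cage.merge_bidirectional(cl)
        assert len(units) == 2  # one merged pair + one unlinked


class TestClassify:
    def unit(self, plus, minus):
        return pd.DataFrame(
            [("c1", 0, 100, "B", plus, minus, np.nan, "a,b")], columns=cage.UNIT_COLS
        )

    def test_fourfold_imbalance_is_bu(self):
        units, counts = cage.classify(self.unit(4.0, 1.0))
        assert units.iloc[0]["klass"] == "BU"
        assert units.iloc[0]["log2fc"] == pytest.approx(2.0)

    def test_mild_imbalance_is_bb(self):
        units, _ = cage.classify(self.unit(2.0, 1.2))
        assert units.iloc[0]["klass"] == "BB"
        assert units.iloc[0]["log2fc"] == pytest.approx(np.log2(2.0 / 1.2))

    def test_boundary_log2fc_of_one_is_balanced(self):
        units, _ = cage.classify(self.unit(2.0, 1.0))
        assert units.iloc[0]["klass"] == "BB"
        units, _ = cage.classify(self.unit(1.0, 2.0))
        assert units.iloc[0]["klass"] == "BB"

    def test_zero_strand_tpm_is_bu_with_infinite_ratio(self):
        units, _ = cage.classify(self.unit(2.0, 0.0))
        assert units.iloc[0]["klass"] == "BU"
        assert np.isinf(units.iloc[0]["log2fc"])

    def test_wider_bound_never_shrinks_bb(self):
        rng = np.random.default_rng(9)
        units = pd.concat(
            [self.unit(float(rng.uniform(0.1, 4)), float(rng.uniform(0.1, 4))) for _ in range(50)],
            ignore_index=True,
        )
        _, narrow = cage.classify(units, balance_bound=1.0)
        _, wide = cage.classify(units, balance_bound=2.0)
        assert wide["BB"] >= narrow["BB"]

    def test_counts_sum(self):
        units = pd.DataFrame(
            [
                ("c1", 0, 10, "U", 1.0, 0.0, np.nan, "a"),
                ("c1", 20, 40, "B", 1.0, 5.0, np.nan, "b,c"),
            ],
            columns=cage.UNIT_COLS,
        )
        _, counts = cage.classify(units)
        assert counts["U"] + counts["B"] == len(units)


def test_cluster_table_round_trip(tmp_path):
    cl = clusters([("c1", 10, 110, "+", 50, 1.5, 3)])
    p = tmp_path / "clusters.tsv"
    cage.write_clusters(cl, p)
    back = cage.read_clusters(p)
    pd.testing.assert_frame_equal(back[cage.CLUSTER_COLS], cl[cage.CLUSTER_COLS])


def test_dominant_tss_outside_interval_rejected(tmp_path):
    cl = clusters([("c1", 10, 110, "+", 200, 1.5, 3)])
    p = tmp_path / "clusters.tsv"
    cage.write_clusters(cl, p)
    with pytest.raises(ValueError):
        cage.read_clusters(p)
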