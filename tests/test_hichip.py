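"""Hierarchical loop-anchor annotation and interaction summaries."""
import itertools

import numpy as np
import pandas as pd
import pytest

from regulomap import hichip
from regulomap import intervals as iv
from regulomap.io import annotate_gene_ends


def loops(rows):
    """rows: (chrom, start1, start2, qvalue) at 5-kb bins"""
    return pd.DataFrame(
        [(c, s1, s1 + 5000, s2, s2 + 5000, q) for c, s1, s2, q in rows],
        columns=["chrom", "start1", "end1", "start2", "end2", "qvalue"],
    )


def track(rows):
    return iv.regions(rows)


def genes(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "confidence"])
    return annotate_gene_ends(df)


class TestAnnotate:
    def test_priority_order_wins(self):
        lib = hichip.FeatureLibrary(
            {"active_promoter": track([("c1", 0, 1000)]), "E7": track([("c1", 0, 1000)])}
        )
        labels = lib.annotate(track([("c1", 500, 600)]))
        assert labels[0] == "active_promoter"

    def test_intron_beats_te(self):
        lib = hichip.FeatureLibrary(
            {"TE": track([("c1", 0, 1000)]), "intron": track([("c1", 0, 1000)])}
        )
        assert lib.annotate(track([("c1", 0, 10)]))[0] == "intron"

    def test_no_overlap_is_other(self):
        lib = hichip.FeatureLibrary({"E7": track([("c1", 0, 100)])})
        assert lib.annotate(track([("c1", 5000, 5100)]))[0] == "other"

    def test_all_feature_subsets_resolve_to_highest_priority(self):
        """Exhaustive 2^7 overlap patterns against the full library."""
        tracks = {
            label: track([("c1", 1000 * (i + 1), 1000 * (i + 1) + 100)])
            for i, label in enumerate(hichip.PRIORITY)
        }
        lib = hichip.FeatureLibrary(tracks)
        for bits in itertools.product([0, 1], repeat=len(hichip.PRIORITY)):
            # an anchor overlapping exactly the selected features
            pieces = [
                (1000 * (i + 1), 1000 * (i + 1) + 100)
                for i, b in enumerate(bits)
                if b
            ]
            if pieces:
                anchor = track([("c1", pieces[0][0], pieces[-1][1])])
                # restrict library to selected features so the long anchor
                # does not touch unselected ones
                sub = hichip.FeatureLibrary(
                    {l: tracks[l] for i, l in enumerate(hichip.PRIORITY) if bits[i]}
                )
                expected = next(l for i, l in enumerate(hichip.PRIORITY) if bits[i])
                assert sub.annotate(anchor)[0] == expected
            else:
                assert lib.annotate(track([("c1", 50_000, 50_100)]))[0] == "other"


class TestComposition:
    lib = hichip.FeatureLibrary(
        {
            "active_promoter": track([("c1", 0, 5000), ("c1", 10_000, 15_000)]),
            "E7": track([("c1", 50_000, 55_000)]),
        }
    )

    def test_known_mixture_percentages(self):
        # 4 of 10 loops promoter-promoter -> 40% (dedup is snap_to_grid's job)
        rows = [("c1", 0, 10_000, 0.01)] * 4 + [("c1", 0, 50_000, 0.01)] * 6
        comp = hichip.class_composition(loops(rows), self.lib)
        pp = comp.set_index("klass")["percent"].to_dict()
        assert pp["active_promoter|active_promoter"] == pytest.approx(40.0)
        assert pp["E7|active_promoter"] == pytest.approx(60.0)

    def test_single_loop_is_100_percent(self):
        comp = hichip.class_composition(loops([("c1", 0, 10_000, 0.01)]), self.lib)
        assert comp["percent"].tolist() == [100.0]

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(2)
        rows = [
            ("c1", int(rng.integers(0, 5)) * 5000, int(rng.integers(5, 12)) * 5000, 0.01)
            for _ in range(30)
        ]
        comp = hichip.class_composition(loops(rows), self.lib)
        assert comp["percent"].sum() == pytest.approx(100.0)

    def test_centric_restriction(self):
        rows = [("c1", 0, 50_000, 0.01), ("c1", 30_000, 45_000, 0.01)]
        comp = hichip.class_composition(loops(rows), self.lib, centric="active_promoter")
        assert comp["klass"].tolist() == ["E7|active_promoter"]

    def test_centric_with_no_matching_loops_is_empty(self):
        rows = [("c1", 30_000, 45_000, 0.01)]
        comp = hichip.class_composition(loops(rows), self.lib, centric="active_promoter")
        assert comp.empty

    def test_fdr_filter(self):
        rows = [("c1", 0, 10_000, 0.2)]
        comp = hichip.class_composition(loops(rows), self.lib, fdr=0.05)
        assert comp.empty
        with pytest.raises(ValueError):
            hichip.class_composition(loops(rows), self.lib, fdr=0.0)


class TestSnap:
    def test_unbinned_inputs_are_snapped_and_oriented(self):
        df = pd.DataFrame(
            [("c1", 12_345, 12_400, 3_000, 3_050, 0.01)],
            columns=["chrom", "start1", "end1", "start2", "end2", "qvalue"],
        )
        out = hichip.snap_to_grid(df, 5000)
        assert (out.iloc[0]["start1"], out.iloc[0]["start2"]) == (0, 10_000)

    def test_duplicates_keep_smallest_q(self):
        df = loops([("c1", 0, 10_000, 0.04), ("c1", 0, 10_000, 0.001)])
        out = hichip.snap_to_grid(df, 5000)
        assert len(out) == 1
        assert out.iloc[0]["qvalue"] == 0.001


class TestSpannedGenes:
    def test_adjacent_bins_span_nothing(self):
        assert hichip.spanned_genes(
            loops([("c1", 0, 5_000, 0.01)]), genes([("c1", 1000, 2000, "+", "g", "high")])
        )[0] == 0

    def test_straddling_gene_excluded(self):
        gs = genes(
            [
                ("c1", 6_000, 7_000, "+", "a", "high"),
                ("c1", 8_000, 9_000, "+", "b", "high"),
                ("c1", 12_000, 13_000, "+", "c", "high"),
                ("c1", 18_000, 22_000, "+", "d", "high"),  # straddles anchor2
            ]
        )
        assert hichip.spanned_genes(loops([("c1", 0, 20_000, 0.01)]), gs)[0] == 3

    def test_gene_abutting_anchor_end_counts(self):
        gs = genes([("c1", 5_000, 6_000, "+", "g", "high")])
        assert hichip.spanned_genes(loops([("c1", 0, 20_000, 0.01)]), gs)[0] == 1


class TestPerPromoter:
    promoters = pd.DataFrame(
        {"chrom": ["c1", "c1"], "start": [0, 50_000], "end": [5_000, 55_000], "gene_id": ["a", "b"]}
    )

    def test_degree_counts_incident_loops(self):
        ll = loops(
            [("c1", 0, 10_000, 0.01), ("c1", 0, 20_000, 0.01), ("c1", 0, 30_000, 0.01)]
        )
        per, hist = hichip.interactions_per_promoter(ll, self.promoters)
        assert per.set_index("gene_id")["degree"].to_dict() == {"a": 3, "b": 0}
        assert hist.set_index("degree")["n_promoters"].to_dict() == {0: 1, 3: 1}

    def test_both_anchor_hit_counted_once(self):
        ll = loops([("c1", 0, 2_500, 0.01)])  # both anchors within promoter a (snapped bins)
        ll.loc[0, ["start1", "end1", "start2", "end2"]] = [0, 2500, 2500, 5000]
        per, _ = hichip.interactions_per_promoter(ll, self.promoters)
        assert per.set_index("gene_id")["degree"]["a"] == 1


class TestSelfLoops:
    def test_promoter_terminator_pair_detected(self):
        gs = genes([("c1", 2_000, 13_000, "+", "g", "high")])  # TSS 2000, TES 12999
        ll = loops([("c1", 0, 10_000, 0.01)])
        result = hichip.self_loops(ll, gs, 5000)
        assert result["gene_id"].tolist() == ["g"]

    def test_same_bin_loop_is_not_self_loop(self):
        gs = genes([("c1", 1_000, 3_000, "+", "g", "high")])
        ll = loops([("c1", 0, 0, 0.01)])
        assert hichip.self_loops(ll, gs, 5000).empty

    def test_matches_brute_force_bin_matching(self):
        rng = np.random.default_rng(6)
        gs = genes(
            [
                ("c1", int(s), int(s) + 11_000, "+", f"g{i}", "high")
                for i, s in enumerate(rng.integers(0, 80_000, size=8))
            ]
        )
        ll = loops(
            [
                ("c1", int(rng.integers(0, 10)) * 5000, int(rng.integers(10, 19)) * 5000, 0.01)
                for _ in range(20)
            ]
        )
        result = hichip.self_loops(ll, gs, 5000)
        expected = 0
        for g in gs.itertuples(index=False):
            prom = (max(g.tss - 2500, 0), g.tss + 2500)
            term = (max(g.tes - 2500, 0), g.tes + 2500)
            for row in ll.itertuples(index=False):
                if row.start1 == row.start2:
                    continue
                a1 = (row.start1, row.end1)
                a2 = (row.start2, row.end2)
                def hit(a, w):
                    return a[0] < w[1] and a[1] > w[0]
                if (hit(a1, prom) and hit(a2, term)) or (hit(a1, term) and hit(a2, prom)):
                    expected += 1
        assert len(result) == expected


class TestBivalent:
    def test_identical_loop_is_shared(self):
        a = loops([("c1", 0, 10_000, 0.01)])
        b = loops([("c1", 0, 10_000, 0.02)])
        assert len(hichip.bivalent_interactions(a, b, 5000)) == 1

    def test_single_shared_anchor_not_shared(self):
        a = loops([("c1", 0, 10_000, 0.01)])
        b = loops([("c1", 0, 20_000, 0.01)])
        assert hichip.bivalent_interactions(a, b, 5000).empty

    def test_symmetric(self):
        rng = np.random.default_rng(17)
        mk = lambda: loops(
            [
                ("c1", int(rng.integers(0, 8)) * 5000, int(rng.integers(8, 16)) * 5000, 0.01)
                for _ in range(25)
            ]
        )
        a, b = mk(), mk()
        ab = hichip.bivalent_interactions(a, b, 5000)
        ba = hichip.bivalent_interactions(b, a, 5000)
        key = lambda df: sorted(zip(df["chrom"], df["start1"], df["start2"]))
        assert key(ab) == key(ba)

    def test_resolution_mismatch_rejected(self):
        a = loops([("c1", 0, 10_000, 0.01)])
        b = a.copy()
        b["end1"] = b["start1"] + 10_000
        with pytest.raises(ValueError):
            hichip.bivalent_interactions(a, b, 5000)


class TestDistances:
    def test_single_loop_midpoint_distance(self):
        d = hichip.distance_stats(loops([("c1", 0, 10_000, 0.01)]))
        assert d["mean"] == 10_000

    def test_two_loops(self):
        d = hichip.distance_stats(loops([("c1", 0, 10_000, 0.01), ("c1", 0, 30_000, 0.01)]))
        assert (d["mean"], d["median"]) == (20_000, 20_000)

    def test_empty_is_missing(self):
        d = hichip.distance_stats(loops([]))
        assert d == {"mean": None, "median": None}

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(23)
        rows = [
            ("c1", int(rng.integers(0, 100)) * 5000, int(rng.integers(100, 400)) * 5000, 0.01)
            for _ in range(100)
        ]
        ll = loops(rows)
        d = hichip.distance_stats(ll)
        direct = [abs((s2 + s2 + 5000) // 2 - (s1 + s1 + 5000) // 2) for _, s1, s2, _ in rows]
        assert d["mean"] == pytest.approx(np.mean(direct))
        assert d["median"] == pytest.approx(np.median(direct))


def test_read_bedpe_rejects_interchromosomal(tmp_path):
    p = tmp_path / "l.bedpe"
    p.write_text("chr1\ts1\te1\tchr2\ts2\te2\tQ-Value_Bias\nc1\t0\t5000\tc2\t0\t5000\t0.01\n")
    with pytest.raises(ValueError):
        hichip.read_bedpe(p)
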