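"""End-to-end orchestration: partition -> UMRs -> cCREs -> CAGE -> HiChIP ->
statistics -> conservation, from a flat config mapping.

The run is a pure function of inputs plus config: the summary report is a
sorted-key JSON document with no timestamps, so re-running the same config
yields a byte-identical report.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .genome import Genome
from . import intervals as iv
from . import io as rio
from . import methylome, ccre, cage, hichip, stats, conservation
from .partition import build_partition

log = logging.getLogger("regulomap")

DEFAULTS = {
    "tss_ext": 500,
    "transcribed_ext": 500,
    "window": 300,
    "max_meth": 0.01,
    "min_cov": 5,
    "cage_max_dist": 600,
    "partner_min_tpm": 0.1,
    "gene_margin": 500,
    "rna_margin": 500,
    "resolution": 5000,
    "fdr": 0.05,
    "max_loop_dist": 2e6,
    "n_perm": 500,
    "seed": 0,
}

REQUIRED_INPUTS = [
    "genome", "genes", "transcribed", "lncrna", "atac", "k9ac", "k4me3",
    "k27me3", "states", "cx_report", "cage_clusters", "loops_k4",
    "loops_k27", "te", "phastcons", "expression_clusters", "tf_genes",
]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_all(config: dict, outdir) -> dict:
    """Execute the full stage chain; returns the summary dict and writes
    ``summary.json`` plus per-stage output files under ``outdir``.

    ``config["inputs"]`` maps input names to paths (``states`` maps stage
    name -> segmentation BED; the first stage is the primary one);
    remaining keys override :data:`DEFAULTS`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k != "inputs"}}
    inputs = dict(config["inputs"])
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise FileNotFoundError(f"config missing inputs: {missing}")
    paths = {
        k: v for k, v in inputs.items() if k != "states"
    }
    for name, p in {**paths, **dict(inputs["states"])}.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")
    summary: dict = {"parameters": {k: params[k] for k in sorted(params)}}

    genome = Genome.from_chrom_sizes(inputs["genome"])
    genes = rio.read_gff3_genes(inputs["genes"])
    transcribed = rio.read_bed(inputs["transcribed"])
    lncrna = rio.read_bed(inputs["lncrna"])

    # stage 1: coding-potential partition
    part = build_partition(
        genes, transcribed, lncrna, genome,
        tss_ext=params["tss_ext"], transcribed_ext=params["transcribed_ext"],
    )
    part.check_tiling(genome)
    rio.write_bed(part.genic, outdir / "genic.bed", cols=[])
    rio.write_bed(part.intergenic, outdir / "intergenic.bed", cols=[])
    summary["partition"] = {
        "n_genes": len(genes),
        "genic_bases": iv.total_bases(part.genic),
        "intergenic_bases": iv.total_bases(part.intergenic),
    }
    log.info("partition: %d genes, %d genic bp", len(genes), summary["partition"]["genic_bases"])

    # stage 2: methylome
    cx = methylome.read_cytosine_report(inputs["cx_report"])
    levels = methylome.global_methylation(cx, min_cov=params["min_cov"])
    umrs = methylome.call_umrs(
        cx, part.intergenic, window=params["window"],
        max_meth=params["max_meth"], min_cov=params["min_cov"],
    )
    rio.write_bed(umrs, outdir / "umrs.bed")
    summary["methylome"] = {
        "global_levels_pct": {k: (round(v, 4) if v is not None else None) for k, v in levels.items()},
        "n_umrs": len(umrs),
        "umr_bases": iv.total_bases(umrs),
    }
    log.info("methylome: %d UMRs", len(umrs))

    # stage 3: robust cCREs, weak E7, stage dynamics
    atac = rio.read_bed(inputs["atac"])
    k9ac = rio.read_bed(inputs["k9ac"])
    stage_states = {s: ccre.read_state_segments(p) for s, p in inputs["states"].items()}
    primary = next(iter(stage_states))
    e7 = ccre.state_subset(stage_states[primary], "E7")
    e4 = ccre.state_subset(stage_states[primary], "E4")
    robust = ccre.call_robust_ccres(atac, umrs, k9ac, part.intergenic, e7=e7)
    weak = ccre.weak_e7(e7, atac, umrs, k9ac)
    rio.write_bed(robust, outdir / "robust_ccres.bed")
    rio.write_bed(weak, outdir / "weak_e7.bed", cols=[])
    e7_by_stage = {s: ccre.state_subset(seg, "E7") for s, seg in stage_states.items()}
    pooled, venn = ccre.pool_and_venn(e7_by_stage)
    rio.write_tsv(venn, outdir / "e7_venn.tsv")
    all_stage_cells = venn.loc[venn["stages"] == "+".join(e7_by_stage), "fraction"]
    summary["ccre"] = {
        "n_robust": len(robust),
        "n_weak_e7": len(weak),
        "n_pooled_e7": len(pooled),
        "pct_common_all_stages": round(100.0 * float(all_stage_cells.iloc[0]), 4) if len(all_stage_cells) else None,
        "e7_genome_coverage_pct": round(ccre.coverage_fraction(e7, genome), 4),
    }
    log.info("ccre: %d robust cCREs, %d weak E7", len(robust), len(weak))

    # stage 4: CAGE directionality
    clusters = cage.read_clusters(inputs["cage_clusters"])
    pruned = cage.prune_intergenic(
        clusters, genes, transcribed, lncrna,
        gene_margin=params["gene_margin"], rna_margin=params["rna_margin"],
    )
    units = cage.merge_bidirectional(
        pruned, max_dist=params["cage_max_dist"], partner_min_tpm=params["partner_min_tpm"]
    )
    units, class_counts = cage.classify(units)
    rio.write_tsv(units, outdir / "cage_units.tsv")
    summary["cage"] = {
        "n_clusters_input": len(clusters),
        "n_clusters_intergenic": len(pruned),
        "n_units": len(units),
        "class_counts": class_counts,
    }
    log.info("cage: %d units (%s)", len(units), class_counts)

    # stage 5: HiChIP annotation
    res = int(params["resolution"])
    k4me3 = rio.read_bed(inputs["k4me3"])
    k27me3 = rio.read_bed(inputs["k27me3"])
    te = rio.read_bed(inputs["te"])
    prom_tracks = hichip.promoter_terminator_tracks(genes, res, active_marks=k4me3, silent_marks=k27me3)
    library = hichip.FeatureLibrary({**prom_tracks, "E7": e7, "E4": e4, "TE": te})
    loops_k4 = hichip.snap_to_grid(hichip.read_bedpe(inputs["loops_k4"]), res)
    loops_k27 = hichip.snap_to_grid(hichip.read_bedpe(inputs["loops_k27"]), res)
    sig_k4 = hichip.filter_loops(loops_k4, fdr=params["fdr"], max_dist=params["max_loop_dist"])
    annotated = hichip.annotate_loops(sig_k4, library)
    annotated["n_spanned_genes"] = hichip.spanned_genes(annotated, genes)
    rio.write_tsv(annotated, outdir / "loops_k4_annotated.tsv")
    composition = hichip.class_composition(
        loops_k4, library, fdr=params["fdr"], max_dist=params["max_loop_dist"]
    )
    rio.write_tsv(composition, outdir / "class_composition.tsv")
    promoters = pd.concat(
        [prom_tracks["active_promoter"], prom_tracks["silent_promoter"]], ignore_index=True
    )
    per_prom, degree_hist = hichip.interactions_per_promoter(sig_k4, promoters)
    rio.write_tsv(degree_hist, outdir / "promoter_degree_hist.tsv")
    selfl = hichip.self_loops(sig_k4, genes, res)
    bivalent = hichip.bivalent_interactions(loops_k4, loops_k27, res)
    dstats = hichip.distance_stats(sig_k4)
    summary["hichip"] = {
        "n_significant_k4": len(sig_k4),
        "class_composition_pct": {
            row.klass: round(float(row.percent), 4) for row in composition.itertuples(index=False)
        },
        "mean_distance_bp": round(dstats["mean"], 2) if dstats["mean"] is not None else None,
        "median_distance_bp": dstats["median"],
        "max_promoter_degree": int(per_prom["degree"].max()) if len(per_prom) else 0,
        "n_self_loops": len(selfl),
        "n_bivalent": len(bivalent),
        "mean_spanned_genes": round(float(annotated["n_spanned_genes"].mean()), 4) if len(annotated) else None,
    }
    log.info("hichip: %d significant loops, %d bivalent", len(sig_k4), len(bivalent))

    # stage 6: enrichment and concordance statistics
    seed = int(params["seed"])
    overlap = stats.permutation_overlap_test(
        robust[["chrom", "start", "end"]], e7, part.intergenic,
        n_perm=int(params["n_perm"]), seed=seed,
    )
    clusters_map = {
        str(r.gene_id): int(r.cluster)
        for r in rio.read_tsv(inputs["expression_clusters"]).itertuples(index=False)
    }
    pairs = _promoter_pairs(annotated, genes, res)
    cocluster = (
        stats.cocluster_chisq(pairs, clusters_map) if len(pairs) >= 2 else None
    )
    tf_set = {line.strip() for line in open(inputs["tf_genes"]) if line.strip()}
    e7_genes = _e7_interacting_genes(annotated, genes, res)
    universe = set(genes["gene_id"])
    hyper = stats.geneset_hypergeom(e7_genes, tf_set & universe, universe)
    summary["stats"] = {
        "ccre_vs_e7_overlap": {
            "observed": overlap.observed,
            "z": round(overlap.z, 4),
            "p_empirical": round(overlap.p_empirical, 6),
            "n_perm": overlap.n_perm,
            "seed": overlap.seed,
        },
        "cocluster_chisq": (
            {
                "chi2": round(cocluster["chi2"], 4),
                "p": float(f"{cocluster['p']:.6g}"),
                "observed_same": cocluster["observed_same"],
                "expected_same": round(cocluster["expected_same"], 4),
                "n_pairs": cocluster["n_pairs"],
            }
            if cocluster
            else None
        ),
        "tf_hypergeom": {"overlap": hyper["overlap"], "p_upper": float(f"{hyper['p_upper']:.6g}")},
    }

    # stage 7: conservation
    track = conservation.ConservationTrack.from_bedgraph(inputs["phastcons"])
    regions_ccre = robust[["chrom", "start", "end"]]
    if len(regions_ccre):
        _, ccre_mean = conservation.interval_mean(track, regions_ccre, missing_as_zero=True)
        random_regions = conservation.random_matched_regions(regions_ccre, part.intergenic, seed=seed)
        per_random, random_mean = conservation.interval_mean(track, random_regions, missing_as_zero=True)
        per_ccre, _ = conservation.interval_mean(track, regions_ccre, missing_as_zero=True)
        ranksum = stats.ranksum_compare(per_ccre["mean_score"], per_random["mean_score"])
        summary["conservation"] = {
            "ccre_mean_missing_as_zero": round(ccre_mean, 4),
            "random_mean_missing_as_zero": round(random_mean, 4),
            "ranksum_p": float(f"{ranksum['p']:.6g}"),
        }
    else:
        summary["conservation"] = None

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _promoter_pairs(annotated: pd.DataFrame, genes: pd.DataFrame, resolution: int) -> list[tuple[str, str]]:
    """Active-promoter pairs where each anchor bin holds exactly one gene TSS."""
    bin_genes: dict[tuple[str, int], list[str]] = {}
    for g in genes.itertuples(index=False):
        bin_genes.setdefault((g.chrom, (g.tss // resolution) * resolution), []).append(g.gene_id)
    pairs = []
    aa = annotated[
        (annotated["label1"] == "active_promoter") & (annotated["label2"] == "active_promoter")
    ]
    for row in aa.drop_duplicates(["chrom", "start1", "start2"]).itertuples(index=False):
        ga = bin_genes.get((row.chrom, row.start1), [])
        gb = bin_genes.get((row.chrom, row.start2), [])
        if len(ga) == 1 and len(gb) == 1:
            pairs.append((ga[0], gb[0]))
    return pairs


def _e7_interacting_genes(annotated: pd.DataFrame, genes: pd.DataFrame, resolution: int) -> set[str]:
    """Genes whose promoter bin anchors an active-promoter/E7 interaction."""
    bin_genes: dict[tuple[str, int], list[str]] = {}
    for g in genes.itertuples(index=False):
        bin_genes.setdefault((g.chrom, (g.tss // resolution) * resolution), []).append(g.gene_id)
    out: set[str] = set()
    mask = (
        ((annotated["label1"] == "active_promoter") & (annotated["label2"] == "E7"))
        | ((annotated["label1"] == "E7") & (annotated["label2"] == "active_promoter"))
    )
    for row in annotated[mask].itertuples(index=False):
        for b, lab in ((row.start1, row.label1), (row.start2, row.label2)):
            if lab == "active_promoter":
                out.update(bin_genes.get((row.chrom, b), []))
    return out
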