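"""Seeded generator of a miniature epigenome with planted ground truth.

The genome is laid out in 30-kb slots (a common multiple of the 300-bp
methylation window and the 5-kb interaction resolution), each hosting at
most one planted feature: a gene (active or silent), an intergenic UMR
(optionally carrying a cCRE: ATAC + H3K9ac peaks and an E7 segment), an E4
polycomb block with an embedded small UMR, a TE, a weak-E7 segment, a CAGE
transcription unit, a stage-specific E7 segment, a transcribed region, or a
lncRNA. Centering features in their slot guarantees that one 5-kb bin
overlaps exactly one feature, so the hierarchical annotation of planted
loop anchors is unambiguous and the planted interaction-class mixture is
recoverable.

Methylation is Beta-Binomial: per-cytosine levels are Beta-distributed
around per-context means matching genome-wide levels typical of a highly
methylated cereal genome (~88.6% CpG, ~58.1% CHG, ~1.4% CHH), read depth is
Poisson, and planted UMRs are fully unmethylated. All randomness flows from
a single seed through one generator; the emitted bundle is byte-identical
across runs with the same seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome
from . import intervals as iv
from . import io as rio

SLOT = 30_000  # lcm(300, 5000) * 2; one planted feature per slot
STAGES = ("24DAP", "8DAP", "4DAG", "leaf")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 3_900_000
    # genes
    n_active_genes: int = 70
    n_silent_genes: int = 24
    gene_length: int = 4_000
    # long genes whose promoter and terminator fall in different bins,
    # hosting planted promoter-terminator self-loops
    n_self_loop_active: int = 4
    n_self_loop_silent: int = 4
    long_gene_length: int = 12_000
    # methylome
    n_umrs: int = 50
    umr_length: int = 900
    meth_means: dict = field(
        default_factory=lambda: {"CpG": 0.886, "CHG": 0.581, "CHH": 0.014}
    )
    meth_concentration: float = 2.0
    depth_mean: float = 10.0
    cytosine_spacing: int = 6
    # cCREs and chromatin states
    n_ccres: int = 30  # hosted inside the first n_ccres planted UMRs
    n_e4: int = 36
    n_te: int = 20
    n_weak_e7: int = 6
    n_extra_e7: int = 6  # stage-specific E7 segments (stages 2..4)
    p_e7_all_stages: float = 0.65
    # transcription
    n_transcribed: int = 4
    n_lncrna: int = 2
    # CAGE
    n_cage_u: int = 10
    n_cage_bu: int = 6
    n_cage_bb: int = 6
    n_cage_decoy_pairs: int = 4  # antisense pairs > max_dist apart -> two U units
    n_cage_singleton_pairs: int = 2  # close pairs of mutual singletons -> two U units
    n_cage_pruned: int = 6  # clusters planted near genes, removed by pruning
    # loops
    resolution: int = 5_000
    n_loops: int = 2_000
    class_mixture: dict = field(
        default_factory=lambda: {
            "active_promoter|active_promoter": 0.30,
            "E7|active_promoter": 0.25,
            "active_promoter|silent_promoter": 0.20,
            "E4|silent_promoter": 0.15,
            "TE|active_promoter": 0.10,
        }
    )
    n_k27_loops: int = 60
    n_bivalent: int = 40
    n_decoy_loops: int = 100
    # peaks
    n_noise_peaks: int = 20
    # conservation
    ccre_score_range: tuple = (0.4, 0.9)
    exon_score_range: tuple = (0.5, 0.95)
    background_score_range: tuple = (0.0, 0.08)
    # expression
    n_expression_clusters: int = 5
    cocluster_prob: float = 0.45
    tf_prob_interacting: float = 0.5
    tf_prob_other: float = 0.05


@dataclass
class GroundTruth:
    genes: pd.DataFrame
    umrs: pd.DataFrame  # all fully unmethylated planted blocks
    ccres: pd.DataFrame  # with per-stage presence columns
    cage_units: pd.DataFrame  # chrom, anchor_start, anchor_end, klass
    loops: pd.DataFrame  # planted H3K4me3 loops with class labels
    clusters: dict  # gene_id -> expression cluster
    self_loop_genes: pd.DataFrame  # gene_id, mark (K4/K27) of planted self-loops


def _slot_roles(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int, str]]:
    """Assign one role per 30-kb slot, shuffled across the genome.

    Returns [(chrom, slot_start, role), ...].
    """
    roles: list[str] = []
    roles += ["gene_active"] * cfg.n_active_genes
    roles += ["gene_silent"] * cfg.n_silent_genes
    roles += ["long_gene_active"] * cfg.n_self_loop_active
    roles += ["long_gene_silent"] * cfg.n_self_loop_silent
    roles += ["umr_ccre"] * min(cfg.n_ccres, cfg.n_umrs)
    roles += ["umr"] * max(cfg.n_umrs - cfg.n_ccres, 0)
    roles += ["e4"] * cfg.n_e4
    roles += ["te"] * cfg.n_te
    roles += ["weak_e7"] * cfg.n_weak_e7
    roles += ["extra_e7"] * cfg.n_extra_e7
    roles += ["transcribed"] * cfg.n_transcribed
    roles += ["lncrna"] * cfg.n_lncrna
    roles += ["cage_u"] * cfg.n_cage_u
    roles += ["cage_bu"] * cfg.n_cage_bu
    roles += ["cage_bb"] * cfg.n_cage_bb
    roles += ["cage_decoy"] * cfg.n_cage_decoy_pairs
    roles += ["cage_singleton"] * cfg.n_cage_singleton_pairs

    slots = [
        (f"chr{c + 1}", s)
        for c in range(cfg.n_chroms)
        for s in range(0, cfg.chrom_length - SLOT + 1, SLOT)
    ]
    if len(roles) > len(slots):
        raise ValueError(
            f"planted features ({len(roles)}) exceed available {SLOT // 1000}-kb slots ({len(slots)})"
        )
    roles += ["empty"] * (len(slots) - len(roles))
    order = rng.permutation(len(slots))
    return [(slots[i][0], slots[i][1], roles[k]) for k, i in enumerate(order)]


def _simulate_methylome(
    cfg: SimulationConfig,
    genome: Genome,
    umr_blocks: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    frames = []
    contexts = np.array(["CpG", "CHG", "CHH"])
    means = np.array([cfg.meth_means[c] for c in contexts])
    conc = cfg.meth_concentration
    umr_by_chrom = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in iv.merge(umr_blocks).groupby("chrom", sort=False)
    }
    for chrom in genome.names:
        length = genome.length(chrom)
        n = length // cfg.cytosine_spacing
        gaps = rng.integers(1, 2 * cfg.cytosine_spacing, size=n)
        pos = np.cumsum(gaps)
        pos = pos[pos < length]
        ctx_idx = rng.choice(3, size=pos.size, p=[0.25, 0.35, 0.40])
        level = rng.beta(means[ctx_idx] * conc, (1 - means[ctx_idx]) * conc)
        if chrom in umr_by_chrom:
            us, ue = umr_by_chrom[chrom]
            j = np.searchsorted(us, pos, side="right")
            inside = (j > 0) & (pos < ue[np.maximum(j - 1, 0)])
            level[inside] = 0.0
        depth = rng.poisson(cfg.depth_mean, size=pos.size)
        n_meth = rng.binomial(depth, level)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": np.where(rng.random(pos.size) < 0.5, "+", "-"),
                    "n_meth": n_meth,
                    "n_unmeth": depth - n_meth,
                    "context": contexts[ctx_idx],
                    "tri": "NNN",
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    return df


def _sample_loop_bins(
    pools: dict[str, dict[str, np.ndarray]],
    klass: str,
    rng: np.random.Generator,
    max_dist: int,
    used: set[tuple[str, int, int]] | None = None,
) -> tuple[str, int, int]:
    """Sample a same-chromosome anchor-bin pair for an interaction class.

    With ``used`` given, the pair is distinct from every pair already drawn,
    so deduplication at analysis time cannot distort the planted mixture.
    """
    l1, l2 = klass.split("|")
    candidates = [
        c
        for c in pools
        if len(pools[c].get(l1, ())) >= 1
        and len(pools[c].get(l2, ())) >= (2 if l1 == l2 else 1)
    ]
    if not candidates:
        raise ValueError(f"no chromosome can host interaction class {klass}")
    for _ in range(2000):
        chrom = candidates[int(rng.integers(len(candidates)))]
        b1 = int(rng.choice(pools[chrom][l1]))
        b2 = int(rng.choice(pools[chrom][l2]))
        if b1 == b2:
            continue
        if abs(b2 - b1) > max_dist:
            continue
        pair = (chrom, min(b1, b2), max(b1, b2))
        if used is not None:
            if pair in used:
                continue
            used.add(pair)
        return pair
    raise ValueError(f"could not place interaction class {klass} after bounded retries")


def simulate(cfg: SimulationConfig, outdir) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the full synthetic file bundle and its ground truth.

    Returns (file map, GroundTruth). Ground-truth tables are also
    serialized under ``outdir/ground_truth/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = Genome({f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)})
    slots = _slot_roles(cfg, rng)
    res = cfg.resolution

    genes_rows, atac, k9ac, k4me3, k27me3 = [], [], [], [], []
    umr_blocks, ccre_rows = [], []
    e4_rows, te_rows, weak_rows, extra_e7 = [], [], [], []
    trx_rows, lnc_rows = [], []
    cage_rows: list[tuple] = []
    cage_units: list[tuple] = []
    cons_rows = []
    gene_counter = 0
    cage_counter = 0

    self_loop_rows: list[tuple] = []

    def new_gene(chrom: str, s0: int, active: bool, length: int | None = None):
        nonlocal gene_counter
        gene_counter += 1
        gid = f"gene_{gene_counter:04d}"
        start = s0 + 12_000
        end = start + (length or cfg.gene_length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes_rows.append((chrom, start, end, strand, gid, "high", active, length is not None))
        tss = start if strand == "+" else end - 1
        # promoter mark peaks and exon conservation
        if active:
            k4me3.append((chrom, max(tss - 300, 0), tss + 300))
            k9ac.append((chrom, max(tss - 300, 0), tss + 300))
            atac.append((chrom, max(tss - 250, 0), tss + 250))
        else:
            k27me3.append((chrom, max(tss - 300, 0), tss + 300))
        lo, hi = cfg.exon_score_range
        cons_rows.append((chrom, start, end, round(float(rng.uniform(lo, hi)), 4)))
        return gid, tss

    def new_cage_cluster(chrom, dtss, strand, tpm, n_ctss):
        nonlocal cage_counter
        cage_counter += 1
        half = int(rng.integers(20, 60))
        return (
            chrom,
            dtss - half,
            dtss + half + 1,
            strand,
            dtss,
            round(float(tpm), 4),
            int(n_ctss),
            int(rng.integers(10, 80)),
            f"ctss_{cage_counter:04d}",
        )

    for chrom, s0, role in slots:
        center = s0 + 12_000
        if role in ("gene_active", "gene_silent"):
            new_gene(chrom, s0, role == "gene_active")
        elif role in ("long_gene_active", "long_gene_silent"):
            active = role == "long_gene_active"
            gid, tss = new_gene(chrom, s0, active, length=cfg.long_gene_length)
            g = genes_rows[-1]
            tes = g[2] - 1 if g[3] == "+" else g[1]
            b1 = (tss // res) * res
            b2 = (tes // res) * res
            self_loop_rows.append(
                (gid, "H3K4me3" if active else "H3K27me3", chrom, min(b1, b2), max(b1, b2))
            )
        elif role in ("umr_ccre", "umr"):
            u_start = s0 + 10_200
            u_end = u_start + cfg.umr_length
            umr_blocks.append((chrom, u_start, u_end, "planted"))
            if role == "umr_ccre":
                a_s, a_e = u_start + 50, u_end - 50
                atac.append((chrom, a_s, a_e))
                k9ac.append((chrom, u_start + 80, u_end - 80))
                stage_flags = _stage_membership(cfg, rng)
                ccre_rows.append((chrom, a_s, a_e, u_start, u_end) + stage_flags)
                lo, hi = cfg.ccre_score_range
                cons_rows.append((chrom, a_s, a_e, round(float(rng.uniform(lo, hi)), 4)))
        elif role == "e4":
            e4_rows.append((chrom, s0 + 10_000, s0 + 13_500))
            umr_blocks.append((chrom, s0 + 11_100, s0 + 11_400, "e4_embedded"))
        elif role == "te":
            te_rows.append((chrom, s0 + 11_000, s0 + 13_000))
        elif role == "weak_e7":
            weak_rows.append((chrom, s0 + 10_500, s0 + 11_500))
        elif role == "extra_e7":
            stage = STAGES[1 + int(rng.integers(len(STAGES) - 1))]
            extra_e7.append((chrom, s0 + 10_500, s0 + 11_300, stage))
        elif role == "transcribed":
            trx_rows.append((chrom, s0 + 10_000, s0 + 13_000))
        elif role == "lncrna":
            lnc_rows.append((chrom, s0 + 10_000, s0 + 12_000))
        elif role == "cage_u":
            strand = "+" if rng.random() < 0.5 else "-"
            cl = new_cage_cluster(chrom, center, strand, rng.uniform(0.5, 8), rng.integers(3, 12))
            cage_rows.append(cl)
            cage_units.append((chrom, center, center + 1, "U"))
        elif role in ("cage_bu", "cage_bb"):
            d = int(rng.integers(100, 551))
            minus_dtss, plus_dtss = center, center + d  # divergent geometry
            minus_tpm = rng.uniform(0.5, 3.0)
            if role == "cage_bu":
                shift = rng.uniform(1.2, 3.0) * (1 if rng.random() < 0.5 else -1)
            else:
                shift = rng.uniform(-0.9, 0.9)
            plus_tpm = minus_tpm * 2.0**shift
            cage_rows.append(new_cage_cluster(chrom, minus_dtss, "-", minus_tpm, rng.integers(3, 12)))
            cage_rows.append(new_cage_cluster(chrom, plus_dtss, "+", plus_tpm, rng.integers(3, 12)))
            cage_units.append((chrom, minus_dtss, plus_dtss + 1, "BU" if role == "cage_bu" else "BB"))
        elif role == "cage_decoy":
            d = int(rng.integers(700, 1500))
            cage_rows.append(new_cage_cluster(chrom, center, "-", rng.uniform(0.5, 3), rng.integers(3, 12)))
            cage_rows.append(new_cage_cluster(chrom, center + d, "+", rng.uniform(0.5, 3), rng.integers(3, 12)))
            cage_units.append((chrom, center, center + 1, "U"))
            cage_units.append((chrom, center + d, center + d + 1, "U"))
        elif role == "cage_singleton":
            d = int(rng.integers(100, 551))
            cage_rows.append(new_cage_cluster(chrom, center, "-", rng.uniform(0.02, 0.09), 1))
            cage_rows.append(new_cage_cluster(chrom, center + d, "+", rng.uniform(0.02, 0.09), 1))
            cage_units.append((chrom, center, center + 1, "U"))
            cage_units.append((chrom, center + d, center + d + 1, "U"))

    genes = pd.DataFrame(
        genes_rows,
        columns=["chrom", "start", "end", "strand", "gene_id", "confidence", "active", "long"],
    )
    genes = rio.annotate_gene_ends(genes)

    # clusters pruned away: planted close to genes
    gene_slots = [(c, s) for c, s, r in slots if r.startswith("gene")]
    for k in range(min(cfg.n_cage_pruned, len(gene_slots))):
        chrom, s0 = gene_slots[k]
        strand = "+" if rng.random() < 0.5 else "-"
        cage_rows.append(
            new_cage_cluster(chrom, s0 + 11_700, strand, rng.uniform(0.5, 3), rng.integers(3, 12))
        )

    # noise ATAC peaks inside gene bodies (genic midpoint -> not cCREs)
    for k in range(min(cfg.n_noise_peaks, len(genes))):
        g = genes.iloc[k % len(genes)]
        mid = (g["start"] + g["end"]) // 2
        atac.append((g["chrom"], mid - 150, mid + 150))

    # chromatin-state segmentations per stage
    ccre_cols = ["chrom", "start", "end", "umr_start", "umr_end"] + [f"in_{s}" for s in STAGES]
    ccres = pd.DataFrame(ccre_rows, columns=ccre_cols)
    states_by_stage: dict[str, pd.DataFrame] = {}
    for si, stage in enumerate(STAGES):
        segs = []
        for row in ccres.itertuples(index=False):
            if getattr(row, f"in_{stage}"):
                segs.append((row.chrom, row.umr_start, row.umr_end, "E7"))
        if si == 0:
            segs += [(c, s, e, "E7") for c, s, e in weak_rows]
            segs += [(c, s, e, "E4") for c, s, e in e4_rows]
            for g in genes.itertuples(index=False):
                segs.append((g.chrom, g.start, g.end, "E1" if g.active else "E3"))
        segs += [(c, s, e, "E7") for c, s, e, st in extra_e7 if st == stage]
        states_by_stage[stage] = iv.sort_regions(
            pd.DataFrame(segs, columns=["chrom", "start", "end", "state"])
        )

    # methylome (planted UMR blocks are fully unmethylated)
    umr_df = pd.DataFrame(umr_blocks, columns=["chrom", "start", "end", "origin"])
    cx = _simulate_methylome(cfg, genome, umr_df, rng)

    # interaction-anchor bin pools per chromosome and label
    # (long self-loop genes are kept out so planted anchors stay unambiguous)
    active_genes = genes[genes["active"] & ~genes["long"]]
    silent_genes = genes[~genes["active"] & ~genes["long"]]
    pools: dict[str, dict[str, np.ndarray]] = {c: {} for c in genome.names}
    prim = STAGES[0]

    def add_pool(label: str, positions: pd.DataFrame, col: str):
        for chrom, sub in positions.groupby("chrom", sort=False):
            bins = np.unique((sub[col].to_numpy(np.int64) // res) * res)
            pools[chrom][label] = bins

    add_pool("active_promoter", active_genes, "tss")
    add_pool("silent_promoter", silent_genes, "tss")
    if not ccres.empty:
        e7_primary = ccres[ccres[f"in_{prim}"].astype(bool)].copy()
        e7_primary["mid"] = (e7_primary["umr_start"] + e7_primary["umr_end"]) // 2
        add_pool("E7", e7_primary, "mid")
    e4_df = pd.DataFrame(e4_rows, columns=["chrom", "start", "end"])
    if not e4_df.empty:
        e4_df["mid"] = (e4_df["start"] + e4_df["end"]) // 2
        add_pool("E4", e4_df, "mid")
    te_df = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])
    if not te_df.empty:
        te_df["mid"] = (te_df["start"] + te_df["end"]) // 2
        add_pool("TE", te_df, "mid")

    # planted H3K4me3 loops realizing the class mixture
    classes = list(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in classes])
    probs = probs / probs.sum()
    max_dist = 2_000_000
    used_k4: set[tuple[str, int, int]] = set()
    loop_rows = []
    if cfg.n_loops:
        draws = rng.choice(len(classes), size=cfg.n_loops, p=probs)
        for d in draws:
            chrom, b1, b2 = _sample_loop_bins(pools, classes[d], rng, max_dist, used_k4)
            loop_rows.append((chrom, b1, b1 + res, b2, b2 + res, float(rng.uniform(1e-6, 0.04)), classes[d]))
    # planted promoter-terminator self-loops within long genes
    k27_rows = []
    for gid, mark, chrom, b1, b2 in self_loop_rows:
        row = (chrom, b1, b1 + res, b2, b2 + res, float(rng.uniform(1e-6, 0.04)), "self")
        (loop_rows if mark == "H3K4me3" else k27_rows).append(row)
        used_k4.add((chrom, b1, b2))
    loops_k4 = pd.DataFrame(
        loop_rows, columns=["chrom", "start1", "end1", "start2", "end2", "qvalue", "klass"]
    )
    # decoys: well-formed bin pairs with q above any sensible FDR cut
    decoy_rows = []
    for k in range(cfg.n_decoy_loops):
        chrom, b1, b2 = _sample_loop_bins(pools, classes[k % len(classes)], rng, max_dist, used_k4)
        decoy_rows.append((chrom, b1, b1 + res, b2, b2 + res, float(rng.uniform(0.2, 0.9)), "decoy"))
    # H3K27me3 loops: silent-silent pairs, plus a bivalent subset shared with K4
    used_k27: set[tuple[str, int, int]] = set()
    for _ in range(cfg.n_k27_loops):
        chrom, b1, b2 = _sample_loop_bins(pools, "silent_promoter|silent_promoter", rng, max_dist, used_k27)
        k27_rows.append((chrom, b1, b1 + res, b2, b2 + res, float(rng.uniform(1e-6, 0.04)), "SS"))
    loops_k27 = pd.DataFrame(
        k27_rows, columns=["chrom", "start1", "end1", "start2", "end2", "qvalue", "klass"]
    )
    n_biv = min(cfg.n_bivalent, len(loops_k4))
    bivalent = loops_k4.drop_duplicates(["chrom", "start1", "start2"]).head(n_biv).copy()
    loops_k27 = pd.concat([loops_k27, bivalent], ignore_index=True)

    # conservation: low-scoring background patches in empty slots
    for chrom, s0, role in slots:
        if role == "empty" and rng.random() < 0.5:
            lo, hi = cfg.background_score_range
            cons_rows.append((chrom, s0 + 5_000, s0 + 8_000, round(float(rng.uniform(lo, hi)), 4)))
    conservation = iv.sort_regions(
        pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])
    )

    # expression clusters: genes of interacting active-promoter pairs co-cluster
    cluster_of = {
        gid: int(c)
        for gid, c in zip(
            genes["gene_id"], rng.integers(1, cfg.n_expression_clusters + 1, size=len(genes))
        )
    }
    tss_to_gene = {
        (g.chrom, (g.tss // res) * res): g.gene_id for g in genes.itertuples(index=False)
    }
    aa = loops_k4[loops_k4["klass"] == "active_promoter|active_promoter"]
    for row in aa.drop_duplicates(["chrom", "start1", "start2"]).itertuples(index=False):
        ga = tss_to_gene.get((row.chrom, row.start1))
        gb = tss_to_gene.get((row.chrom, row.start2))
        if ga and gb and rng.random() < cfg.cocluster_prob:
            cluster_of[gb] = cluster_of[ga]

    # TF gene set enriched among E7-interacting genes
    e7_loops = loops_k4[loops_k4["klass"] == "E7|active_promoter"]
    e7_genes = set()
    for row in e7_loops.itertuples(index=False):
        for b in (row.start1, row.start2):
            gid = tss_to_gene.get((row.chrom, b))
            if gid:
                e7_genes.add(gid)
    tf_genes = [
        gid
        for gid in genes["gene_id"]
        if rng.random() < (cfg.tf_prob_interacting if gid in e7_genes else cfg.tf_prob_other)
    ]

    # ---- write the bundle ----
    files: dict[str, Path] = {}

    def path(name: str) -> Path:
        p = outdir / name
        files[name.split(".")[0]] = p
        return p

    genome.to_chrom_sizes(path("chrom.sizes"))
    rio.write_gff3_genes(genes, path("genes.gff3"))
    rio.write_bed(pd.DataFrame(trx_rows, columns=["chrom", "start", "end"]), path("transcribed.bed"), cols=[])
    rio.write_bed(pd.DataFrame(lnc_rows, columns=["chrom", "start", "end"]), path("lncrna.bed"), cols=[])
    for name, rows in (("atac", atac), ("k9ac", k9ac), ("k4me3", k4me3), ("k27me3", k27me3)):
        rio.write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end"]), path(f"{name}_peaks.bed"), cols=[])
    rio.write_bed(pd.DataFrame(te_rows, columns=["chrom", "start", "end"]), path("te.bed"), cols=[])
    for stage, seg in states_by_stage.items():
        rio.write_bed(seg, path(f"states_{stage}.bed"), cols=["state"])
    from .methylome import write_cytosine_report

    write_cytosine_report(cx, path("cx_report.tsv"))
    cage_df = pd.DataFrame(
        cage_rows,
        columns=["chrom", "start", "end", "strand", "dominant_tss", "tpm", "n_ctss", "iqw", "cluster_id"],
    ).sort_values(["chrom", "start"], kind="mergesort")
    cage_df.to_csv(path("cage_clusters.tsv"), sep="\t", index=False)
    loops_all_k4 = pd.concat(
        [loops_k4, pd.DataFrame(decoy_rows, columns=loops_k4.columns)], ignore_index=True
    )
    _write_bedpe(loops_all_k4, path("loops_k4.bedpe"))
    _write_bedpe(loops_k27, path("loops_k27.bedpe"))
    pd.DataFrame(
        {"chrom": conservation["chrom"], "start": conservation["start"], "end": conservation["end"], "score": conservation["score"]}
    ).to_csv(path("phastcons.bedgraph"), sep="\t", header=False, index=False)
    pd.DataFrame(
        sorted(cluster_of.items()), columns=["gene_id", "cluster"]
    ).to_csv(path("expression_clusters.tsv"), sep="\t", index=False)
    path("tf_genes.txt").write_text("".join(f"{g}\n" for g in sorted(tf_genes)))

    # ---- ground truth ----
    truth = GroundTruth(
        genes=genes,
        umrs=iv.sort_regions(umr_df),
        ccres=iv.sort_regions(ccres),
        cage_units=pd.DataFrame(
            cage_units, columns=["chrom", "anchor_start", "anchor_end", "klass"]
        ).sort_values(["chrom", "anchor_start"], kind="mergesort").reset_index(drop=True),
        loops=loops_k4,
        clusters=cluster_of,
        self_loop_genes=pd.DataFrame(
            self_loop_rows, columns=["gene_id", "mark", "chrom", "bin1", "bin2"]
        ),
    )
    gt = outdir / "ground_truth"
    rio.write_tsv(truth.umrs, gt / "umrs.tsv")
    rio.write_tsv(truth.ccres, gt / "ccres.tsv")
    rio.write_tsv(truth.cage_units, gt / "cage_units.tsv")
    rio.write_tsv(truth.loops, gt / "loops.tsv")
    rio.write_tsv(truth.self_loop_genes, gt / "self_loop_genes.tsv")
    cfg_dict = asdict(cfg)
    for key in ("ccre_score_range", "exon_score_range", "background_score_range"):
        cfg_dict[key] = list(cfg_dict[key])
    (gt / "manifest.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n")
    return files, truth


def _stage_membership(cfg: SimulationConfig, rng: np.random.Generator) -> tuple:
    """cCRE presence per stage; the primary stage always contains the element."""
    if rng.random() < cfg.p_e7_all_stages:
        return (True,) * len(STAGES)
    return (True,) + tuple(bool(rng.random() < 0.6) for _ in STAGES[1:])


def _write_bedpe(loops: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chr1": loops["chrom"],
            "s1": loops["start1"],
            "e1": loops["end1"],
            "chr2": loops["chrom"],
            "s2": loops["start2"],
            "e2": loops["end2"],
            "Q-Value_Bias": loops["qvalue"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
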