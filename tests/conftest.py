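import pytest

from regulomap.simulate import SimulationConfig, STAGES, simulate


def pipeline_config(files, seed=11, **overrides):
    """Pipeline run config pointing at a simulated bundle."""
    return {
        "seed": seed,
        **overrides,
        "inputs": {
            "genome": str(files["chrom"]),
            "genes": str(files["genes"]),
            "transcribed": str(files["transcribed"]),
            "lncrna": str(files["lncrna"]),
            "atac": str(files["atac_peaks"]),
            "k9ac": str(files["k9ac_peaks"]),
            "k4me3": str(files["k4me3_peaks"]),
            "k27me3": str(files["k27me3_peaks"]),
            "te": str(files["te"]),
            "cx_report": str(files["cx_report"]),
            "cage_clusters": str(files["cage_clusters"]),
            "loops_k4": str(files["loops_k4"]),
            "loops_k27": str(files["loops_k27"]),
            "phastcons": str(files["phastcons"]),
            "expression_clusters": str(files["expression_clusters"]),
            "tf_genes": str(files["tf_genes"]),
            "states": {s: str(files[f"states_{s}"]) for s in STAGES},
        },
    }


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full-size synthetic bundle at the default study conditions."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=11)
    files, truth = simulate(cfg, outdir)
    return cfg, files, truth


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """One end-to-end run of the stage chain on the default bundle."""
    from regulomap import pipeline

    _, files, _ = default_bundle
    outdir = tmp_path_factory.mktemp("run")
    summary = pipeline.run_all(pipeline_config(files), outdir)
    return summary, outdir


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A fast, reduced bundle for unit-scale checks."""
    outdir = tmp_path_factory.mktemp("small_bundle")
    cfg = SimulationConfig(
        seed=7,
        chrom_length=600_000,
        n_active_genes=8,
        n_silent_genes=6,
        n_self_loop_active=1,
        n_self_loop_silent=1,
        n_umrs=6,
        n_ccres=4,
        n_e4=2,
        n_te=2,
        n_weak_e7=1,
        n_extra_e7=1,
        n_transcribed=1,
        n_lncrna=1,
        n_cage_u=2,
        n_cage_bu=1,
        n_cage_bb=1,
        n_cage_decoy_pairs=1,
        n_cage_singleton_pairs=1,
        n_cage_pruned=1,
        n_loops=12,
        n_k27_loops=2,
        n_bivalent=3,
        n_decoy_loops=4,
        n_noise_peaks=3,
    )
    files, truth = simulate(cfg, outdir)
    return cfg, files, truth
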