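import pytest
from hypothesis import HealthCheck, settings

from bsamap import simdata

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Full fixture emission for one simulated experiment (seed 11)."""
    out = tmp_path_factory.mktemp("sim11")
    simdata.emit_fixtures(out, simdata.toy_config(seed=11))
    return out


@pytest.fixture(scope="session")
def study_tables():
    """The packaged worked tables of the soybean dwarf mapping study."""
    from bsamap import study

    snps, anns = study.mapping_region_snps()
    return {
        "snps": snps,
        "annotations": anns,
        "genes": study.interval_genes(),
        "markers": study.linkage_marker_positions(),
        "fine_mapping": study.fine_mapping_linkage(),
        "segregation": study.segregation_counts(),
        "intervals": study.scan_intervals(),
    }


def tiny_config(seed: int = 0, **overrides) -> simdata.SimConfig:
    """Minimal genome for fast per-seed simulation loops."""
    params = dict(
        chrom_lengths=[("c1", 50_000), ("c2", 50_000)],
        ems_snp_count=40,
        causal=("c2", 25_000),
        linked_window_bp=10_000,
        recomb_rate=5e-6,
        n_plants=400,
        seed=seed,
    )
    params.update(overrides)
    return simdata.SimConfig(**params)
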