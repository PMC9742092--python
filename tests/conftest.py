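import pytest

from cherbp.genome import GeneModel, GenomicInterval, RegionConfig
from cherbp.simulate import SimConfig, simulate


def small_sim_config(seed: int, noise_sd: float = 0.0, **overrides) -> SimConfig:
    """A scaled-down study configuration for the many-replicate tests."""
    kw = dict(
        seed=seed,
        n_genes=120,
        chrom_length=500_000,
        n_trans_targets=20,
        n_splice_targets=15,
        n_co_regulated=5,
        n_decoy_chip=60,
        n_decoy_clip=80,
        n_null_events_per_type=20,
        n_pma_extra_deg=15,
        n_pma_extra_events=10,
        noise_sd=noise_sd,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default noiseless study bundle, simulated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=7)
    manifest = simulate(cfg, str(outdir))
    return str(outdir), cfg, manifest


@pytest.fixture()
def toy_genes():
    """Two hand-built genes on one small chromosome (one per strand).

    gplus: chr1:[5000, 7000) '+', exons [5000,5400) [5900,6300) [6700,7000)
    gminus: chr1:[12000, 14000) '-', exons [12000,12500) [13400,14000)
    """
    gplus = GeneModel(
        "gplus", "GPLUS",
        GenomicInterval("chr1", 5000, 7000, "+"),
        (
            GenomicInterval("chr1", 5000, 5400, "+"),
            GenomicInterval("chr1", 5900, 6300, "+"),
            GenomicInterval("chr1", 6700, 7000, "+"),
        ),
    )
    gminus = GeneModel(
        "gminus", "GMINUS",
        GenomicInterval("chr1", 12000, 14000, "-"),
        (
            GenomicInterval("chr1", 12000, 12500, "-"),
            GenomicInterval("chr1", 13400, 14000, "-"),
        ),
    )
    return [gplus, gminus]


@pytest.fixture()
def region_cfg():
    return RegionConfig()
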