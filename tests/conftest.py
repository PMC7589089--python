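import pytest

from chlorotrna.cub import cub_ratio
from chlorotrna.fixtures import codon_usage_fixture, fixture_inventories
from chlorotrna.simulate import (
    GenomeSimConfig,
    generate_host_genome,
    generate_virus_genome,
    ma1e_like_cluster,
    sag_like_cluster,
)


@pytest.fixture(scope="session")
def cu_tables():
    """(PBCV-1, AN69C, host) codon-usage tables plus the printed ratios."""
    return codon_usage_fixture()


@pytest.fixture(scope="session")
def ratio_table(cu_tables):
    pbcv1, an69c, host, _ = cu_tables
    return cub_ratio([pbcv1, an69c], host)


@pytest.fixture(scope="session")
def cohort():
    """(inventories, clade_map) for the 41-virus cluster-table fixtures."""
    return fixture_inventories()


@pytest.fixture(scope="session")
def nc64a_sim(cu_tables):
    """A simulated NC64A-type virus genome with the 14-gene cluster."""
    pbcv1 = cu_tables[0]
    cfg = GenomeSimConfig(
        seed=11,
        genome_length=60_000,
        codon_table=pbcv1.frequencies,
        gc_intergenic=40.0,
        cluster=ma1e_like_cluster(),
        clade="NC64A",
        genome_id="synth_nc64a",
    )
    return generate_virus_genome(cfg)


@pytest.fixture(scope="session")
def sag_sim(cu_tables):
    """A simulated SAG-type virus genome with the ~30 kb orphan tRNA-Thr."""
    pbcv1 = cu_tables[0]
    cfg = GenomeSimConfig(
        seed=5,
        genome_length=80_000,
        codon_table=pbcv1.frequencies,
        gc_intergenic=40.0,
        cluster=sag_like_cluster(),
        clade="SAG",
        genome_id="synth_sag",
    )
    return generate_virus_genome(cfg)


@pytest.fixture(scope="session")
def host_sim(cu_tables):
    """A simulated GC-rich host genome (no tRNA cluster)."""
    host = cu_tables[2]
    cfg = GenomeSimConfig(
        seed=3,
        genome_length=50_000,
        cds_count=40,
        codon_table=host.frequencies,
        gc_intergenic=67.0,
        clade="host",
        genome_id="synth_host",
    )
    return generate_host_genome(cfg)
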