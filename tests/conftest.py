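import pytest
from hypothesis import settings

from gojivar.genomic_io import CohortMap, load_packaged_site_tables
from gojivar.synthetic_data import SimulationConfig, simulate_run

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohorts8() -> CohortMap:
    """The study's cohort layout: Lb1-Lb5 cultivated, Lb6w-Lb8w wild."""
    return CohortMap(
        {
            **{f"Lb{i}": "cultivated" for i in range(1, 6)},
            **{f"Lb{i}w": "wild" for i in range(6, 9)},
        }
    )


@pytest.fixture(scope="session")
def packaged_tables():
    """The three published BODYGUARD coding-SNP tables, keyed by gene id."""
    return load_packaged_site_tables()


@pytest.fixture(scope="session")
def chr4_gene(packaged_tables):
    return packaged_tables["LOC132634709"]


@pytest.fixture(scope="session")
def chr8_gene(packaged_tables):
    return packaged_tables["LOC132607278"]


@pytest.fixture(scope="session")
def chr9_gene(packaged_tables):
    return packaged_tables["LOC132609965"]


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small but fully featured simulated run shared across tests."""
    config = SimulationConfig(
        seed=11,
        chromosomes=(("chr1", 150_000), ("chr2", 150_000)),
        n_cds_genes=4,
        cds_length=300,
    )
    outdir = tmp_path_factory.mktemp("sim")
    paths = simulate_run(config, outdir)
    return config, paths
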