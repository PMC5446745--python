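import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from txpopgen.model import SampleSheet, SimulationConfig, SnpRecord
from txpopgen.simulate import simulate, write_fixture


def make_record(
    unigene="g1",
    pos=10,
    ref="A",
    alt="G",
    genotypes=(0, 1, 2, 0, 1, 2),
    gq=None,
    samples=None,
    fs=1.0,
    qd=20.0,
    depth=100,
):
    genotypes = np.array(genotypes, dtype=np.int8)
    if samples is None:
        samples = tuple(f"s{i}" for i in range(len(genotypes)))
    if gq is None:
        gq = np.full(len(genotypes), 99, dtype=np.int16)
    return SnpRecord(
        unigene_id=unigene,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        genotype_quals=np.asarray(gq, dtype=np.int16),
        samples=samples,
        fs=fs,
        qd=qd,
        depth=depth,
    )


@pytest.fixture
def six_sample_sheet():
    samples = tuple(f"s{i}" for i in range(6))
    return SampleSheet(
        samples=samples,
        population_of={s: ("A" if i < 3 else "B") for i, s in enumerate(samples)},
    )


@pytest.fixture(scope="session")
def clean_config():
    """A small, artifact-free simulation: no missingness, no low-GQ tail."""
    return SimulationConfig(
        n_genes=60,
        gene_length_mean=900,
        snps_per_gene=4.0,
        n_per_pop=24,
        F=0.2,
        missing_rate=0.0,
        low_gq_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    return simulate(clean_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, clean_sim):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(clean_sim, d)
    return d


@pytest.fixture(scope="session")
def planted_sim():
    """Simulation with planted hard-filter violations."""
    cfg = SimulationConfig(
        n_genes=80,
        gene_length_mean=2000,
        snps_per_gene=3.0,
        n_per_pop=24,
        F=0.1,
        missing_rate=0.01,
        low_gq_rate=0.02,
        fs_fail_rate=0.04,
        qd_fail_rate=0.04,
        depth_fail_rate=0.03,
        n_cluster_genes=3,
        seed=7,
    )
    return simulate(cfg)
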