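import numpy as np
import pandas as pd
import pytest

import snbias as sb
from snbias import qc as qcm


@pytest.fixture(scope="session")
def small_config():
    """A fast universe: short genes with a high polyA rate per nt."""
    return sb.SimulationConfig(
        seed=2,
        n_genes=400,
        n_cells_per_protocol=60,
        length_log_mean=6.5,
        length_log_sd=1.0,
        polya_rate_per_nt=3e-3,
        n_lncrna=40,
        n_fusion=20,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    return sb.simulate_gene_universe(small_config)


@pytest.fixture(scope="session")
def small_adata(small_config, small_universe):
    return sb.simulate_experiment(small_universe, small_config)


@pytest.fixture(scope="session")
def planted_config():
    """Default planted effect sizes at the study's simulated scale."""
    return sb.SimulationConfig(seed=7, n_genes=5000, n_cells_per_protocol=300)


@pytest.fixture(scope="session")
def planted_universe(planted_config):
    return sb.simulate_gene_universe(planted_config)


@pytest.fixture(scope="session")
def planted_adata(planted_config, planted_universe):
    return sb.simulate_experiment(planted_universe, planted_config)


@pytest.fixture(scope="session")
def planted_norm(planted_adata):
    return qcm.lognormalize(planted_adata)


@pytest.fixture(scope="session")
def null_config():
    """All planted effects switched off: protocols are exchangeable."""
    return sb.SimulationConfig(
        seed=11,
        n_genes=2000,
        n_cells_per_protocol=300,
        warm_stress_fold=1.0,
        cold_stress_fold=1.0,
        nuclei_polya_capture_coef=0.0,
        nuclei_lncrna_fold=1.0,
        n_mito=0,
    )


@pytest.fixture(scope="session")
def null_norm(null_config):
    universe = sb.simulate_gene_universe(null_config)
    adata = sb.simulate_experiment(universe, null_config)
    return qcm.lognormalize(adata)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory, small_universe):
    """50-gene toy genome files plus the planted layout truth."""
    d = tmp_path_factory.mktemp("genome")
    fasta, gtf = str(d / "toy.fa"), str(d / "toy.gtf")
    layout = sb.write_toy_genome(small_universe.head(50), fasta, gtf, seed=3)
    return fasta, gtf, layout
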