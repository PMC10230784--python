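"""Shared study conditions for the numbered analysis scripts.

Every script regenerates the same seeded synthetic experiment (5,000 genes,
300 cells per protocol, default planted effects) so each is runnable on its
own; generation takes about a second.
"""

import os

import snbias as sb
from snbias import qc as qcm

SEED = 7
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

CONFIG = sb.SimulationConfig(seed=SEED, n_genes=5000, n_cells_per_protocol=300)


def outdir(sub: str) -> str:
    path = os.path.join(RESULTS, sub)
    os.makedirs(path, exist_ok=True)
    return path


def dataset():
    """(universe, raw AnnData) under the study conditions."""
    universe = sb.simulate_gene_universe(CONFIG)
    return universe, sb.simulate_experiment(universe, CONFIG)


def normalized():
    """(universe, QC-passed log-normalized AnnData, QC report)."""
    universe, adata = dataset()
    mito = universe.loc[universe["is_mito"], "gene_id"].tolist()
    qc_table = qcm.compute_qc_metrics(adata, mito)
    filtered, report = qcm.apply_qc(adata, qc_table)
    return universe, qcm.lognormalize(filtered), report
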