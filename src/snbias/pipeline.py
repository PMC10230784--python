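"""End-to-end orchestration: annotate -> QC -> normalize -> score -> DE ->
length-bias analyses -> classify, from one configuration with one seed.

``run_pipeline`` drives the analysis from files on disk; ``demo`` first
synthesizes a planted-bias experiment and then runs the same stages, so the
report can compare recovered effects against the planted truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classify as clf
from . import diffexp as de
from . import io as sio
from . import qc as qcm
from . import scoring as scm
from . import simulate as sim

__all__ = ["PipelineConfig", "run_pipeline", "demo"]


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    counts_format: str = "mtx_dir"
    meta_path: str | None = None
    fasta_path: str | None = None
    gtf_path: str | None = None
    signature_files: list = field(default_factory=list)
    region_fractions_path: str | None = None
    out_dir: str = "snbias_out"
    seed: int = 0
    contrast: tuple = ("warm", "nuclei")
    force: bool = False
    annotation: ann.AnnotationParams = field(default_factory=ann.AnnotationParams)
    qc: qcm.QCParams = field(default_factory=qcm.QCParams)
    scoring: scm.ScoringParams = field(default_factory=scm.ScoringParams)
    de: de.DEParams = field(default_factory=de.DEParams)
    split: clf.SplitSpec = field(default_factory=clf.SplitSpec)
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    baseline_reps: int = 10


def _provenance(config: PipelineConfig) -> dict:
    prov = {
        "seed": config.seed,
        "annotation": asdict(config.annotation),
        "qc": asdict(config.qc),
        "scoring": asdict(config.scoring),
        "de": asdict(config.de),
        "split": asdict(config.split),
        "contrast": list(config.contrast),
    }
    return prov


def _stage_classify(adata_norm, signatures, config, report):
    labels_nuclei = pd.Series(
        (adata_norm.obs["protocol"] == "nuclei").astype(int),
        index=adata_norm.obs_names,
    )
    labels_cells = 1 - labels_nuclei
    out = {}
    tasks = []
    if "length_bias" in signatures:
        tasks.append(("length_bias", signatures["length_bias"], labels_nuclei, "nuclei"))
    if "warm_dissociation" in signatures:
        tasks.append(
            ("warm_dissociation", signatures["warm_dissociation"], labels_cells, "cells")
        )
    for name, sig, labels, target in tasks:
        res = clf.score_classifier_auc(
            adata_norm, sig, labels, config.split, config.scoring
        )
        baseline = clf.random_signature_baseline(
            adata_norm,
            len(sig),
            labels,
            config.split,
            config.scoring,
            n_reps=config.baseline_reps,
            seed=config.seed,
        )
        out[name] = {
            "target": target,
            "test_auc": res["test_auc"],
            "train_auc": res["train_roc"].auc,
            "model": {
                "intercept": res["model"].intercept,
                "slope": res["model"].slope,
                "converged": res["model"].converged,
            },
            "baseline_auc_mean": float(baseline.mean()),
            "baseline_auc": [float(a) for a in baseline],
        }
    report["classifier"] = out


def _core_stages(adata, gene_table, signatures, config: PipelineConfig) -> dict:
    """QC -> normalize -> score -> DE -> length-bias, shared by run and demo."""
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}

    mito_ids = (
        gene_table.loc[gene_table.get("is_mito", False) == True, "gene_id"].tolist()
        if "is_mito" in gene_table
        else [g for g in adata.var_names if g.upper().startswith("MT-")]
    )
    qc_table = qcm.compute_qc_metrics(adata, mito_ids)
    filtered, qc_report = qcm.apply_qc(adata, qc_table, config.qc)
    qc_table.to_csv(os.path.join(config.out_dir, "qc_metrics.tsv"), sep="\t")
    qc_report.to_csv(
        os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False
    )
    report["qc"] = qc_report.to_dict(orient="records")

    norm = qcm.lognormalize(filtered)

    # length annotation joined to the filtered universe
    models = gene_table.set_index("gene_id").loc[list(norm.var_names)].reset_index()
    bins, labels = ann.assign_length_quartiles(
        pd.Series(models["length_nt"].to_numpy(), index=models["gene_id"])
    )
    length_sig = ann.build_length_bias_signature(models, config.annotation)
    sio.write_signature(
        length_sig, os.path.join(config.out_dir, "length_bias_signature.txt")
    )
    signatures = dict(signatures)
    signatures["length_bias"] = length_sig
    report["length_bins"] = {"edges": [float(e) for e in bins.edges]}
    report["signature_sizes"] = {k: len(v) for k, v in signatures.items()}
    report["polya_length_pearson_r"] = float(
        np.corrcoef(models["length_nt"], models["polya_count"])[0, 1]
    )

    score_table = scm.score_signatures(
        norm, list(signatures.values()), config.scoring
    )
    score_table.to_csv(os.path.join(config.out_dir, "module_scores.tsv"), sep="\t")
    contrasts = scm.compare_scores_between_protocols(score_table, norm.obs)
    contrasts.to_csv(
        os.path.join(config.out_dir, "score_contrasts.tsv"), sep="\t", index=False
    )
    report["score_contrasts"] = contrasts.to_dict(orient="records")
    report["score_means"] = {
        sig: {
            prot: float(score_table.loc[norm.obs["protocol"] == prot, sig].mean())
            for prot in norm.obs["protocol"].unique()
        }
        for sig in score_table.columns
    }

    a, b = config.contrast
    mask_a = (norm.obs["protocol"] == a).to_numpy()
    mask_b = (norm.obs["protocol"] == b).to_numpy()
    de_table = de.wilcoxon_de(norm, mask_a, mask_b, config.de)
    de_table.to_csv(
        os.path.join(config.out_dir, f"de_{a}_vs_{b}.tsv"), sep="\t", index=False
    )
    set_a, set_b = de.filter_de(
        de_table, config.de, name_a=f"enriched_in_{a}", name_b=f"enriched_in_{b}"
    )
    report["de"] = {
        "contrast": [a, b],
        "n_enriched_a": len(set_a) if set_a else 0,
        "n_enriched_b": len(set_b) if set_b else 0,
    }

    fractions = de.quartile_enrichment_fractions({a: set_a, b: set_b}, labels)
    fractions.to_csv(
        os.path.join(config.out_dir, "quartile_fractions.tsv"), sep="\t", index=False
    )
    report["quartile_fractions"] = fractions.to_dict(orient="records")
    if set_a is not None and set_b is not None:
        lengths = pd.Series(
            models["length_nt"].to_numpy(float), index=models["gene_id"]
        )
        report["length_comparison"] = de.gene_length_comparison(set_b, set_a, lengths)

    _stage_classify(norm, signatures, config, report)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis from files on disk; returns the report dict.

    The annotation stage is skipped when ``gene_table.tsv`` already exists in
    the output directory (unless ``force``), so re-runs reuse intermediates.
    """
    if config.counts_path is None:
        raise ValueError("counts_path is required (use demo() for synthetic data)")
    os.makedirs(config.out_dir, exist_ok=True)
    gene_table_path = os.path.join(config.out_dir, "gene_table.tsv")
    if os.path.exists(gene_table_path) and not config.force:
        gene_table = sio.read_gene_table(gene_table_path)
    else:
        if config.gtf_path is None or config.fasta_path is None:
            raise ValueError("fasta_path and gtf_path are required to annotate")
        gene_table = ann.load_gene_models(
            config.gtf_path, config.fasta_path, config.annotation
        )
        sio.write_gene_table(gene_table, gene_table_path)

    adata = qcm.read_counts(
        config.counts_path, config.counts_format, meta_path=config.meta_path
    )
    common = [g for g in adata.var_names if g in set(gene_table["gene_id"])]
    if not common:
        raise ValueError("no overlap between counts and annotation gene ids")
    adata = adata[:, common].copy()

    signatures = {}
    for path in config.signature_files:
        s = sio.read_signature(path)
        signatures[s.name] = s

    report = _core_stages(adata, gene_table, signatures, config)

    if config.region_fractions_path:
        rf = pd.read_csv(config.region_fractions_path, sep="\t")
        summary, tests = de.summarize_region_fractions(rf)
        tests.to_csv(
            os.path.join(config.out_dir, "region_fraction_tests.tsv"),
            sep="\t",
            index=False,
        )
        report["region_fractions"] = tests.to_dict(orient="records")

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def demo(seed: int = 0, out_dir: str = "snbias_demo", config: PipelineConfig | None = None) -> dict:
    """Synthesize a planted-bias experiment and run the full pipeline on it.

    Uses a deliberately small universe (2,000 genes, 150 cells per protocol,
    short genes) so the whole run takes seconds; the report includes a
    planted-vs-recovered section and a toy-genome annotation round-trip
    check.
    """
    if config is None:
        config = PipelineConfig(out_dir=out_dir, seed=seed, baseline_reps=5)
        config.simulation = sim.SimulationConfig(
            seed=seed,
            n_genes=2000,
            n_cells_per_protocol=150,
            length_log_mean=6.5,
            length_log_sd=1.0,
            polya_rate_per_nt=3e-3,
            n_lncrna=100,
            n_fusion=25,
        )
        config.split = clf.SplitSpec(seed=seed)
        config.scoring = scm.ScoringParams(seed=seed)
    os.makedirs(config.out_dir, exist_ok=True)

    universe = sim.simulate_gene_universe(config.simulation)
    adata = sim.simulate_experiment(universe, config.simulation)
    sim.write_counts(adata, os.path.join(config.out_dir, "counts"))

    # toy-genome round trip on a subset: annotation must recover the truth
    subset = universe.head(100)
    fasta = os.path.join(config.out_dir, "toy_genome.fa")
    gtf = os.path.join(config.out_dir, "toy_genes.gtf")
    sim.write_toy_genome(subset, fasta, gtf, seed=config.seed)
    recovered = ann.load_gene_models(gtf, fasta, config.annotation)
    merged = subset.merge(recovered, on="gene_id", suffixes=("_true", ""))
    roundtrip_exact = bool(
        (merged["length_nt_true"] == merged["length_nt"]).all()
        and (merged["polya_count_true"] == merged["polya_count"]).all()
    )

    gene_table = universe.copy()
    sio.write_gene_table(gene_table, os.path.join(config.out_dir, "gene_table.tsv"))
    planted = sim.signatures_from_universe(universe)
    signatures = {
        "warm_dissociation": ann.SignatureSet(
            "warm_dissociation", planted["warm_dissociation"]
        ),
        "lncRNA": ann.SignatureSet("lncRNA", planted["lncRNA"]),
    }

    report = _core_stages(adata, gene_table, signatures, config)

    rf = sim.simulate_region_fractions(config.simulation)
    rf.to_csv(
        os.path.join(config.out_dir, "region_fractions.tsv"), sep="\t", index=False
    )
    summary, tests = de.summarize_region_fractions(rf)
    report["region_fractions"] = tests.to_dict(orient="records")

    report["planted"] = {
        "n_stress": int(universe["is_stress"].sum()),
        "n_lncrna": int(universe["is_lncrna"].sum()),
        "warm_stress_fold": config.simulation.warm_stress_fold,
        "nuclei_polya_capture_coef": config.simulation.nuclei_polya_capture_coef,
        "toy_genome_roundtrip_exact": roundtrip_exact,
        "n_cells_simulated": int(adata.n_obs),
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
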