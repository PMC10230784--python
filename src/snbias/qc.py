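"""Count-matrix ingestion, MAD-based cell QC, and log-normalization.

QC follows robust-outlier practice: per-cell UMI and gene counts are tested
(on the log1p scale by default) against median +/- n_mads * MAD bounds,
mitochondrial percentage against an upper bound only, and hard floors
("generic cut-offs") back the adaptive bounds. Filtering is applied per
sample, never pooled, since depth and complexity differ by sample and
protocol.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

__all__ = [
    "QCParams",
    "read_counts",
    "compute_qc_metrics",
    "mad_filter",
    "apply_qc",
    "lognormalize",
]

#: Consistency constant making the MAD unbiased for the SD under normality.
MAD_SCALE = 1.4826


@dataclass
class QCParams:
    n_mads: float = 2.0
    log_metrics: bool = True       # MAD-filter log1p(n_umi), log1p(n_genes)
    mito_upper_only: bool = True   # high %mito is harmful; low is not
    min_genes: int = 200           # hard floors backing the adaptive bounds
    min_umis: int = 500

    def __post_init__(self):
        if self.n_mads <= 0:
            raise ValueError("n_mads must be > 0")


def _attach_meta(adata: ad.AnnData, meta: pd.DataFrame | None) -> ad.AnnData:
    if meta is None:
        return adata
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} barcodes lack metadata rows, e.g. {list(missing[:5])}"
        )
    for col in meta.columns:
        adata.obs[col] = meta.loc[adata.obs_names, col].to_numpy()
    return adata


def read_counts(path, format: str = "mtx_dir", meta_path=None) -> ad.AnnData:
    """Read a UMI count matrix into AnnData (cells x genes, sparse int X).

    ``mtx_dir`` expects a 10x-style triplet directory (``matrix.mtx`` genes x
    cells, ``features.tsv``, ``barcodes.tsv``); ``dense_tsv`` a genes-rows x
    cells-columns table with gene ids in the first column and barcodes in the
    header. Cell metadata (TSV indexed by barcode, or ``cell_meta.tsv``
    inside an MTX directory) is joined by barcode; unmatched barcodes are an
    error.
    """
    if format == "mtx_dir":
        mat = mmread(os.path.join(path, "matrix.mtx"))
        features = pd.read_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=None
        )
        barcodes = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        )[0].astype(str)
        gene_ids = features[0].astype(str)
        if mat.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"matrix.mtx is {mat.shape} but ids imply "
                f"{(len(gene_ids), len(barcodes))}"
            )
        X = sp.csr_matrix(mat.T)
        if meta_path is None:
            default_meta = os.path.join(path, "cell_meta.tsv")
            meta_path = default_meta if os.path.exists(default_meta) else None
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = pd.Series(df.index.astype(str))
        barcodes = pd.Series(df.columns.astype(str))
        X = sp.csr_matrix(df.to_numpy().T)
    else:
        raise ValueError(f"unknown format {format!r}")

    data = X.data
    if data.size and (np.any(data < 0) or np.any(data != np.rint(data))):
        raise ValueError("counts must be non-negative integers")
    X = X.astype(np.int64)
    if gene_ids.duplicated().any():
        dups = gene_ids[gene_ids.duplicated()].unique()
        raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
    if barcodes.duplicated().any():
        raise ValueError("duplicate barcodes")

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {"gene_id": gene_ids.to_numpy()}, index=pd.Index(gene_ids, name=None)
        ),
    )
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        _attach_meta(adata, meta)
    return adata


def compute_qc_metrics(adata: ad.AnnData, mito_gene_ids) -> pd.DataFrame:
    """Per-cell n_umi, n_genes (count > 0) and pct_mito (0 for empty cells)."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = sp.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_ids = [g for g in mito_gene_ids if g in adata.var_names]
    missing = set(mito_gene_ids) - set(mito_ids)
    if missing:
        warnings.warn(f"{len(missing)} mito gene ids absent from the matrix")
    if mito_ids:
        idx = adata.var_names.get_indexer(mito_ids)
        mito_umi = np.asarray(X[:, idx].sum(axis=1)).ravel()
    else:
        mito_umi = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_umi": n_umi.astype(np.int64), "n_genes": n_genes.astype(np.int64),
         "pct_mito": pct},
        index=adata.obs_names.copy(),
    )


def mad_filter(values, n_mads: float, two_sided: bool = True) -> np.ndarray:
    """Keep-mask for values within median +/- n_mads * scaled MAD.

    MAD = 1.4826 * median(|x - median|). When the MAD is zero (over half the
    values tied at the median) only the median value is kept. One-sided mode
    applies the upper bound only.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_filter needs at least one value")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    if mad == 0:
        return x == med
    upper = med + n_mads * mad
    if two_sided:
        lower = med - n_mads * mad
        return (x >= lower) & (x <= upper)
    return x <= upper


def apply_qc(
    adata: ad.AnnData, qc: pd.DataFrame, params: QCParams | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells per sample by MAD bounds plus hard floors.

    A cell passes if, within its sample: log1p(n_umi) and log1p(n_genes)
    (raw values if ``log_metrics`` is off) lie within two-sided MAD bounds,
    pct_mito lies below its upper MAD bound, and the floors are met. Returns
    the filtered matrix and a per-sample report of pre/post cell counts.
    """
    params = params or QCParams()
    if not qc.index.equals(adata.obs_names):
        qc = qc.loc[adata.obs_names]
    samples = (
        adata.obs["sample_id"]
        if "sample_id" in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    keep = np.zeros(adata.n_obs, dtype=bool)
    report_rows = []
    for sample, idx in samples.groupby(samples, observed=True).groups.items():
        loc = adata.obs_names.get_indexer(idx)
        sub = qc.iloc[loc]
        umi = np.log1p(sub["n_umi"]) if params.log_metrics else sub["n_umi"]
        genes = np.log1p(sub["n_genes"]) if params.log_metrics else sub["n_genes"]
        mask = mad_filter(umi, params.n_mads, two_sided=True)
        mask &= mad_filter(genes, params.n_mads, two_sided=True)
        mask &= mad_filter(
            sub["pct_mito"], params.n_mads, two_sided=not params.mito_upper_only
        )
        mask &= (sub["n_genes"] >= params.min_genes).to_numpy()
        mask &= (sub["n_umi"] >= params.min_umis).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"QC removed every cell of sample {sample!r}")
        keep[loc] = mask
        report_rows.append(
            {"sample_id": sample, "n_pre": len(sub), "n_post": int(mask.sum())}
        )
    filtered = adata[keep].copy()
    filtered.obs["qc_pass"] = True
    report = pd.DataFrame(report_rows)
    return filtered, report


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: value = ln(1 + count * sf / depth).

    Returns a copy with float X (raw counts kept in ``layers['counts']``).
    Zero-depth cells become all-zero columns with a warning.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = sp.csr_matrix(adata.X)
    if X.data.size and X.data.min() < 0:
        raise ValueError("negative counts")
    depth = np.asarray(X.sum(axis=1)).ravel()
    if np.any(depth == 0):
        warnings.warn(f"{int((depth == 0).sum())} zero-depth cells left all-zero")
    scale = np.where(depth > 0, scale_factor / np.maximum(depth, 1), 0.0)
    norm = sp.diags(scale) @ X.astype(float)
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.layers["counts"] = X
    out.X = norm.tocsr()
    out.uns["scale_factor"] = scale_factor
    return out
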