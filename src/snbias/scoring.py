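"""Module scoring with expression-matched binned controls.

A cell's score for a gene set is the mean normalized expression of the set
minus the mean over control genes drawn from the same average-expression
strata: genes are ranked by mean expression across cells, cut into
``n_bins`` equal-frequency bins, and each signature gene contributes
``n_ctrl`` control genes sampled without replacement from its bin. Under
the null (the set is exchangeable with its bins) the score is centered at
zero; dissociation stress or nuclear capture bias shifts it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._rng import substream
from .annotation import SignatureSet

__all__ = [
    "ScoringParams",
    "module_score",
    "score_signatures",
    "compare_scores_between_protocols",
]


@dataclass
class ScoringParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0
    exclude_signature_from_controls: bool = False

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


def _dense_col_mean(X, cols: np.ndarray) -> np.ndarray:
    """Mean over a (multiset of) columns, per row."""
    return np.asarray(X[:, cols].mean(axis=1)).ravel()


def module_score(
    norm: ad.AnnData, sig: SignatureSet, params: ScoringParams | None = None
) -> pd.Series:
    """Per-cell module score of one signature on log-normalized data.

    Bins are equal-frequency on the across-cell mean expression, with ties
    broken by gene id so binning is reproducible. Control draws are seeded
    from ``params.seed``; a bin smaller than ``n_ctrl`` contributes all its
    genes. The score subtracts the mean over the multiset union of control
    draws, so controls drawn for several signature genes count once per draw.
    """
    params = params or ScoringParams()
    n_genes = norm.n_vars
    if n_genes < params.n_bins:
        raise ValueError(
            f"{n_genes} genes < n_bins={params.n_bins}: cannot stratify"
        )
    present = [g for g in sig.gene_ids if g in norm.var_names]
    dropped = len(sig.gene_ids) - len(present)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is in the matrix")
    if dropped:
        warnings.warn(f"signature {sig.name!r}: {dropped} genes absent, dropped")

    X = norm.X
    means = np.asarray(X.mean(axis=0)).ravel()
    gene_ids = norm.var_names.to_numpy(dtype=object)
    order = np.lexsort((gene_ids, means))  # mean asc, gene id breaks ties
    ranks = np.empty(n_genes, dtype=np.int64)
    ranks[order] = np.arange(n_genes)
    bin_of = ranks * params.n_bins // n_genes

    sig_idx = norm.var_names.get_indexer(present)
    sig_set = set(sig_idx.tolist())
    rng = substream(params.seed, "module-score")
    ctrl_draws: list[np.ndarray] = []
    bin_members: dict[int, np.ndarray] = {}
    for gi in sig_idx:
        b = bin_of[gi]
        if b not in bin_members:
            members = np.flatnonzero(bin_of == b)
            if params.exclude_signature_from_controls:
                members = members[[m not in sig_set for m in members]]
            bin_members[b] = members
        pool = bin_members[b]
        if len(pool) <= params.n_ctrl:
            ctrl_draws.append(pool)
        else:
            ctrl_draws.append(rng.choice(pool, size=params.n_ctrl, replace=False))
    ctrl_idx = np.concatenate(ctrl_draws)

    score = _dense_col_mean(X, sig_idx) - _dense_col_mean(X, ctrl_idx)
    return pd.Series(score, index=norm.obs_names.copy(), name=sig.name)


def score_signatures(
    norm: ad.AnnData,
    signatures: list[SignatureSet],
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """One module-score column per signature (cells x signatures).

    Each column re-seeds the control stream identically, so scores do not
    depend on the order signatures are requested in.
    """
    params = params or ScoringParams()
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names")
    return pd.DataFrame({s.name: module_score(norm, s, params) for s in signatures})


def compare_scores_between_protocols(
    table: pd.DataFrame, cell_meta: pd.DataFrame, group_col: str = "protocol"
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests per signature, Bonferroni-corrected.

    The correction multiplies each raw p by the number of group pairs for
    that signature (post-hoc family per signature), capping at 1.
    """
    groups = cell_meta.loc[table.index, group_col]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups to compare")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 cells")
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for sig in table.columns:
        for a, b in pairs:
            xa = table.loc[groups == a, sig].to_numpy()
            xb = table.loc[groups == b, sig].to_numpy()
            pooled = np.concatenate([xa, xb])
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            rows.append(
                {
                    "signature": sig,
                    "group_a": a,
                    "group_b": b,
                    "p": float(p),
                    "p_bonferroni": min(1.0, float(p) * len(pairs)),
                }
            )
    return pd.DataFrame(rows)
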