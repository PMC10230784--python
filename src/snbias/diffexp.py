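"""Wilcoxon differential expression between protocols and length-bias tests.

Per gene, a two-sided Mann-Whitney rank-sum test compares normalized
expression between two cell groups: exact enumeration over all group
assignments when both groups have <= 8 cells, otherwise the tie-corrected
normal approximation (no continuity correction, which calibrates better on
heavily tied count data). Fold change is computed on de-logged means with a
pseudocount, log2((mean_A + c) / (mean_B + c)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import SignatureSet

__all__ = [
    "DEParams",
    "wilcoxon_de",
    "filter_de",
    "consensus_genes",
    "overrepresentation_test",
    "quartile_enrichment_fractions",
    "gene_length_comparison",
    "summarize_region_fractions",
]

EXACT_MAX_N = 8  # both groups at or below this size -> exhaustive enumeration


@dataclass
class DEParams:
    lfc_threshold: float = math.log2(1.5)
    alpha: float = 0.05
    p_adjust: str = "bonferroni"  # or "bh"
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.p_adjust not in ("bonferroni", "bh"):
            raise ValueError("p_adjust must be 'bonferroni' or 'bh'")


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided permutation p of the rank-sum statistic by full enumeration
    of all C(n_a + n_b, n_a) group assignments (midranks handle ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = len(pooled), len(a)
    expected = na * (n + 1) / 2.0
    observed = abs(ranks[:na].sum() - expected)
    hits = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - expected) >= observed - 1e-9:
            hits += 1
    return hits / total


def _asymptotic_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    )


def _resolve_groups(norm: ad.AnnData, group) -> np.ndarray:
    """Accept barcode lists or boolean masks; return positional indices."""
    group = np.asarray(group)
    if group.dtype == bool:
        if group.size != norm.n_obs:
            raise ValueError("boolean group mask has wrong length")
        return np.flatnonzero(group)
    idx = norm.obs_names.get_indexer(group)
    if np.any(idx < 0):
        raise KeyError("group contains barcodes absent from the matrix")
    return idx


def wilcoxon_de(
    norm: ad.AnnData, group_a, group_b, params: DEParams | None = None
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum DE of group A versus group B.

    Returns a table (gene, log2fc, p, p_adj, direction, all_zero) where
    direction marks genes passing both the fold-change and adjusted-p
    thresholds in either group. Genes with no signal in either group get
    p = 1, log2fc = 0 and the ``all_zero`` flag.
    """
    params = params or DEParams()
    ia, ib = _resolve_groups(norm, group_a), _resolve_groups(norm, group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 cells")
    if set(ia) & set(ib):
        raise ValueError("groups overlap")

    Xa = np.asarray(sp.csr_matrix(norm.X)[ia].todense())
    Xb = np.asarray(sp.csr_matrix(norm.X)[ib].todense())
    exact = len(ia) <= EXACT_MAX_N and len(ib) <= EXACT_MAX_N

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + params.pseudocount) / (mean_b + params.pseudocount))

    pvals = np.ones(norm.n_vars)
    all_zero = np.zeros(norm.n_vars, dtype=bool)
    for g in range(norm.n_vars):
        a, b = Xa[:, g], Xb[:, g]
        if not (a.any() or b.any()):
            all_zero[g] = True
            log2fc[g] = 0.0
            continue
        pvals[g] = _exact_ranksum_p(a, b) if exact else _asymptotic_p(a, b)

    method = "bonferroni" if params.p_adjust == "bonferroni" else "fdr_bh"
    p_adj = multipletests(pvals, method=method)[1]
    direction = np.where(
        (log2fc >= params.lfc_threshold) & (p_adj < params.alpha),
        "A",
        np.where((log2fc <= -params.lfc_threshold) & (p_adj < params.alpha), "B", "none"),
    )
    return pd.DataFrame(
        {
            "gene": norm.var_names.to_numpy(),
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "direction": direction,
            "all_zero": all_zero,
        }
    )


def filter_de(
    results: pd.DataFrame,
    params: DEParams | None = None,
    name_a: str = "enriched_in_A",
    name_b: str = "enriched_in_B",
) -> tuple[SignatureSet | None, SignatureSet | None]:
    """Split a DE table into the two enriched gene sets.

    A gene is enriched in A iff log2fc >= lfc_threshold and p_adj < alpha
    (symmetric for B). Returns None in place of an empty set.
    """
    params = params or DEParams()
    up_a = results.loc[
        (results["log2fc"] >= params.lfc_threshold) & (results["p_adj"] < params.alpha),
        "gene",
    ].tolist()
    up_b = results.loc[
        (results["log2fc"] <= -params.lfc_threshold) & (results["p_adj"] < params.alpha),
        "gene",
    ].tolist()
    set_a = SignatureSet(name_a, up_a) if up_a else None
    set_b = SignatureSet(name_b, up_b) if up_b else None
    return set_a, set_b


def consensus_genes(per_subtype_sets: list[SignatureSet]) -> list[str]:
    """Genes enriched in every subtype: set intersection, sorted by id."""
    if not per_subtype_sets:
        raise ValueError("need at least one gene set")
    if len(per_subtype_sets) < 2:
        raise ValueError("consensus requires >= 2 sets")
    common = set(per_subtype_sets[0].gene_ids)
    for s in per_subtype_sets[1:]:
        common &= set(s.gene_ids)
    if not common:
        warnings.warn("consensus is empty")
    return sorted(common)


def overrepresentation_test(
    query: SignatureSet, collection: list[SignatureSet], universe
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric upper tail) per gene set.

    Sets are intersected with the universe; BH adjustment runs across the
    collection. Odds ratios use a Haldane 0.5 correction when any cell of
    the 2x2 table is zero.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    q = set(query.gene_ids) & uset
    if set(query.gene_ids) - uset:
        raise ValueError("query contains genes outside the universe")
    M, nq = len(universe), len(q)
    rows = []
    for s in collection:
        members = set(s.gene_ids) & uset
        k, K = len(q & members), len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, nq)) if K else 1.0
        a, b, c, d = k, nq - k, K - k, M - nq - K + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append(
            {"set_name": s.name, "overlap": k, "set_size": K,
             "p": min(1.0, p), "odds_ratio": (a * d) / (b * c)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def quartile_enrichment_fractions(
    enriched_sets: dict[str, SignatureSet | None], bin_labels: pd.Series
) -> pd.DataFrame:
    """Share of each length bin's enriched genes claimed by each protocol.

    For protocol P and bin Q the default fraction is
    |enriched(P) & Q| / |Q & union of all enriched genes|, so that within a
    bin the protocols' fractions sum to 1 when their sets are disjoint. The
    whole-bin denominator |Q| is also reported (``frac_of_bin``).
    """
    union: set[str] = set()
    for s in enriched_sets.values():
        if s is not None:
            union |= set(s.gene_ids)
    missing = union - set(bin_labels.index)
    if missing:
        raise ValueError(f"{len(missing)} enriched genes lack a length bin")
    rows = []
    for bin_name in bin_labels.cat.categories if hasattr(bin_labels, "cat") else sorted(
        bin_labels.unique()
    ):
        bin_genes = set(bin_labels.index[bin_labels == bin_name])
        denom_enriched = len(bin_genes & union)
        for protocol, s in enriched_sets.items():
            genes = set(s.gene_ids) if s is not None else set()
            k = len(genes & bin_genes)
            rows.append(
                {
                    "protocol": protocol,
                    "length_bin": bin_name,
                    "n_enriched": k,
                    "frac_among_enriched": k / denom_enriched if denom_enriched else 0.0,
                    "frac_of_bin": k / len(bin_genes) if bin_genes else 0.0,
                }
            )
    return pd.DataFrame(rows)


def gene_length_comparison(set_a: SignatureSet, set_b: SignatureSet, lengths: pd.Series) -> dict:
    """Two-sided rank-sum comparison of gene lengths between two sets."""
    overlap = set(set_a.gene_ids) & set(set_b.gene_ids)
    if overlap:
        warnings.warn(f"{len(overlap)} genes are in both sets")
    la = lengths.loc[set_a.gene_ids].to_numpy(float)
    lb = lengths.loc[set_b.gene_ids].to_numpy(float)
    pooled = np.concatenate([la, lb])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(la, lb, alternative="two-sided").pvalue)
    return {
        "p": p,
        "median_a": float(np.median(la)),
        "median_b": float(np.median(lb)),
    }


def summarize_region_fractions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protocol mean +/- SEM of region read fractions, with pairwise
    Welch t-tests per region, Bonferroni-corrected over all pair x region
    comparisons."""
    regions = ["frac_exonic", "frac_intronic", "frac_intergenic"]
    counts = table.groupby("protocol").size()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"protocols with a single sample: {bad}")
    summary = (
        table.groupby("protocol")[regions]
        .agg(["mean", lambda x: x.std(ddof=1) / np.sqrt(len(x))])
        .rename(columns={"<lambda_0>": "sem"}, level=1)
    )
    protocols = sorted(table["protocol"].unique())
    pairs = list(combinations(protocols, 2))
    rows = []
    n_comp = len(pairs) * len(regions)
    for region in regions:
        for a, b in pairs:
            xa = table.loc[table["protocol"] == a, region]
            xb = table.loc[table["protocol"] == b, region]
            if np.allclose(xa.var(ddof=1) + xb.var(ddof=1), 0):
                p = 1.0 if np.isclose(xa.mean(), xb.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            rows.append(
                {"region": region, "group_a": a, "group_b": b, "p": p,
                 "p_bonferroni": min(1.0, p * n_comp)}
            )
    return summary, pd.DataFrame(rows)
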