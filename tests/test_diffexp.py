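import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad
from scipy import stats

import snbias as sb
from snbias import diffexp as dx
from snbias import qc as qcm
from snbias.annotation import SignatureSet


def _norm_from_values(a_vals, b_vals):
    """Build a 'normalized' AnnData with groups A then B (genes as columns)."""
    values = np.vstack([np.atleast_2d(a_vals), np.atleast_2d(b_vals)]).astype(float)
    n = values.shape[0]
    return (
        ad.AnnData(
            X=sp.csr_matrix(values),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(values.shape[1])]),
        ),
        np.arange(len(np.atleast_2d(a_vals))),
        np.arange(len(np.atleast_2d(a_vals)), n),
    )


def brute_force_two_sided_p(a, b):
    """Independent oracle: U statistic by pair counting, p by enumerating all
    group assignments of the pooled values."""

    def u_stat(x, y):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
        )

    pooled = list(a) + list(b)
    na = len(a)
    center = na * len(b) / 2.0
    observed = abs(u_stat(a, b) - center)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        xa = [pooled[i] for i in comb]
        xb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(u_stat(xa, xb) - center) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonDE:
    def test_exact_three_vs_three(self):
        norm, ga, gb = _norm_from_values([[1.0], [2], [3]], [[4.0], [5], [6]])
        res = dx.wilcoxon_de(norm, norm.obs_names[:3], norm.obs_names[3:])
        assert np.isclose(res["p"].iloc[0], 0.1)  # 2 of 20 assignments, two-sided

    def test_identical_groups(self):
        vals = [[1.0, 5], [2, 6], [3, 7]]
        norm, _, _ = _norm_from_values(vals, vals)
        res = dx.wilcoxon_de(norm, norm.obs_names[:3], norm.obs_names[3:])
        assert (res["p"] == 1.0).all()
        assert np.allclose(res["log2fc"], 0.0)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 4), (3, 5)])
    def test_exact_path_matches_pair_counting_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(5):
            a = rng.integers(0, 4, size=(na, 1)).astype(float)  # ties likely
            b = rng.integers(0, 4, size=(nb, 1)).astype(float)
            norm, _, _ = _norm_from_values(a, b)
            res = dx.wilcoxon_de(norm, norm.obs_names[:na], norm.obs_names[na:])
            want = brute_force_two_sided_p(a.ravel(), b.ravel())
            if not (a.any() or b.any()):
                continue
            assert np.isclose(res["p"].iloc[0], want)

    def test_planted_fold_change_recovered(self):
        # one 4-fold gene among background genes, 200 vs 200 cells
        rng = np.random.default_rng(0)
        n = 200
        base = rng.poisson(5.0, size=(2 * n, 50)).astype(float)
        planted = np.concatenate([rng.poisson(20.0, n), rng.poisson(5.0, n)])
        counts = np.column_stack([planted, base])
        adata = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(2 * n)]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(51)]),
        )
        norm = qcm.lognormalize(adata, scale_factor=100)
        res = dx.wilcoxon_de(norm, norm.obs_names[:n], norm.obs_names[n:])
        assert res["p_adj"].iloc[0] < 0.05
        assert 1.5 <= res["log2fc"].iloc[0] <= 2.5

    def test_all_zero_gene_flagged(self):
        norm, _, _ = _norm_from_values([[0.0, 1], [0, 2], [0, 1]], [[0.0, 5], [0, 6], [0, 7]])
        res = dx.wilcoxon_de(norm, norm.obs_names[:3], norm.obs_names[3:])
        assert res["all_zero"].iloc[0]
        assert res["p"].iloc[0] == 1.0 and res["log2fc"].iloc[0] == 0.0

    def test_overlapping_groups_rejected(self):
        norm, _, _ = _norm_from_values([[1.0], [2], [3]], [[4.0], [5], [6]])
        with pytest.raises(ValueError, match="overlap"):
            dx.wilcoxon_de(norm, norm.obs_names[:3], norm.obs_names[2:])

    def test_planted_stress_genes_recovered(self, planted_norm, planted_universe):
        """>= 90% of planted stress genes come out warm-enriched vs nuclei."""
        warm = (planted_norm.obs["protocol"] == "warm").to_numpy()
        nuc = (planted_norm.obs["protocol"] == "nuclei").to_numpy()
        res = dx.wilcoxon_de(planted_norm, warm, nuc)
        up_warm, up_nuc = dx.filter_de(res)
        stress = set(planted_universe.loc[planted_universe["is_stress"], "gene_id"])
        recovered = len(stress & set(up_warm.gene_ids)) / len(stress)
        assert recovered >= 0.9
        assert up_nuc is not None and len(up_nuc) > len(up_warm)  # polyA tilt


class TestFilterDE:
    def _frame(self, log2fc, p_adj):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(log2fc))],
             "log2fc": log2fc, "p": p_adj, "p_adj": p_adj}
        )

    def test_threshold_is_strict_log2_1_5(self):
        res = self._frame([1.0, 0.58, math.log2(1.5)], [0.01, 1e-9, 0.01])
        up_a, _ = dx.filter_de(res)
        assert up_a.gene_ids == ["g0", "g2"]  # 0.58 < log2(1.5) = 0.585

    def test_sign_assignment_in_the_permissive_limit(self):
        res = self._frame([0.3, -0.2, 0.0], [0.5, 0.5, 0.5])
        params = dx.DEParams(lfc_threshold=0.0, alpha=0.999)
        up_a, up_b = dx.filter_de(res, params)
        assert up_a.gene_ids == ["g0", "g2"] and up_b.gene_ids == ["g1", "g2"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        res = self._frame(rng.normal(0, 1, 100), rng.uniform(0, 1, 100))
        loose_a, _ = dx.filter_de(res, dx.DEParams(lfc_threshold=0.2, alpha=0.3))
        tight_a, _ = dx.filter_de(res, dx.DEParams(lfc_threshold=0.6, alpha=0.05))
        tight = set(tight_a.gene_ids) if tight_a else set()
        assert tight <= set(loose_a.gene_ids)


class TestConsensus:
    def test_intersection(self):
        sets = [SignatureSet("a", ["a", "b", "c"]), SignatureSet("b", ["b", "c", "d"]),
                SignatureSet("c", ["c"])]
        assert dx.consensus_genes(sets) == ["c"]

    def test_identical_sets(self):
        sets = [SignatureSet("a", ["x", "y"]), SignatureSet("b", ["y", "x"])]
        assert dx.consensus_genes(sets) == ["x", "y"]

    def test_disjoint_sets_warn_empty(self):
        sets = [SignatureSet("a", ["x"]), SignatureSet("b", ["y"])]
        with pytest.warns(UserWarning, match="empty"):
            assert dx.consensus_genes(sets) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dx.consensus_genes([])


class TestOverrepresentation:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        query = SignatureSet("q", universe[:5])
        res = dx.overrepresentation_test(query, [SignatureSet("s", universe[:5])], universe)
        assert np.isclose(res["p"].iloc[0], 1 / math.comb(20, 5))

    def test_set_equal_to_universe(self):
        universe = [f"g{i}" for i in range(10)]
        res = dx.overrepresentation_test(
            SignatureSet("q", universe[:3]), [SignatureSet("s", universe)], universe
        )
        assert res["p"].iloc[0] == 1.0

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        res = dx.overrepresentation_test(
            SignatureSet("q", universe[:3]), [SignatureSet("s", universe[5:7])], universe
        )
        assert res["p"].iloc[0] == 1.0
        assert res["overlap"].iloc[0] == 0

    def test_matches_direct_hypergeometric_summation(self):
        # exhaustive check over all tables on a 25-gene universe
        M = 25
        universe = [f"g{i}" for i in range(M)]
        for nq in (1, 5, 12):
            for K in (1, 6, 20):
                for k in range(0, min(nq, K) + 1):
                    query = SignatureSet("q", universe[:nq])
                    members = universe[:k] + universe[nq : nq + (K - k)]
                    res = dx.overrepresentation_test(
                        query, [SignatureSet("s", members)], universe
                    )
                    direct = sum(
                        math.comb(K, j) * math.comb(M - K, nq - j) / math.comb(M, nq)
                        for j in range(k, min(nq, K) + 1)
                    )
                    assert np.isclose(res["p"].iloc[0], min(1.0, direct))


class TestQuartileFractions:
    def _bins(self, labels_by_gene):
        s = pd.Series(labels_by_gene)
        return pd.Series(
            pd.Categorical(s, categories=sb.annotation.QUARTILE_LABELS, ordered=True),
            index=s.index,
        )

    def test_two_protocol_toy(self):
        labels = self._bins(
            {"g1": "Short", "g2": "Short", "g3": "Long", "g4": "Long",
             "g5": "Short Med.", "g6": "Short Med.", "g7": "Long Med.", "g8": "Long Med."}
        )
        res = dx.quartile_enrichment_fractions(
            {"nuclei": SignatureSet("n", ["g3", "g4"]),
             "warm": SignatureSet("w", ["g1", "g2"])},
            labels,
        )
        piv = res.pivot(index="length_bin", columns="protocol",
                        values="frac_among_enriched")
        assert piv.loc["Long", "nuclei"] == 1.0
        assert piv.loc["Short", "warm"] == 1.0
        assert piv.loc["Long", "warm"] == 0.0

    def test_empty_protocol_set_gives_zeros(self):
        labels = self._bins({"g1": "Short", "g2": "Long"})
        res = dx.quartile_enrichment_fractions(
            {"nuclei": SignatureSet("n", ["g2"]), "warm": None}, labels
        )
        warm = res[res["protocol"] == "warm"]
        assert (warm["frac_among_enriched"] == 0).all()

    def test_unlabeled_enriched_gene_rejected(self):
        labels = self._bins({"g1": "Short"})
        with pytest.raises(ValueError, match="lack"):
            dx.quartile_enrichment_fractions(
                {"nuclei": SignatureSet("n", ["g1", "gX"])}, labels
            )

    def test_planted_nuclei_enrichment_peaks_in_long_bin(
        self, planted_norm, planted_universe
    ):
        warm = (planted_norm.obs["protocol"] == "warm").to_numpy()
        nuc = (planted_norm.obs["protocol"] == "nuclei").to_numpy()
        res = dx.wilcoxon_de(planted_norm, warm, nuc)
        up_warm, up_nuc = dx.filter_de(res)
        _, labels = sb.assign_length_quartiles(
            pd.Series(planted_universe["length_nt"].to_numpy(),
                      index=planted_universe["gene_id"])
        )
        fr = dx.quartile_enrichment_fractions(
            {"warm": up_warm, "nuclei": up_nuc}, labels
        )
        nuc_frac = fr[fr["protocol"] == "nuclei"].set_index("length_bin")[
            "frac_among_enriched"
        ]
        assert nuc_frac.idxmax() == "Long"
        assert nuc_frac.idxmin() == "Short"


class TestGeneLengths:
    def test_identical_length_multisets(self):
        lengths = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0, "d": 5.0})
        res = dx.gene_length_comparison(
            SignatureSet("x", ["a", "b"]), SignatureSet("y", ["c", "d"]), lengths
        )
        assert res["p"] == 1.0

    def test_strongly_shifted_lengths(self):
        lengths = pd.Series(
            {f"a{i}": float(i) for i in range(1, 51)}
            | {f"b{i}": float(1000 + i) for i in range(1, 51)}
        )
        res = dx.gene_length_comparison(
            SignatureSet("x", [f"a{i}" for i in range(1, 51)]),
            SignatureSet("y", [f"b{i}" for i in range(1, 51)]),
            lengths,
        )
        assert res["p"] < 1e-15
        assert res["median_b"] > res["median_a"]

    def test_singleton_sets_are_defined(self):
        lengths = pd.Series({"a": 1.0, "b": 2.0})
        res = dx.gene_length_comparison(
            SignatureSet("x", ["a"]), SignatureSet("y", ["b"]), lengths
        )
        assert 0 < res["p"] <= 1

    def test_overlapping_sets_warn(self):
        lengths = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.warns(UserWarning, match="both sets"):
            dx.gene_length_comparison(
                SignatureSet("x", ["a", "b"]), SignatureSet("y", ["b", "c"]), lengths
            )


class TestRegionFractionSummary:
    def _table(self, by_protocol):
        rows = []
        for protocol, cols in by_protocol.items():
            for i, (e, intr, inter) in enumerate(cols):
                rows.append(
                    {"sample_id": f"{protocol}-{i}", "protocol": protocol,
                     "frac_exonic": e, "frac_intronic": intr, "frac_intergenic": inter}
                )
        return pd.DataFrame(rows)

    def test_identical_protocols_give_p_one(self):
        vals = [(0.4, 0.3, 0.3), (0.5, 0.2, 0.3), (0.45, 0.25, 0.3)]
        table = self._table({"warm": vals, "nuclei": vals})
        _, tests = dx.summarize_region_fractions(table)
        assert (tests["p_bonferroni"] == 1.0).all()

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(0)
        warm = [(0.5, x, 0.5 - x) for x in 0.24 + 0.05 * rng.standard_normal(6)]
        nuc = [(0.2, x, 0.8 - x) for x in 0.52 + 0.05 * rng.standard_normal(6)]
        table = self._table({"warm": warm, "nuclei": nuc})
        _, tests = dx.summarize_region_fractions(table)
        intronic = tests[tests["region"] == "frac_intronic"]
        assert (intronic["p_bonferroni"] < 0.001).all()

    def test_sem_definition(self):
        table = self._table({"a": [(0.2, 0.3, 0.5), (0.4, 0.3, 0.3), (0.6, 0.3, 0.1)],
                             "b": [(0.3, 0.3, 0.4), (0.3, 0.3, 0.4)]})
        summary, _ = dx.summarize_region_fractions(table)
        x = np.array([0.2, 0.4, 0.6])
        want = x.std(ddof=1) / np.sqrt(3)
        assert np.isclose(summary.loc["a", ("frac_exonic", "sem")], want)
        assert np.isclose(summary.loc["a", ("frac_exonic", "mean")], 0.4)

    def test_single_sample_protocol_rejected(self):
        table = self._table({"a": [(0.2, 0.3, 0.5)], "b": [(0.3, 0.3, 0.4), (0.1, 0.4, 0.5)]})
        with pytest.raises(ValueError, match="single sample"):
            dx.summarize_region_fractions(table)

    def test_simulated_fractions_recover_protocol_contrast(self, small_config):
        rf = sb.simulate_region_fractions(small_config, n_samples=6)
        _, tests = dx.summarize_region_fractions(rf)
        intronic = tests[
            (tests["region"] == "frac_intronic")
            & (tests["group_a"] != "cold") & (tests["group_b"] == "nuclei")
        ]
        assert (intronic["p_bonferroni"] < 0.01).all()
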