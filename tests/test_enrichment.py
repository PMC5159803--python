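"""GSEA, hypergeometric enrichment and over-representation analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from polarmir import cluster_ora, gsea, hypergeom_heatmap, mirna_pathway_gsea
from polarmir.enrichment import hypergeom_pvalue


def hypergeom_oracle(N, K, n, k) -> float:
    """Upper-tail probability by direct summation of the density."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def es_oracle(metric: np.ndarray, hit: np.ndarray, w: float) -> float:
    """Running-sum enrichment score computed with an explicit loop."""
    K = hit.sum()
    N = len(metric)
    weights = np.abs(metric) ** w
    total = weights[hit].sum()
    run, best = 0.0, 0.0
    for i in range(N):
        if hit[i]:
            run += weights[i] / total if total > 0 else 1.0 / K
        else:
            run -= 1.0 / (N - K)
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def test_all_hits_at_top_give_unit_score(self):
        genes = [f"G{i:02d}" for i in range(20)]
        ranked = pd.Series(np.arange(20, 0, -1, dtype=float), index=genes)
        res = gsea(ranked, set(genes[:5]), weight_exponent=0.0, n_perm=200, seed=0)
        assert res.es == pytest.approx(1.0)
        assert sorted(res.leading_edge) == sorted(genes[:5])

    def test_set_covering_entire_list_not_testable(self):
        genes = [f"G{i}" for i in range(10)]
        ranked = pd.Series(np.arange(10.0), index=genes)
        res = gsea(ranked, set(genes), n_perm=100, seed=0)
        assert not res.testable and np.isnan(res.es)

    def test_disjoint_set_not_testable(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        res = gsea(ranked, {"x", "y"}, n_perm=100, seed=0)
        assert not res.testable

    def test_permutation_p_matches_enumeration_oracle(self):
        """20-gene list, 5-gene set, w=0: the permutation p agrees with the
        exact p from full enumeration of all C(20,5) hit placements."""
        rng = np.random.default_rng(0)
        genes = [f"G{i:02d}" for i in range(20)]
        metric = np.sort(rng.normal(size=20))[::-1]
        ranked = pd.Series(metric, index=genes)
        gene_set = set(rng.choice(genes, size=5, replace=False))
        res = gsea(ranked, gene_set, weight_exponent=0.0, n_perm=2000, seed=1)

        null_es = []
        for pos in itertools.combinations(range(20), 5):
            hit = np.zeros(20, dtype=bool)
            hit[list(pos)] = True
            null_es.append(es_oracle(metric, hit, 0.0))
        null_es = np.asarray(null_es)
        same = null_es[null_es >= 0] if res.es >= 0 else null_es[null_es < 0]
        extreme = (same >= res.es) if res.es >= 0 else (same <= res.es)
        exact_p = extreme.sum() / len(same)
        se = math.sqrt(exact_p * (1 - exact_p) / 2000)
        assert abs(res.pvalue - exact_p) < 3 * se + 1 / 2001

    def test_es_invariant_under_monotone_metric_transform_at_w0(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        metric = rng.normal(size=30)
        ranked = pd.Series(metric, index=genes)
        gene_set = set(rng.choice(genes, size=8, replace=False))
        a = gsea(ranked, gene_set, weight_exponent=0.0, n_perm=100, seed=3)
        b = gsea(pd.Series(np.exp(metric), index=genes), gene_set,
                 weight_exponent=0.0, n_perm=100, seed=3)
        assert a.es == pytest.approx(b.es, abs=1e-12)
        assert sorted(a.leading_edge) == sorted(b.leading_edge)

    def test_es_matches_loop_oracle_with_weighting(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i:03d}" for i in range(50)]
        metric = rng.normal(size=50)
        ranked = pd.Series(metric, index=genes)
        order = np.argsort([-m for m in metric], kind="mergesort")
        for _ in range(10):
            gene_set = set(rng.choice(genes, size=10, replace=False))
            res = gsea(ranked, gene_set, weight_exponent=1.0, n_perm=100, seed=5)
            sorted_metric = metric[order]
            hit = np.isin(np.array(genes)[order], list(gene_set))
            assert res.es == pytest.approx(es_oracle(sorted_metric, hit, 1.0), abs=1e-12)

    def test_leading_edge_subset_and_side(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(40)]
        ranked = pd.Series(rng.normal(size=40), index=genes)
        gene_set = set(rng.choice(genes, size=10, replace=False))
        res = gsea(ranked, gene_set, n_perm=100, seed=7)
        assert set(res.leading_edge) <= gene_set

    def test_seeded_reproducibility(self):
        ranked = pd.Series(np.arange(30.0)[::-1], index=[f"G{i}" for i in range(30)])
        s = {f"G{i}" for i in range(0, 30, 4)}
        a = gsea(ranked, s, n_perm=500, seed=42)
        b = gsea(ranked, s, n_perm=500, seed=42)
        assert a.pvalue == b.pvalue and a.nes == b.nes

    def test_false_positive_rate_calibrated_under_null(self):
        """Random gene sets against a random ranked list are significant at
        p < 0.05 about 5% of the time (binomial 99% bounds)."""
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(150)]
        ranked = pd.Series(rng.normal(size=150), index=genes)
        n_sets = 250
        hits = 0
        for _ in range(n_sets):
            s = set(rng.choice(genes, size=12, replace=False))
            res = gsea(ranked, s, weight_exponent=1.0, n_perm=499,
                       seed=int(rng.integers(2**31)))
            hits += res.pvalue < 0.05
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_sets)
        assert abs(hits / n_sets - 0.05) < half_width


class TestHypergeom:
    def test_worked_example(self):
        assert hypergeom_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_zero_draw(self):
        assert hypergeom_pvalue(10, 5, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            N = int(rng.integers(5, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_pvalue(N, K, n, k) == pytest.approx(
                hypergeom_oracle(N, K, n, k), abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_pvalue(40, 12, 10, k) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestHypergeomHeatmap:
    def _de_table(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(100)]
        lfc = rng.normal(0, 0.2, size=(100, 2))
        lfc[:20] += 3.0  # DE at both time points
        return pd.DataFrame({
            "log2fc_1h": lfc[:, 0], "log2fc_2h": lfc[:, 1],
            "adj_pvalue": [0.001] * 20 + [0.9] * 80,
        }, index=genes)

    def test_enriched_targets_flagged(self):
        de = self._de_table()
        targets = pd.DataFrame({"mirna_id": ["m"] * 10, "gene_id": [f"g{i}" for i in range(10)]})
        cells = hypergeom_heatmap(targets, de)
        assert (cells["significant"]).all()
        assert (cells["k"] == 10).all()

    def test_zero_target_mirna_not_testable(self):
        de = self._de_table()
        targets = pd.DataFrame({"mirna_id": ["m"], "gene_id": ["absent"]})
        cells = hypergeom_heatmap(targets, de)
        assert (~cells["testable"]).all()
        assert (cells["pvalue"] == 1.0).all()

    def test_bh_joint_across_cells(self):
        de = self._de_table()
        targets = pd.DataFrame({
            "mirna_id": ["m1"] * 10 + ["m2"] * 10,
            "gene_id": [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(50, 60)],
        })
        cells = hypergeom_heatmap(targets, de)
        testable = cells[cells["testable"]]
        from polarmir.stats import bh_adjust

        np.testing.assert_allclose(testable["adj_pvalue"],
                                   bh_adjust(testable["pvalue"].to_numpy()), atol=1e-12)


class TestClusterOra:
    def test_planted_pathway_tops_its_cluster(self):
        genes = [f"g{i}" for i in range(200)]
        assignments = pd.Series([-1] * 200, index=genes)
        assignments.iloc[:30] = 0
        pathways = {"planted": set(genes[:30]), "random": set(genes[100:130])}
        ora = cluster_ora(assignments, pathways, universe=genes)
        top = ora.sort_values("adj_pvalue").iloc[0]
        assert top["pathway"] == "planted" and top["adj_pvalue"] < 0.05

    def test_universe_equals_pathway_gives_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        assignments = pd.Series([0] * 5 + [-1] * 15, index=genes)
        ora = cluster_ora(assignments, {"all": set(genes)}, universe=genes)
        assert ora.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_duplicate_members_deduplicated(self):
        genes = [f"g{i}" for i in range(20)]
        assignments = pd.Series([0] * 10 + [-1] * 10, index=genes)
        dup = cluster_ora(assignments, {"pw": list(genes[:5]) * 3}, universe=genes)
        ded = cluster_ora(assignments, {"pw": set(genes[:5])}, universe=genes)
        assert dup.loc[0, "K"] == ded.loc[0, "K"] == 5
        assert dup.loc[0, "pvalue"] == ded.loc[0, "pvalue"]

    def test_cluster_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(120)]
        labels = rng.integers(0, 3, size=120)
        pathways = {f"pw{j}": set(rng.choice(genes, size=25, replace=False)) for j in range(4)}
        a = cluster_ora(pd.Series(labels, index=genes), pathways, universe=genes)
        relabel = {0: 2, 1: 0, 2: 1}
        b = cluster_ora(pd.Series([relabel[l] for l in labels], index=genes),
                        pathways, universe=genes)
        a_key = a.set_index(["cluster", "pathway"])["pvalue"]
        for (cl, pw), p in a_key.items():
            assert b.set_index(["cluster", "pathway"])["pvalue"][(relabel[cl], pw)] == p


class TestMirnaPathwayGsea:
    def _setup(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        t = pd.Series(rng.normal(size=60), index=genes)
        t.iloc[:6] = -8.0 + rng.normal(0, 0.1, 6)  # strongly repressed block
        de_table = pd.DataFrame({"t": t, "de": t.abs() > 2, "adj_pvalue": 0.01}, index=genes)
        refined = pd.DataFrame({"mirna_id": ["m"] * 20, "gene_id": genes[:20]})
        pathways = {"repressed": set(genes[:6]), "noise": set(genes[30:40])}
        return refined, pathways, de_table

    def test_planted_pathway_recovered(self):
        refined, pathways, de_table = self._setup()
        results, edges = mirna_pathway_gsea(refined, pathways, de_table, de_mirnas=["m"],
                                            n_perm=500, min_targets=10, seed=0)
        testable = results[results["testable"]].sort_values("pvalue")
        assert testable.iloc[0]["pathway"] == "repressed"
        assert testable.iloc[0]["pvalue"] < 0.05
        assert set(edges["gene_id"]) <= set(f"g{i}" for i in range(6))
        assert (edges["gene_de"]).all()

    def test_mirna_with_few_targets_skipped(self):
        refined, pathways, de_table = self._setup()
        small = refined.iloc[:5]
        results, edges = mirna_pathway_gsea(small, pathways, de_table, de_mirnas=["m"],
                                            n_perm=200, min_targets=10, seed=0)
        assert len(results) == 0 and len(edges) == 0

    def test_disjoint_pathway_not_testable(self):
        refined, pathways, de_table = self._setup()
        pathways = {"off_target": {"g55", "g56"}}
        results, _ = mirna_pathway_gsea(refined, pathways, de_table, de_mirnas=["m"],
                                        n_perm=200, min_targets=10, seed=0)
        assert not results.iloc[0]["testable"]
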