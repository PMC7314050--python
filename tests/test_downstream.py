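"""Hub selection, hypergeometric association, enrichment, TF ranking,
guilt-by-association annotation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.downstream import GeneList, hypergeom_tails


def hypergeom_enrich_oracle(N, K, n, k):
    """Upper-tail probability by direct combinatorial summation."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        for i in range(k, min(K, n) + 1)
    )


def enumeration_oracle(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total


@pytest.fixture(scope="module")
def small_network():
    """3 planted modules with hubs, full downstream context."""
    m, truth = cx.generate_dataset(
        n_modules=3, module_sizes=(30, 30, 30), n_background=20,
        loading_range=(0.8, 0.9), seed=77,
    )
    labels = np.array([truth.labels[g] for g in m.gene_ids])
    part = cx.ModulePartition(gene_ids=m.gene_ids, labels=labels, min_module_size=20)
    s = cx.similarity_matrix(m)
    a = cx.adjacency(s, 6)
    tom = cx.topological_overlap(a)
    net = cx.GeneNetwork(gene_ids=m.gene_ids, similarity=s.values, adjacency=a, tom=tom, beta=6)
    me = cx.module_eigengenes(m, part)
    conn = cx.intramodular_connectivity(net, part, m, me)
    return m, truth, part, net, conn


class TestConnectivity:
    def test_three_gene_module_arithmetic(self):
        genes = ["a", "b", "c"]
        adj = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.1], [0.25, 0.1, 1.0]])
        tom = cx.topological_overlap(adj)
        net = cx.GeneNetwork(gene_ids=genes, similarity=adj, adjacency=adj, tom=tom, beta=1)
        part = cx.ModulePartition(gene_ids=genes, labels=np.array([1, 1, 1]), min_module_size=2)
        conn = cx.intramodular_connectivity(net, part)
        assert conn.loc["a", "kWithin"] == pytest.approx(0.75)
        assert conn.loc["a", "kTotal"] == pytest.approx(0.75)

    def test_grey_gene_flagged(self, small_network):
        m, truth, part, net, conn = small_network
        grey = conn[~conn["in_module"]]
        assert len(grey) == 20
        assert (grey["kWithin"] <= grey["kTotal"] + 1e-12).all()

    def test_matches_double_loop_oracle(self, rng):
        n = 30
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i}" for i in range(n)]
        labels = rng.integers(1, 4, size=n)
        tom = cx.topological_overlap(a)
        net = cx.GeneNetwork(gene_ids=genes, similarity=a, adjacency=a, tom=tom, beta=1)
        part = cx.ModulePartition(gene_ids=genes, labels=labels, min_module_size=2)
        conn = cx.intramodular_connectivity(net, part)
        for i in range(n):
            kt = sum(a[i, j] for j in range(n) if j != i)
            kw = sum(a[i, j] for j in range(n) if j != i and labels[j] == labels[i])
            assert conn.iloc[i]["kTotal"] == pytest.approx(kt, abs=1e-12)
            assert conn.iloc[i]["kWithin"] == pytest.approx(kw, abs=1e-12)


class TestSelectHubs:
    def test_planted_hubs_selected(self, small_network):
        m, truth, part, net, conn = small_network
        hubs = cx.select_hubs(conn, part)
        for lab in part.module_labels:
            assert hubs.loc[lab, "hub"] == truth.hubs[lab]
            assert not hubs.loc[lab, "kme_fallback"]

    def test_tie_breaks_lexicographically(self):
        genes = ["zz", "aa", "mm"]
        conn = pd.DataFrame(
            {"module": [1, 1, 1], "kTotal": [2.0, 2.0, 1.0],
             "kWithin": [1.0, 1.0, 0.5], "kME": [0.9, 0.9, 0.9]},
            index=pd.Index(genes, name="gene_id"),
        )
        part = cx.ModulePartition(gene_ids=genes, labels=np.array([1, 1, 1]), min_module_size=2)
        hubs = cx.select_hubs(conn, part)
        assert hubs.loc[1, "hub"] == "aa"

    def test_kme_fallback_flag(self):
        genes = ["a", "b"]
        conn = pd.DataFrame(
            {"module": [1, 1], "kTotal": [2.0, 1.0], "kWithin": [2.0, 1.0],
             "kME": [0.3, 0.2]},
            index=pd.Index(genes, name="gene_id"),
        )
        part = cx.ModulePartition(gene_ids=genes, labels=np.array([1, 1]), min_module_size=2)
        hubs = cx.select_hubs(conn, part)
        assert hubs.loc[1, "hub"] == "a"
        assert hubs.loc[1, "kme_fallback"]

    def test_invariant_to_gene_order(self, small_network):
        m, truth, part, net, conn = small_network
        hubs = cx.select_hubs(conn, part)
        perm = np.random.default_rng(0).permutation(len(conn))
        hubs2 = cx.select_hubs(conn.iloc[perm], part)
        assert (hubs["hub"] == hubs2["hub"]).all()


class TestHypergeometric:
    def test_all_overlap_closed_form(self):
        p, _ = hypergeom_tails(10, 5, 5, 5)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_upper_tail_is_one(self):
        p, _ = hypergeom_tails(20, 5, 5, 0)
        assert p == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self, rng):
        for _ in range(20):
            N = int(rng.integers(5, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            p, _ = hypergeom_tails(N, K, n, k)
            assert p == pytest.approx(hypergeom_enrich_oracle(N, K, n, k), rel=1e-10)

    def test_matches_exhaustive_enumeration(self):
        for N, K, n, k in [(8, 3, 4, 2), (10, 5, 3, 1), (12, 6, 4, 3), (9, 2, 5, 0)]:
            p, _ = hypergeom_tails(N, K, n, k)
            assert p == pytest.approx(enumeration_oracle(N, K, n, k), rel=1e-10)

    def test_two_tails_overlap_at_pmf(self):
        from scipy import stats

        N, K, n, k = 30, 10, 8, 3
        pe, pd_ = hypergeom_tails(N, K, n, k)
        assert pe + pd_ == pytest.approx(1 + stats.hypergeom.pmf(k, N, K, n), rel=1e-12)


class TestModuleSetAssociation:
    def test_planted_overlap_is_significant(self, small_network):
        m, truth, part, net, conn = small_network
        lst = cx.generate_trait_lists(truth, list_size=25, target_module=1,
                                      overlap_count=15, seed=1)
        res = cx.module_set_association(part, lst, m.gene_ids)
        by_mod = res.set_index("module")
        assert by_mod.loc[1, "significant"]
        assert not by_mod.loc[2, "significant"]
        assert not by_mod.loc[3, "significant"]

    def test_members_outside_universe_discarded(self, small_network):
        m, truth, part, net, conn = small_network
        lst = GeneList(label="x", members=["M1_HUB", "not_a_gene"])
        res = cx.module_set_association(part, lst, m.gene_ids)
        assert (res["list_size"] == 1).all()
        assert (res["discarded_ids"] == 1).all()

    def test_empty_list_after_intersection_rejected(self, small_network):
        m, truth, part, net, conn = small_network
        with pytest.raises(ValueError):
            cx.module_set_association(part, GeneList(label="x", members=["nope"]), m.gene_ids)

    def test_uniform_lists_are_super_uniform(self, small_network):
        m, truth, part, net, conn = small_network
        rng = np.random.default_rng(0)
        genes = np.array(m.gene_ids)
        hits = 0
        n_lists = 300
        for i in range(n_lists):
            members = list(rng.choice(genes, size=20, replace=False))
            res = cx.module_set_association(part, GeneList(label=f"l{i}", members=members),
                                            m.gene_ids)
            hits += int(res.set_index("module").loc[1, "significant"])
        assert hits / n_lists < 0.10  # nominal level 0.05, discrete test is conservative


class TestTermEnrichment:
    def _context(self):
        universe = [f"g{i}" for i in range(50)]
        ann = {g: {"T1"} for g in universe[:10]}
        for g in universe[10:30]:
            ann[g] = {"T2"}
        return universe, ann

    def test_exact_term_set_is_top_hit(self):
        universe, ann = self._context()
        res = cx.term_enrichment(universe[:10], ann, universe)
        assert res.iloc[0]["term"] == "T1"
        p, _ = hypergeom_tails(50, 10, 10, 10)
        assert res.iloc[0]["p_enrich"] == pytest.approx(p, rel=1e-12)

    def test_absent_term_boundary(self):
        universe, ann = self._context()
        res = cx.term_enrichment(universe[30:35], {**ann, universe[30]: {"T2"}}, universe)
        t1 = res[res["term"] == "T1"].iloc[0]
        assert t1["overlap"] == 0
        assert t1["p_enrich"] == pytest.approx(1.0)

    def test_planted_frequent_term_ranks_first(self):
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(500)]
        terms = [f"T{t}" for t in range(20)]
        ann = {g: {terms[int(rng.integers(0, 20))]} for g in universe}
        planted = [g for g in universe if "T7" in ann[g]][:15]
        others = [g for g in universe if "T7" not in ann[g]]
        test_set = planted + list(rng.choice(others, size=30, replace=False))
        res = cx.term_enrichment(test_set, ann, universe)
        assert res.iloc[0]["term"] == "T7"

    def test_bh_column_present_and_monotone(self):
        universe, ann = self._context()
        res = cx.term_enrichment(universe[:10], ann, universe, correction="BH")
        assert (res["p_enrich_bh"] >= res["p_enrich"] - 1e-15).all()


class TestTfRanking:
    def test_planted_regulator_ranks_first(self):
        m, truth = cx.generate_dataset(
            n_modules=2, module_sizes=(30, 30), n_background=10,
            loading_range=(0.8, 0.9), tfs_per_module=1, tf_loading=0.93, seed=55,
        )
        labels = np.array([truth.labels[g] for g in m.gene_ids])
        part = cx.ModulePartition(gene_ids=m.gene_ids, labels=labels, min_module_size=20)
        s = cx.similarity_matrix(m)
        a = cx.adjacency(s, 6)
        net = cx.GeneNetwork(gene_ids=m.gene_ids, similarity=s.values, adjacency=a,
                             tom=cx.topological_overlap(a), beta=6)
        me = cx.module_eigengenes(m, part)
        conn = cx.intramodular_connectivity(net, part, m, me)
        hubs = cx.select_hubs(conn, part)
        # decoy TFs: background noise genes
        decoys = [g for g in m.gene_ids if g.startswith("BG")][:5]
        tf_ids = list(truth.tf_modules) + decoys
        ranking, unmapped = cx.rank_tfs(m, tf_ids, part, hubs)
        assert set(unmapped) == set(decoys)  # decoys are unassigned genes
        for tf, lab in truth.tf_modules.items():
            row = ranking[ranking["tf"] == tf].iloc[0]
            assert row["rank"] == 1
            assert row["module"] == lab

    def test_hub_itself_scores_one(self, small_network):
        m, truth, part, net, conn = small_network
        hubs = cx.select_hubs(conn, part)
        ranking, _ = cx.rank_tfs(m, [hubs.loc[1, "hub"]], part, hubs)
        assert ranking.iloc[0]["bicor_with_hub"] == 1.0
        assert ranking.iloc[0]["category"] == "high"

    def test_strength_categories(self):
        assert_cat = lambda v, c: c == (
            "high" if abs(v) >= 0.8 else "moderate" if abs(v) >= 0.5 else "low"
        )
        rng = np.random.default_rng(0)
        n = 200
        hubp = rng.standard_normal(n)
        rows = {"hub": hubp}
        for target in (0.9, 0.78, 0.6, 0.3):
            rows[f"tf{target}"] = target * hubp + np.sqrt(1 - target**2) * rng.standard_normal(n)
        vals = pd.DataFrame(rows).T
        vals.columns = [f"s{j}" for j in range(n)]
        m = cx.ExpressionMatrix(values=vals, batches=pd.Series("b", index=vals.columns))
        part = cx.ModulePartition(gene_ids=m.gene_ids, labels=np.ones(5, dtype=int),
                                  min_module_size=2)
        hubs = pd.DataFrame({"hub": ["hub"]}, index=pd.Index([1], name="module"))
        ranking, _ = cx.rank_tfs(m, [g for g in m.gene_ids if g != "hub"], part, hubs)
        cats = dict(zip(ranking["tf"], ranking["category"]))
        scores = dict(zip(ranking["tf"], ranking["bicor_with_hub"]))
        assert cats["tf0.9"] == "high"
        assert cats["tf0.3"] == "low"
        for tf, c in cats.items():
            assert assert_cat(scores[tf], c)


class TestNeighborsAndAnnotation:
    def test_full_toy_network_neighbors(self):
        genes = list("abcde")
        tom = np.full((5, 5), 0.5)
        np.fill_diagonal(tom, 1.0)
        net = cx.GeneNetwork(gene_ids=genes, similarity=tom, adjacency=tom, tom=tom, beta=1)
        assert len(cx.first_neighbors("a", net, tom_min=0.0)) == 4

    def test_counts_match_linear_scan(self, small_network):
        m, truth, part, net, conn = small_network
        rng = np.random.default_rng(2)
        for gene in rng.choice(m.gene_ids, size=5, replace=False):
            nb = cx.first_neighbors(gene, net, tom_min=0.01)
            i = m.gene_ids.index(gene)
            expected = [g for j, g in enumerate(m.gene_ids) if j != i and net.tom[i, j] > 0.01]
            assert sorted(nb) == sorted(expected)

    def test_module_restriction_is_subset(self, small_network):
        m, truth, part, net, conn = small_network
        gene = truth.hubs[1]
        unrestricted = set(cx.first_neighbors(gene, net, 0.01))
        restricted = set(cx.first_neighbors(gene, net, 0.01, partition=part))
        assert restricted <= unrestricted

    def test_unknown_gene_rejected(self, small_network):
        m, truth, part, net, conn = small_network
        with pytest.raises(KeyError):
            cx.first_neighbors("nope", net, 0.01)

    def test_hub_annotation_recovers_module_term(self, small_network):
        m, truth, part, net, conn = small_network
        ann = {}
        for g in m.gene_ids:
            lab = truth.labels[g]
            ann[g] = {f"MODTERM{lab}"} if lab else {"BGTERM"}
        res = cx.annotate_hypothetical_hub(truth.hubs[1], net, ann, m.gene_ids, tom_min=0.01)
        assert res.top_term == "MODTERM1"
        assert truth.hubs[1] not in res.neighbors

    def test_extreme_threshold_unassigned(self, small_network):
        m, truth, part, net, conn = small_network
        res = cx.annotate_hypothetical_hub(truth.hubs[1], net, {}, m.gene_ids, tom_min=1.0)
        assert res.top_term == "unassigned"
        assert res.neighbors == []

    def test_tie_broken_lexicographically(self):
        genes = ["hub", "n1", "n2", "n3", "n4", "o1", "o2", "o3", "o4"]
        tom = np.eye(9)
        for j in range(1, 5):
            tom[0, j] = tom[j, 0] = 0.5
        net = cx.GeneNetwork(gene_ids=genes, similarity=tom, adjacency=tom, tom=tom, beta=1)
        ann = {"n1": {"TA"}, "n2": {"TA"}, "n3": {"TB"}, "n4": {"TB"}}
        res = cx.annotate_hypothetical_hub("hub", net, ann, genes, tom_min=0.01, alpha=0.5)
        assert res.top_term == "TA"
        assert res.tie
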