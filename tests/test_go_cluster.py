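import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom

from methdmr.go_cluster import (GOCluster, cluster_components, enrich,
                                export_clusters, gograph_clust,
                                highest_parental_term, remerge_parents,
                                select_terms, semantic_similarity,
                                split_large_clusters)

from _oracles import reference_gograph


def _ontology(edges, terms=None):
    """edges: list of (child, parent) is_a links."""
    g = nx.MultiDiGraph()
    if terms:
        g.add_nodes_from(terms)
    for child, parent in edges:
        g.add_node(child)
        g.add_node(parent)
        g.add_edge(child, parent, key="is_a")
    for n in g.nodes:
        g.nodes[n].setdefault("namespace", "biological_process")
    return g


def _parents_dict(graph):
    return {t: set(graph.successors(t)) for t in graph.nodes}


class TestEnrich:
    def test_query_equals_universe_never_significant(self):
        genes = {f"g{i}" for i in range(10)}
        res = enrich(genes, {"T1": set(genes)}, genes, alpha=1.1)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = enrich({"g0", "g1"}, {"T1": {"g10", "g11"}}, universe,
                     alpha=1.1)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_sum(self):
        # table (a, b, c, d) = (3, 2, 7, 88)
        universe = [f"g{i}" for i in range(100)]
        query = set(universe[:5])
        term = set(universe[:3]) | set(universe[5:12])
        res = enrich(query, {"T": term}, universe, alpha=1.1)
        # tail sum over a 2x2 with fixed margins: N=100, K=10, n=5, k>=3
        expect = sum(hypergeom.pmf(k, 100, 10, 5) for k in range(3, 6))
        assert res.loc[0, "p_value"] == pytest.approx(expect, rel=1e-10)

    def test_empty_query(self):
        assert len(enrich([], {"T": {"a"}}, {"a"})) == 0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"x"}, {"T": {"a"}}, {"a"})


class TestSelectTerms:
    def test_single_gene_terms_excluded(self):
        import pandas as pd
        df = pd.DataFrame([{"term": "T1", "p_value": 0.01,
                            "overlap_genes": "a", "n_overlap": 1,
                            "gene_ratio": 0.1}])
        out = select_terms({("TDP-A", "FCX"): df})
        assert len(out) == 0

    def test_duplicate_terms_tagged_once(self):
        import pandas as pd
        row = {"term": "T1", "p_value": 0.01, "overlap_genes": "a,b",
               "n_overlap": 2, "gene_ratio": 0.2}
        out = select_terms({("TDP-A", "FCX"): pd.DataFrame([row]),
                            ("TDP-B", "CER"): pd.DataFrame([dict(
                                row, p_value=0.02)])})
        assert len(out) == 1
        assert out.loc[0, "tags"] == "TDP-A:FCX;TDP-B:CER"
        assert out.loc[0, "best_p"] == 0.01


class TestComponents:
    def test_unlinked_terms_are_singletons(self):
        g = _ontology([("B", "A"), ("D", "C")])
        out = cluster_components({"B", "D"}, g)
        assert sorted(len(c.members) for c in out) == [1, 1]

    def test_direct_parent_child_connect(self):
        g = _ontology([("B", "A")])
        out = cluster_components({"A", "B"}, g)
        assert len(out) == 1 and out[0].members == {"A", "B"}

    def test_path_through_unselected_term_does_not_connect(self):
        g = _ontology([("C", "B"), ("B", "A")])
        out = cluster_components({"A", "C"}, g)   # B not selected
        assert len(out) == 2

    def test_missing_term_warns_and_drops(self):
        g = _ontology([("B", "A")])
        with pytest.warns(UserWarning, match="missing"):
            out = cluster_components({"B", "ZZ"}, g)
        assert out[0].members == {"B"}

    def test_order_invariance(self, rng):
        g = _ontology([(f"T{i}", f"T{i // 2}") for i in range(1, 12)])
        terms = [f"T{i}" for i in range(12)]
        base = sorted(frozenset(c.members)
                      for c in cluster_components(terms, g))
        shuffled = list(terms)
        rng.shuffle(shuffled)
        assert sorted(frozenset(c.members)
                      for c in cluster_components(shuffled, g)) == base


class TestSplit:
    def test_below_limit_untouched(self):
        g = _ontology([(f"C{i}", "P") for i in range(23)])
        clusters = cluster_components({"P"} | {f"C{i}" for i in range(23)}, g)
        assert clusters[0].size == 24
        out, removed = split_large_clusters(clusters, g, limit=25)
        assert removed == []
        assert out[0].size == 24

    def test_star_parent_removed_children_become_singletons(self):
        g = _ontology([(f"C{i:02d}", "P") for i in range(25)])
        clusters = cluster_components({"P"} | {f"C{i:02d}" for i in range(25)},
                                      g)
        out, removed = split_large_clusters(clusters, g, limit=25)
        assert removed == ["P"]
        assert len(out) == 25
        assert all(c.size == 1 for c in out)

    def test_all_post_split_sizes_below_limit(self, rng):
        edges = [(f"T{i}", f"T{int(rng.integers(0, i))}")
                 for i in range(1, 40)]
        g = _ontology(edges)
        terms = [f"T{i}" for i in range(40)]
        clusters = cluster_components(terms, g)
        out, removed = split_large_clusters(clusters, g, limit=10)
        assert all(c.size < 10 for c in out)
        covered = set().union(*(c.members for c in out)) | set(removed)
        assert covered == set(terms)

    def test_highest_parental_is_most_member_descendants(self):
        g = _ontology([("B", "A"), ("C", "B"), ("D", "B")])
        assert highest_parental_term({"A", "B", "C", "D"}, g) == "A"
        assert highest_parental_term({"B", "C", "D"}, g) == "B"


class TestRemerge:
    def test_single_adjacent_small_cluster(self):
        g = _ontology([("B", "A"), ("C", "B"), ("D", "B")])
        clusters = [GOCluster({"B", "C", "D"}, 0)]
        out = remerge_parents(["A"], clusters, g, {}, limit=25)
        assert out[0].members == {"A", "B", "C", "D"}

    def test_only_full_clusters_leaves_singleton(self):
        g = _ontology([("B", "A")])
        clusters = [GOCluster({"B"}, 0)]
        out = remerge_parents(["A"], clusters, g, {}, limit=1)
        members = [frozenset(c.members) for c in out]
        assert frozenset({"A"}) in members
        assert frozenset({"B"}) in members

    def test_similarity_guides_choice(self):
        g = _ontology([("B", "A"), ("C", "A")])
        anno = {"A": {"g1", "g2", "g3"}, "B": {"g1", "g2", "g3", "g4"},
                "C": {"g9"}}
        clusters = [GOCluster({"B"}, 0), GOCluster({"C"}, 1)]
        # Jaccard(A, B) = 3/4; Jaccard(A, C) = 0
        out = remerge_parents(["A"], clusters, g, anno, limit=25)
        members = [c.members for c in out]
        assert {"A", "B"} in members
        assert {"C"} in members


class TestSimilarity:
    def test_identical_sets(self):
        anno = {"T": {"a", "b"}, "U": {"a", "b"}}
        assert semantic_similarity("T", ["U"], anno) == 1.0

    def test_disjoint_sets(self):
        anno = {"T": {"a"}, "U": {"b"}}
        assert semantic_similarity("T", ["U"], anno) == 0.0

    def test_worked_jaccard(self):
        anno = {"T": {"a", "b", "c"}, "U": {"b", "c", "d"}, "V": {"e"}}
        # T = {a,b,c}; union(U, V) = {b,c,d,e}: Jaccard = 2/5
        assert semantic_similarity("T", ["U", "V"], anno) \
            == pytest.approx(2 / 5)

    def test_empty_sets_give_zero(self):
        assert semantic_similarity("T", ["U"], {}) == 0.0


class TestExport:
    def test_visualization_floor(self):
        import pandas as pd
        clusters = [GOCluster({"A", "B", "C"}, 0),
                    GOCluster({"D", "E", "F", "G"}, 1)]
        sel = pd.DataFrame({"term": list("ABCDEFG"), "best_p": 0.01,
                            "gene_ratio": 0.2, "tags": "x:y"})
        out = export_clusters(clusters, sel, min_viz=4)
        assert set(out["term"]) == {"D", "E", "F", "G"}
        assert (out["cluster_size"] == 4).all()


class TestFullPipelineProperties:
    def test_partition_property(self, rng):
        edges = [(f"T{i}", f"T{int(rng.integers(0, i))}")
                 for i in range(1, 30)]
        g = _ontology(edges)
        terms = [f"T{i}" for i in range(30)]
        anno = {t: set(rng.choice([f"g{j}" for j in range(12)],
                                  size=3, replace=False))
                for t in terms}
        out = gograph_clust(terms, g, anno, limit=8)
        all_members = [t for c in out for t in c.members]
        assert sorted(all_members) == sorted(terms)  # exactly one cluster

    def test_matches_reference_on_exhaustive_small_ontologies(self):
        rng = np.random.default_rng(99)
        genes = [f"g{j}" for j in range(6)]
        for trial in range(8):
            n = int(rng.integers(4, 9))
            terms = [f"T{i}" for i in range(n)]
            edges = [(terms[i], terms[int(rng.integers(0, i))])
                     for i in range(1, n)]
            g = _ontology(edges)
            anno = {t: set(rng.choice(genes, size=int(rng.integers(1, 4)),
                                      replace=False)) for t in terms}
            parents = _parents_dict(g)
            for size in range(1, n + 1):
                for subset in itertools.combinations(terms, size):
                    got = sorted(
                        (frozenset(c.members)
                         for c in gograph_clust(subset, g, anno, limit=3)),
                        key=min)
                    want = reference_gograph(subset, parents, anno, limit=3)
                    assert got == want, (edges, subset)
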