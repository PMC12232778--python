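"""Fisher-exact GO enrichment and graph-based clustering of enriched terms.

Enriched terms (one-sided Fisher exact p < 0.05, >= 2 overlapping genes,
pooled over groups and tissues) are clustered into connected components of
the GO DAG restricted to the selected terms: two terms are adjacent only
when a direct is_a/part_of edge links them ("unbroken" in the graph — paths
through unselected intermediate terms do not connect clusters). Components
of >= 25 terms are split by iteratively removing the highest parental term
(most member-descendants; ties broken by smaller depth, then id) and
recomputing components. Removed parental terms are then re-merged, in
removal order, into an adjacent cluster below the 25-term limit, preferring
higher semantic similarity (Jaccard of annotated gene sets) and then
smaller size. Clusters with >= 4 terms are exported for visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class GOCluster:
    """A set of GO terms with split/merge provenance."""

    members: set[str]
    component_id: int
    split_removed: list[str] = field(default_factory=list)
    merge_events: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def cluster_id(self) -> str:
        return min(self.members)


# ---------------------------------------------------------------------------
# Ontology helpers (edges run child -> parent, as obonet loads them)
# ---------------------------------------------------------------------------


def namespace_roots(graph: nx.MultiDiGraph) -> dict[str, str]:
    """Root term (no outgoing edge) of each namespace."""
    roots: dict[str, str] = {}
    for node in graph.nodes:
        if graph.out_degree(node) == 0:
            ns = graph.nodes[node].get("namespace", "biological_process")
            roots.setdefault(ns, node)
    return roots


def term_depth(graph: nx.MultiDiGraph, term: str) -> int:
    """Shortest child->parent path length from the term to any root."""
    best = 0
    found = False
    lengths = nx.single_source_shortest_path_length(graph, term)
    for node, dist in lengths.items():
        if graph.out_degree(node) == 0:
            if not found or dist < best:
                best, found = dist, True
    return best if found else 0


def term_descendants(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """All ontology descendants (more specific terms) of ``term``."""
    return nx.ancestors(graph, term)  # nodes with a path TO term


def direct_neighbors(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """Direct parents and children of a term."""
    return set(graph.predecessors(term)) | set(graph.successors(term))


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrich(query_genes: Iterable[str], annotation: Mapping[str, set[str]],
           universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a gene list against GO terms.

    The 2x2 table per term is (query∩term, query∖term, term∖query, rest)
    over the explicit ``universe`` (all genes annotated to the namespace
    unless the caller supplies one). Results with p < ``alpha`` are
    returned with the overlapping genes and the gene ratio (overlap /
    query size).
    """
    query = set(query_genes)
    universe = set(universe)
    if not query:
        return _empty_enrichment()
    if not query <= universe:
        raise ValueError("query genes must lie within the universe")
    rows = []
    for term in sorted(annotation):
        term_genes = annotation[term] & universe
        overlap = query & term_genes
        a = len(overlap)
        b = len(query) - a
        c = len(term_genes) - a
        d = len(universe) - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        if p < alpha:
            rows.append({"term": term, "p_value": float(p),
                         "overlap_genes": ",".join(sorted(overlap)),
                         "n_overlap": a,
                         "gene_ratio": a / len(query)})
    if not rows:
        return _empty_enrichment()
    return pd.DataFrame(rows)


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(columns=["term", "p_value", "overlap_genes",
                                 "n_overlap", "gene_ratio"])


def select_terms(results: Mapping[tuple[str, str], pd.DataFrame],
                 alpha: float = 0.05, min_genes: int = 2) -> pd.DataFrame:
    """Pool significant terms (p < alpha, >= ``min_genes`` overlapping genes)
    across (group, tissue) strata, deduplicated with contribution tags."""
    tags: dict[str, list[str]] = {}
    pbest: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for (group, tissue), df in sorted(results.items()):
        for row in df.itertuples(index=False):
            if row.p_value >= alpha or row.n_overlap < min_genes:
                continue
            tags.setdefault(row.term, []).append(f"{group}:{tissue}")
            if row.term not in pbest or row.p_value < pbest[row.term]:
                pbest[row.term] = row.p_value
                ratios[row.term] = row.gene_ratio
    rows = [{"term": t, "best_p": pbest[t], "gene_ratio": ratios[t],
             "tags": ";".join(tags[t])} for t in sorted(tags)]
    return pd.DataFrame(rows, columns=["term", "best_p", "gene_ratio", "tags"])


# ---------------------------------------------------------------------------
# GOgraphClust
# ---------------------------------------------------------------------------


def induced_adjacency(terms: Iterable[str],
                      ontology: nx.MultiDiGraph) -> nx.Graph:
    """Undirected graph on the terms, edges = direct parent-child links."""
    terms = set(terms)
    g = nx.Graph()
    g.add_nodes_from(terms)
    for t in terms:
        if not ontology.has_node(t):
            continue
        for other in direct_neighbors(ontology, t):
            if other in terms:
                g.add_edge(t, other)
    return g


def cluster_components(terms: Iterable[str],
                       ontology: nx.MultiDiGraph) -> list[GOCluster]:
    """Connected components of the induced adjacency; isolated terms form
    singleton clusters. Terms absent from the ontology are dropped with a
    warning."""
    terms = set(terms)
    missing = {t for t in terms if not ontology.has_node(t)}
    if missing:
        warnings.warn(f"terms missing from ontology: {sorted(missing)}")
        terms -= missing
    g = induced_adjacency(terms, ontology)
    comps = sorted(nx.connected_components(g), key=min)
    return [GOCluster(set(c), component_id=i) for i, c in enumerate(comps)]


def highest_parental_term(members: set[str],
                          ontology: nx.MultiDiGraph) -> str:
    """The member with the most member-descendants; ties broken by smaller
    ontology depth (closer to the root), then lexicographic id."""
    def key(t):
        n_desc = len(term_descendants(ontology, t) & members)
        return (-n_desc, term_depth(ontology, t), t)
    return min(members, key=key)


def split_large_clusters(clusters: list[GOCluster],
                         ontology: nx.MultiDiGraph, limit: int = 25
                         ) -> tuple[list[GOCluster], list[str]]:
    """Split every cluster of size >= ``limit``.

    Largest cluster first; the highest parental term is removed, recorded,
    and connectivity among the remaining members recomputed after each
    removal. Terminates because each removal strictly reduces the member
    count. Returns (clusters, removal order).
    """
    removed: list[str] = []
    done: list[GOCluster] = []
    work = [GOCluster(set(c.members), c.component_id,
                      list(c.split_removed), list(c.merge_events))
            for c in clusters]
    while work:
        work.sort(key=lambda c: (-c.size, c.cluster_id))
        cl = work.pop(0)
        if cl.size < limit:
            done.append(cl)
            continue
        top = highest_parental_term(cl.members, ontology)
        removed.append(top)
        rest = cl.members - {top}
        trail = cl.split_removed + [top]
        if rest:
            g = induced_adjacency(rest, ontology)
            for comp in sorted(nx.connected_components(g), key=min):
                work.append(GOCluster(set(comp), cl.component_id,
                                      list(trail), list(cl.merge_events)))
    done.sort(key=lambda c: c.cluster_id)
    return done, removed


def semantic_similarity(term: str, cluster_members: Iterable[str],
                        annotation: Mapping[str, set[str]]) -> float:
    """Jaccard index between the term's gene set and the union of the
    cluster members' gene sets; 0 when both sides are empty."""
    tset = set(annotation.get(term, set()))
    cset: set[str] = set()
    for m in cluster_members:
        cset |= annotation.get(m, set())
    union = tset | cset
    if not union:
        return 0.0
    return len(tset & cset) / len(union)


def remerge_parents(removed: Sequence[str], clusters: list[GOCluster],
                    ontology: nx.MultiDiGraph,
                    annotation: Mapping[str, set[str]],
                    limit: int = 25) -> list[GOCluster]:
    """Re-merge removed parental terms, in removal order.

    Candidates are clusters below the size limit containing a direct
    ontology neighbor of the term; the candidate with the highest semantic
    similarity wins, ties going to the smaller cluster, then the smaller
    cluster id. A term with no candidate becomes a singleton cluster.
    """
    final = [GOCluster(set(c.members), c.component_id,
                       list(c.split_removed), list(c.merge_events))
             for c in clusters]
    next_comp = max((c.component_id for c in final), default=-1) + 1
    for term in removed:
        neighbors = direct_neighbors(ontology, term)
        candidates = [c for c in final
                      if c.size < limit and c.members & neighbors]
        if not candidates:
            final.append(GOCluster({term}, next_comp,
                                   merge_events=[f"singleton:{term}"]))
            next_comp += 1
            continue
        best = max(candidates,
                   key=lambda c: (semantic_similarity(term, c.members,
                                                      annotation),
                                  -c.size, _revkey(c.cluster_id)))
        best.members.add(term)
        best.merge_events.append(f"merged:{term}")
    final.sort(key=lambda c: c.cluster_id)
    return final


class _revkey:
    """Inverts lexicographic order so max() picks the smaller id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def gograph_clust(terms: Iterable[str], ontology: nx.MultiDiGraph,
                  annotation: Mapping[str, set[str]],
                  limit: int = 25) -> list[GOCluster]:
    """The full pipeline: components -> split at ``limit`` -> re-merge."""
    clusters = cluster_components(terms, ontology)
    clusters, removed = split_large_clusters(clusters, ontology, limit)
    return remerge_parents(removed, clusters, ontology, annotation, limit)


def export_clusters(clusters: list[GOCluster], selected: pd.DataFrame,
                    min_viz: int = 4) -> pd.DataFrame:
    """Visualization table for clusters with >= ``min_viz`` terms: one row
    per member term with its best p, gene ratio and contribution tags."""
    info = selected.set_index("term") if len(selected) else None
    rows = []
    for c in clusters:
        if c.size < min_viz:
            continue
        for term in sorted(c.members):
            row = {"cluster_id": c.cluster_id, "cluster_size": c.size,
                   "term": term}
            if info is not None and term in info.index:
                row.update({"p_value": info.loc[term, "best_p"],
                            "gene_ratio": info.loc[term, "gene_ratio"],
                            "tags": info.loc[term, "tags"]})
            rows.append(row)
    return pd.DataFrame(rows, columns=["cluster_id", "cluster_size", "term",
                                       "p_value", "gene_ratio", "tags"])
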