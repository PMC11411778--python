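"""Gene communities from the signed significant-correlation graph.

Significant pairs define a graph whose vertices are genes and whose edges
carry the sign of the correlation and its signed equivalent PCC.  Community
extraction proceeds in four deterministic stages:

1. random-walk (walktrap) clustering of the unweighted adjacency, both signs;
2. within each community, negative edges are removed and walktrap is rerun so
   that mutually anti-correlated blocks (e.g. mitochondrially encoded versus
   ribosomal-protein genes) separate;
3. pairs of communities whose positive inter-community edge density is large
   relative to their internal density are merged (guarded so the positive
   subgraph's modularity never drops more than 0.05 below its pre-merge
   value);
4. oversized communities are re-subdivided by one more walktrap pass.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

__all__ = [
    "SignedGeneGraph",
    "CommunityPartition",
    "build_graph",
    "find_communities",
    "top_connected_genes",
    "fold_enrichment",
]


@dataclass
class SignedGeneGraph:
    """Signed graph of significant gene-gene correlations.

    ``graph`` is an :mod:`igraph` graph with vertex attribute ``name`` (gene
    id, vertices sorted by id for determinism) and edge attributes ``sign``
    (+1/-1) and ``weight`` (signed equivalent PCC).
    """

    graph: ig.Graph

    @property
    def genes(self) -> list:
        return list(self.graph.vs["name"]) if self.graph.vcount() else []

    def edge_list(self):
        g = self.graph
        names = g.vs["name"] if g.vcount() else []
        return [
            (names[e.source], names[e.target], e["sign"], e["weight"])
            for e in g.es
        ]


@dataclass
class CommunityPartition:
    """Gene -> community assignment with contiguous integer ids (0, 1, ...,
    ordered by decreasing size) plus positive-edge counts within and between
    communities."""

    assignments: dict
    sizes: list
    intra_positive: dict = field(default_factory=dict)
    inter_positive: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    def members(self, community: int) -> list:
        return sorted(g for g, c in self.assignments.items() if c == community)


def build_graph(pairs, min_equivalent_pcc: float = 0.0) -> SignedGeneGraph:
    """Graph of BH-significant pairs with |equivalent PCC| above a floor.

    ``pairs`` is the scan's pair table (DataFrame with ``gene_a``,
    ``gene_b``, ``significant``, ``equivalent_pcc``); isolated genes are
    dropped, vertex order is canonicalized by gene id.
    """
    sig = pairs[pairs["significant"]]
    if min_equivalent_pcc > 0:
        sig = sig[np.abs(sig["equivalent_pcc"]) >= min_equivalent_pcc]
    edges = sorted(
        (min(a, b), max(a, b), float(w))
        for a, b, w in zip(sig["gene_a"], sig["gene_b"], sig["equivalent_pcc"])
    )
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    index = {g: i for i, g in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes),
        edges=[(index[a], index[b]) for a, b, _ in edges],
        vertex_attrs={"name": nodes},
        edge_attrs={
            "weight": [w for _, _, w in edges],
            "sign": [1 if w >= 0 else -1 for _, _, w in edges],
        },
    )
    return SignedGeneGraph(g)


def _walktrap_membership(g: ig.Graph, steps: int) -> list:
    if g.vcount() == 0:
        return []
    if g.ecount() == 0:
        return list(range(g.vcount()))
    return g.community_walktrap(steps=steps).as_clustering().membership


def _split_by_membership(names, membership):
    groups = {}
    for name, m in zip(names, membership):
        groups.setdefault(m, []).append(name)
    return list(groups.values())


def _positive_subgraph(g: ig.Graph) -> ig.Graph:
    keep = [e.index for e in g.es if e["sign"] > 0]
    return g.subgraph_edges(keep, delete_vertices=False)


def _pos_edge_counts(g: ig.Graph, comm_of: dict):
    intra, inter = {}, {}
    for e in g.es:
        if e["sign"] <= 0:
            continue
        ca = comm_of[g.vs[e.source]["name"]]
        cb = comm_of[g.vs[e.target]["name"]]
        if ca == cb:
            intra[ca] = intra.get(ca, 0) + 1
        else:
            key = (min(ca, cb), max(ca, cb))
            inter[key] = inter.get(key, 0) + 1
    return intra, inter


def _intra_density(size: int, n_edges: int) -> float:
    # singletons are treated as fully dense, so they never drive a merge
    possible = size * (size - 1) / 2
    return 1.0 if possible == 0 else n_edges / possible


def find_communities(
    signed: SignedGeneGraph,
    steps: int = 4,
    max_size: int = 1000,
    merge_density: float = 0.25,
) -> CommunityPartition:
    """Deterministic four-stage walktrap community extraction (see module
    docstring).  Disconnected graphs are handled per component."""
    g = signed.graph
    if g.vcount() == 0:
        return CommunityPartition(assignments={}, sizes=[])

    # stage 1: walktrap per connected component, unweighted, both signs
    communities = []
    for comp in g.connected_components():
        sub = g.subgraph(comp)
        membership = _walktrap_membership(sub, steps)
        communities.extend(_split_by_membership(sub.vs["name"], membership))

    # stage 2: drop negative links inside each community and split again
    split = []
    for comm in communities:
        sub = _positive_subgraph(g.subgraph(g.vs.select(name_in=comm)))
        for comp in sub.connected_components():
            ssub = sub.subgraph(comp)
            membership = _walktrap_membership(ssub, steps)
            split.extend(_split_by_membership(ssub.vs["name"], membership))
    communities = [sorted(c) for c in split]

    # stage 3: merge communities whose positive inter-density is large
    pos = _positive_subgraph(g)
    pre_merge_modularity = _positive_modularity(pos, communities)
    merged = True
    while merged:
        merged = False
        comm_of = {gene: i for i, c in enumerate(communities) for gene in c}
        intra, inter = _pos_edge_counts(g, comm_of)
        candidates = []
        for (ca, cb), n_between in inter.items():
            da = _intra_density(len(communities[ca]), intra.get(ca, 0))
            db = _intra_density(len(communities[cb]), intra.get(cb, 0))
            d_between = n_between / (len(communities[ca]) * len(communities[cb]))
            floor = merge_density * min(da, db)
            if floor > 0 and d_between > floor:
                candidates.append((d_between / floor, ca, cb))
        for _, ca, cb in sorted(candidates, reverse=True):
            trial = [c for i, c in enumerate(communities) if i not in (ca, cb)]
            trial.append(sorted(communities[ca] + communities[cb]))
            if _positive_modularity(pos, trial) >= pre_merge_modularity - 0.05:
                communities = trial
                merged = True
                break

    # stage 4: subdivide oversized communities with one more walktrap pass
    final = []
    for comm in communities:
        if len(comm) <= max_size:
            final.append(comm)
            continue
        sub = g.subgraph(g.vs.select(name_in=comm))
        membership = _walktrap_membership(sub, steps)
        final.extend(sorted(c) for c in _split_by_membership(sub.vs["name"], membership))

    # reinsert genes connected only by negative edges into the community they
    # touch most (reporting convenience; cannot create new communities)
    final = [c for c in final if c]
    final.sort(key=lambda c: (-len(c), c[0]))
    comm_of = {gene: i for i, c in enumerate(final) for gene in c}
    intra, inter = _pos_edge_counts(g, comm_of)
    sizes = [len(c) for c in final]
    return CommunityPartition(
        assignments=comm_of, sizes=sizes,
        intra_positive=intra, inter_positive=inter,
    )


def _positive_modularity(pos: ig.Graph, communities) -> float:
    comm_of = {}
    for i, c in enumerate(communities):
        for gene in c:
            comm_of[gene] = i
    membership = [comm_of[v["name"]] for v in pos.vs]
    if pos.ecount() == 0:
        return 0.0
    return pos.modularity(membership)


def top_connected_genes(
    partition: CommunityPartition,
    signed: SignedGeneGraph,
    community: int,
    k: int = 50,
) -> list:
    """The k most positively connected genes of a community.

    Genes are ranked by the sum of positive equivalent PCCs to other members;
    ties break by gene id.  Useful as cluster features.
    """
    members = partition.members(community)
    if not members:
        raise KeyError(f"community {community} does not exist")
    if k > len(members):
        warnings.warn(
            f"k={k} exceeds community size {len(members)}; returning all members"
        )
    member_set = set(members)
    score = {gene: 0.0 for gene in members}
    g = signed.graph
    names = g.vs["name"]
    for e in g.es:
        a, b = names[e.source], names[e.target]
        if e["weight"] > 0 and a in member_set and b in member_set:
            score[a] += e["weight"]
            score[b] += e["weight"]
    ranked = sorted(members, key=lambda gene: (-score[gene], gene))
    return ranked[: max(k, 0)]


def fold_enrichment(sig_positive_pairs, reference_pairs, detected_genes) -> float:
    """Enrichment of reference pairs among significant positive correlations.

    observed = |sig & ref| / |sig|; expected = |ref among detected| /
    (m (m-1) / 2) for m detected genes (reference pairs are restricted to
    detected genes before computing the expectation); returns their ratio.
    """
    detected = set(detected_genes)
    if len(detected) < 2:
        raise ValueError("need at least 2 detected genes")
    canon = lambda p: tuple(sorted(p[:2]))
    sig = {canon(p) for p in sig_positive_pairs}
    ref = {canon(p) for p in reference_pairs
           if p[0] in detected and p[1] in detected and p[0] != p[1]}
    if not sig:
        raise ValueError("no significant pairs: fold enrichment is undefined")
    m = len(detected)
    expected = len(ref) / (m * (m - 1) / 2)
    if expected == 0:
        raise ValueError("no reference pairs among detected genes: "
                         "fold enrichment is undefined")
    observed = len(sig & ref) / len(sig)
    return observed / expected
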