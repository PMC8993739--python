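"""Interaction-graph handling, topological centralities and core-GRN assembly.

The interaction graph is an undirected :class:`networkx.Graph` whose edges
carry a ``score`` attribute in [0, 1] (STRING-style combined confidence,
optionally rescaled from the 0-1000 integer export).  Hub extraction follows
the CytoHubba-style recipe: filter edges at the highest-confidence cutoff,
call hubs by degree, rank candidates by twelve topological centralities and
keep those associated with seed marker genes.

Centralities are computed per their operational definitions; several
(stress, radiality, eccentricity centrality, MNC, DMNC, MCC, bottleneck,
EPC) have no library implementation and are written out here.  Closeness is
harmonic (sum of reciprocal distances, 1/inf = 0) so disconnected graphs
need no special-casing; eccentricity centrality is the reciprocal of the
eccentricity within the node's component.  Isolated nodes score 0 under
every method.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSet

__all__ = [
    "CENTRALITY_METHODS",
    "CoreGRN",
    "read_edge_list",
    "write_edge_list",
    "filter_edges",
    "degree_hubs",
    "centrality",
    "epc",
    "rank_and_filter_hubs",
    "assemble_core_grn",
]

CENTRALITY_METHODS = (
    "degree", "epc", "mnc", "dmnc", "mcc", "bottleneck", "eccentricity",
    "closeness", "radiality", "betweenness", "stress", "clustering_coefficient",
)


# ---------------------------------------------------------------------------
# graph I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, score_scale: float = 1.0) -> nx.Graph:
    """Read a TSV edge list (node_a, node_b, combined_score).

    Set ``score_scale=1000`` for STRING-style integer scores on 0-1000.
    Self-loops are rejected; a duplicate pair keeps the higher score.
    """
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (node_a, node_b, score)")
    for a, b, s in df.itertuples(index=False):
        a, b = str(a).strip(), str(b).strip()
        score = float(s) / score_scale
        if a == b:
            raise ValueError(f"{path}: self-loop on node {a!r}")
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"{path}: score {score} outside [0, 1] for edge {a}-{b}")
        if g.has_edge(a, b):
            score = max(score, g[a][b]["score"])
        g.add_edge(a, b, score=score)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0)}\n")


# ---------------------------------------------------------------------------
# filtering and degree hubs
# ---------------------------------------------------------------------------

def filter_edges(graph: nx.Graph, min_score: float = 0.9) -> nx.Graph:
    """Keep edges with confidence score >= min_score (inclusive); nodes are retained."""
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from((a, b, d) for a, b, d in graph.edges(data=True)
                       if d.get("score", 1.0) >= min_score)
    return out


def degree_hubs(graph: nx.Graph, min_degree: int = 3, name: str = "degree_hubs") -> GeneSet:
    """Nodes with more than ``min_degree - 1`` connections (default: > 2, i.e. >= 3)."""
    hubs = tuple(sorted(n for n, d in graph.degree() if d >= min_degree))
    return GeneSet(name, f"nodes with degree >= {min_degree}", hubs)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _bfs_levels(graph: nx.Graph, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in graph[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def _shortest_path_counts(graph: nx.Graph, source) -> tuple[dict, dict]:
    """BFS distances and numbers of shortest paths from ``source``."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    order = []
    while q:
        v = q.popleft()
        order.append(v)
        for w in graph[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _stress(graph: nx.Graph) -> dict:
    """Stress centrality: number of shortest s-t paths (s < t) passing through v."""
    nodes = list(graph.nodes)
    info = {v: _shortest_path_counts(graph, v) for v in nodes}
    stress = {v: 0 for v in nodes}
    for v in nodes:
        dist_v, sigma_v = info[v]
        for si, s in enumerate(nodes):
            if s == v or s not in dist_v:
                continue
            dist_s, sigma_s = info[s]
            for t in nodes[si + 1:]:
                if t == v or t == s or t not in dist_s or t not in dist_v:
                    continue
                if dist_s[v] + dist_v[t] == dist_s[t]:
                    stress[v] += sigma_s[v] * sigma_v[t]
    return stress


def _radiality(graph: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n_c = len(comp)
        if n_c == 1:
            out[next(iter(comp))] = 0.0
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            out[v] = sum(diam + 1 - d for w, d in dist[v].items() if w != v) / (n_c - 1)
    return out


def _eccentricity_centrality(graph: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        ecc = nx.eccentricity(sub)
        for v, e in ecc.items():
            out[v] = 1.0 / e if e > 0 else 0.0
    return out


def _neighbourhood_component(graph: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the subgraph induced by v's neighbours."""
    nbrs = list(graph[v])
    if not nbrs:
        return nx.Graph()
    sub = graph.subgraph(nbrs)
    # deterministic tie-break: among equal-size components pick the one with
    # the smallest sorted node tuple
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), tuple(sorted(map(str, c)))))
    return sub.subgraph(comps[0]).copy() if comps else nx.Graph()


def _mnc(graph: nx.Graph) -> dict:
    return {v: _neighbourhood_component(graph, v).number_of_nodes() for v in graph.nodes}


def _dmnc(graph: nx.Graph) -> dict:
    out = {}
    for v in graph.nodes:
        comp = _neighbourhood_component(graph, v)
        nv = comp.number_of_nodes()
        out[v] = comp.number_of_edges() / nv ** 1.7 if nv > 0 else 0.0
    return out


def _mcc(graph: nx.Graph) -> dict:
    """Maximal clique centrality: sum over maximal cliques C containing v,
    |C| >= 2, of (|C| - 1)!; isolated nodes score 0."""
    out = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def _bottleneck_tree(graph: nx.Graph, root) -> dict:
    """Deterministic shortest-path tree: parent = smallest-index neighbour
    at the shallower BFS level.  Returns child -> parent."""
    dist = _bfs_levels(graph, root)
    parent = {}
    for v in dist:
        if v == root:
            continue
        cands = [w for w in graph[v] if dist[w] == dist[v] - 1]
        parent[v] = min(cands, key=str)
    return parent


def _bottleneck(graph: nx.Graph) -> dict:
    out = {v: 0.0 for v in graph.nodes}
    for root in graph.nodes:
        parent = _bottleneck_tree(graph, root)
        tree_nodes = set(parent) | {root}
        n_s = len(tree_nodes)
        if n_s == 1:
            continue
        desc = {v: 0 for v in tree_nodes}
        # count strict descendants by walking each node's ancestor chain
        for v in parent:
            p = parent[v]
            while True:
                desc[p] += 1
                if p == root:
                    break
                p = parent[p]
        for v in tree_nodes:
            if desc[v] > n_s / 4.0:
                out[v] += 1.0
    return out


def centrality(graph: nx.Graph, method: str, n_reductions: int = 1000,
               retain_p: float = 0.5, seed: int = 0) -> pd.Series:
    """Compute one of the twelve topological centralities.

    EPC is stochastic and controlled by ``n_reductions``/``retain_p``/
    ``seed``; every other method is deterministic.  All scores are finite
    and >= 0; isolated nodes score 0 for every method.
    """
    if method not in CENTRALITY_METHODS:
        raise ValueError(f"unknown centrality method {method!r}")
    if method == "degree":
        scores = {v: float(d) for v, d in graph.degree()}
    elif method == "closeness":
        scores = {v: float(s) for v, s in nx.harmonic_centrality(graph).items()}
    elif method == "betweenness":
        scores = {v: float(s) for v, s in
                  nx.betweenness_centrality(graph, normalized=False).items()}
    elif method == "clustering_coefficient":
        scores = {v: float(s) for v, s in nx.clustering(graph).items()}
    elif method == "stress":
        scores = {v: float(s) for v, s in _stress(graph).items()}
    elif method == "radiality":
        scores = _radiality(graph)
    elif method == "eccentricity":
        scores = _eccentricity_centrality(graph)
    elif method == "mnc":
        scores = {v: float(s) for v, s in _mnc(graph).items()}
    elif method == "dmnc":
        scores = _dmnc(graph)
    elif method == "mcc":
        scores = _mcc(graph)
    elif method == "bottleneck":
        scores = _bottleneck(graph)
    else:  # epc
        return epc(graph, n_reductions=n_reductions, retain_p=retain_p, seed=seed)
    s = pd.Series(scores, name=method).sort_index()
    return s.astype(float)


def epc(graph: nx.Graph, n_reductions: int = 1000, retain_p: float = 0.5,
        seed: int = 0) -> pd.Series:
    """Edge-percolated component centrality (Monte Carlo).

    Each of ``n_reductions`` reductions keeps every edge independently with
    probability ``retain_p``; a node's score is the mean number of other
    nodes it can reach across reductions.  Fixed seed => identical output.
    """
    if n_reductions < 1:
        raise ValueError("n_reductions must be >= 1")
    if not (0.0 <= retain_p <= 1.0):
        raise ValueError("retain_p must be in [0, 1]")
    nodes = sorted(graph.nodes, key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1])))
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(nodes))
    for _ in range(n_reductions):
        keep = rng.random(len(edges)) < retain_p
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                totals[idx[v]] += size - 1
    return pd.Series(totals / n_reductions, index=nodes, name="epc").sort_index()


# ---------------------------------------------------------------------------
# hub ranking and core GRN
# ---------------------------------------------------------------------------

@dataclass
class CoreGRN:
    """A hub gene set plus the edges among hubs and per-node provenance.

    Provenance records, per candidate, its degree, its dense rank under each
    centrality method, whether it is (adjacent to) a seed marker, and which
    of the three hub criteria it passed.
    """

    hubs: GeneSet
    edges: list[tuple[str, str, float]]
    provenance: pd.DataFrame
    n_candidates: int = 0


def _dense_ranks(scores: pd.Series) -> pd.Series:
    """Dense descending ranks: the best score has rank 1; ties share a rank."""
    return scores.rank(method="dense", ascending=False).astype(int)


def rank_and_filter_hubs(graph: nx.Graph, methods: Sequence[str], candidates: GeneSet,
                         seeds: GeneSet, top_k: int | None = None,
                         min_methods: int = 1, epc_reductions: int = 1000,
                         epc_retain_p: float = 0.5, seed: int = 0,
                         min_degree: int = 3) -> CoreGRN:
    """Select hubs among candidate genes by degree, centrality rank and seed association.

    A candidate becomes a hub iff (i) its degree in ``graph`` is at least
    ``min_degree``, (ii) it ranks within ``top_k`` (dense ranks among
    candidates) under at least ``min_methods`` of the requested centrality
    methods, and (iii) it is a seed marker or directly adjacent to one.
    """
    if not methods:
        raise ValueError("at least one centrality method is required")
    unknown = [m for m in methods if m not in CENTRALITY_METHODS]
    if unknown:
        raise ValueError(f"unknown centrality methods {unknown}")
    cand = [c for c in candidates.members if c in graph]
    missing = set(candidates.members) - set(cand)
    if missing:
        raise ValueError(f"candidates not in graph: {sorted(missing)[:5]}")
    if top_k is None:
        top_k = len(cand)

    seed_set = seeds.as_set()
    deg = dict(graph.degree)
    rank_cols = {}
    for m in methods:
        scores = centrality(graph, m, n_reductions=epc_reductions,
                            retain_p=epc_retain_p, seed=seed)
        rank_cols[f"rank_{m}"] = _dense_ranks(scores.loc[cand])

    prov = pd.DataFrame(index=pd.Index(cand, name="gene_id"))
    prov["degree"] = [deg[c] for c in cand]
    for col, ranks in rank_cols.items():
        prov[col] = ranks
    n_top = pd.DataFrame(rank_cols).le(top_k).sum(axis=1)
    prov["n_methods_top_k"] = n_top
    prov["seed_associated"] = [
        c in seed_set or any(nb in seed_set for nb in graph[c]) for c in cand
    ]
    prov["pass_degree"] = prov["degree"] >= min_degree
    prov["pass_ranking"] = prov["n_methods_top_k"] >= min_methods
    prov["is_hub"] = prov["pass_degree"] & prov["pass_ranking"] & prov["seed_associated"]

    hub_genes = tuple(sorted(prov.index[prov["is_hub"]]))
    hubs = GeneSet("core_grn_hubs", "hub genes of the core regulatory network", hub_genes)
    hub_sub = graph.subgraph(hub_genes)
    edges = sorted((a, b, d.get("score", 1.0)) for a, b, d in hub_sub.edges(data=True))
    return CoreGRN(hubs=hubs, edges=edges, provenance=prov, n_candidates=len(cand))


def assemble_core_grn(coexpressed: GeneSet, functional: GeneSet, graph: nx.Graph,
                      seeds: GeneSet, min_score: float = 0.9,
                      methods: Sequence[str] = CENTRALITY_METHODS,
                      top_k: int | None = None, min_methods: int = 1,
                      epc_reductions: int = 1000, epc_retain_p: float = 0.5,
                      seed: int = 0, min_degree: int = 3) -> CoreGRN:
    """Assemble the core regulatory network end to end.

    Candidates are the genes both co-expressed in the tissue and annotated
    to the relevant functions; the interaction graph is restricted to them,
    confidence-filtered, and hubs are selected by
    :func:`rank_and_filter_hubs`.
    """
    cand_genes = sorted(coexpressed.as_set() & functional.as_set())
    if not cand_genes:
        empty = GeneSet("core_grn_hubs", "empty", ())
        return CoreGRN(hubs=empty, edges=[], provenance=pd.DataFrame(), n_candidates=0)
    sub = graph.subgraph([g for g in cand_genes if g in graph]).copy()
    sub.add_nodes_from(g for g in cand_genes if g not in sub)
    filtered = filter_edges(sub, min_score)
    candidates = GeneSet("candidates", "coexpressed AND functional", tuple(cand_genes))
    return rank_and_filter_hubs(filtered, methods, candidates, seeds, top_k=top_k,
                                min_methods=min_methods, epc_reductions=epc_reductions,
                                epc_retain_p=epc_retain_p, seed=seed, min_degree=min_degree)
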