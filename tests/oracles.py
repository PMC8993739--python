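"""Independent brute-force oracles used to verify the package's network math.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration over subsets/paths, Fraction arithmetic — and shares no code
with the implementation it checks.  Graphs are plain (nodes, adjacency-set)
structures, not networkx objects.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def brute_tom(a):
    """Topological overlap by direct triple loop over the formula."""
    n = len(a)
    tom = [[0.0] * n for _ in range(n)]
    k = [sum(a[i]) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i][j] = 1.0
                continue
            l_ij = sum(a[i][u] * a[u][j] for u in range(n))
            tom[i][j] = (l_ij + a[i][j]) / (min(k[i], k[j]) + 1.0 - a[i][j])
    return tom


# ---------------------------------------------------------------------------
# tiny graph helpers (adjacency as dict node -> sorted set of neighbours)
# ---------------------------------------------------------------------------

def make_adj(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def all_distances(adj):
    """Floyd-Warshall; missing pairs = infinity (absent from the dict)."""
    nodes = list(adj)
    dist = {v: {v: 0} for v in nodes}
    for v in nodes:
        for w in adj[v]:
            dist[v][w] = 1
    for k in nodes:
        for i in nodes:
            if k not in dist[i]:
                continue
            for j in nodes:
                if j not in dist[k]:
                    continue
                d = dist[i][k] + dist[k][j]
                if j not in dist[i] or d < dist[i][j]:
                    dist[i][j] = d
    return dist


def enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths by DFS guided by the distance table."""
    if t not in dist[s]:
        return []
    paths = []

    def walk(v, acc):
        if v == t:
            paths.append(acc)
            return
        for w in adj[v]:
            if t in dist[w] and dist[v][t] == dist[w][t] + 1:
                walk(w, acc + [w])

    walk(s, [s])
    return paths


def brute_betweenness_stress(adj):
    nodes = sorted(adj, key=str)
    dist = all_distances(adj)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bet[v] += through / len(paths)
                stress[v] += through
    return bet, stress


def brute_harmonic_closeness(adj):
    dist = all_distances(adj)
    return {v: sum(1.0 / d for w, d in dist[v].items() if w != v) for v in adj}


def brute_eccentricity_centrality(adj):
    dist = all_distances(adj)
    out = {}
    for v in adj:
        reach = [d for w, d in dist[v].items() if w != v]
        ecc = max(reach) if reach else 0
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def brute_radiality(adj):
    dist = all_distances(adj)
    out = {}
    for v in adj:
        comp = set(dist[v])
        if len(comp) == 1:
            out[v] = 0.0
            continue
        diam = max(dist[a][b] for a in comp for b in comp)
        out[v] = sum(diam + 1 - dist[v][w] for w in comp if w != v) / (len(comp) - 1)
    return out


def brute_clustering(adj):
    out = {}
    for v in adj:
        nbrs = sorted(adj[v], key=str)
        d = len(nbrs)
        if d < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * links / (d * (d - 1))
    return out


def _components(adj, subset):
    """Connected components of the induced subgraph, by naive flood fill."""
    subset = set(subset)
    seen = set()
    comps = []
    for start in sorted(subset, key=str):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in adj[v]:
                if w in subset and w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def brute_mnc_dmnc(adj):
    mnc, dmnc = {}, {}
    for v in adj:
        comps = _components(adj, adj[v])
        if not comps:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        comps.sort(key=lambda c: (-len(c), tuple(sorted(map(str, c)))))
        comp = comps[0]
        edges = sum(1 for a, b in itertools.combinations(sorted(comp, key=str), 2) if b in adj[a])
        mnc[v] = len(comp)
        dmnc[v] = edges / len(comp) ** 1.7
    return mnc, dmnc


def brute_mcc(adj):
    """Maximal-clique centrality via exhaustive subset enumeration."""
    nodes = sorted(adj, key=str)

    def is_clique(sub):
        return all(b in adj[a] for a, b in itertools.combinations(sub, 2))

    cliques = [set(sub) for r in range(2, len(nodes) + 1)
               for sub in itertools.combinations(nodes, r) if is_clique(sub)]
    maximal = [c for c in cliques
               if not any(c < d for d in cliques)]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def brute_bottleneck(adj):
    """Bottleneck by independently rebuilding each deterministic BFS tree.

    Parent = lexicographically smallest neighbour one level closer to the
    root; v scores a point for root s when strictly more than a quarter of
    the tree's nodes lie strictly below v.
    """
    dist = all_distances(adj)
    out = {v: 0.0 for v in adj}
    for root in adj:
        tree = {w for w in adj if w in dist[root]}
        if len(tree) == 1:
            continue
        parent = {}
        for w in tree:
            if w == root:
                continue
            parent[w] = min((u for u in adj[w] if dist[root].get(u, -1) == dist[root][w] - 1),
                            key=str)
        for v in tree:
            desc = 0
            for w in tree:
                if w == v:
                    continue
                p = w
                while p != root:
                    p = parent[p]
                    if p == v:
                        desc += 1
                        break
                    # keep climbing
            if desc > len(tree) / 4.0:
                out[v] += 1.0
    return out


def exhaustive_epc(adj, edges, retain_p):
    """Exact EPC expectation and per-reduction variance over all 2^|E| subgraphs."""
    nodes = sorted(adj, key=str)
    m = len(edges)
    exp = {v: 0.0 for v in nodes}
    exp2 = {v: 0.0 for v in nodes}
    for keep_mask in itertools.product([0, 1], repeat=m):
        kept = [e for e, k in zip(edges, keep_mask) if k]
        prob = retain_p ** sum(keep_mask) * (1 - retain_p) ** (m - sum(keep_mask))
        sub = make_adj(nodes, kept)
        for comp in _components(sub, nodes):
            for v in comp:
                x = len(comp) - 1
                exp[v] += prob * x
                exp2[v] += prob * x * x
    var = {v: exp2[v] - exp[v] ** 2 for v in nodes}
    return exp, var


def round_pct_oracle(count, total, decimals):
    """Exact half-away-from-zero rounding of 100*count/total via Fractions."""
    scaled = Fraction(100 * count, total) * 10 ** decimals
    floor = scaled.numerator // scaled.denominator
    rem = scaled - floor
    if rem * 2 >= 1:
        floor += 1
    return floor / 10 ** decimals
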