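"""Independent brute-force oracles for the centrality and core measures.

Everything here is computed by exhaustive enumeration (all shortest paths,
all vertex subsets) or by networkx primitives, never by the code under test.
Intended for connected graphs of <= 10 nodes.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np

from cliquescreen.netcore import Network


def net_from_nx(G: nx.Graph) -> Network:
    return Network.from_edges([str(v) for v in G.nodes], [(str(a), str(b)) for a, b in G.edges])


def random_family(count: int, seed: int = 12345, max_nodes: int = 8) -> list[nx.Graph]:
    """Seeded family of connected random graphs with string node labels."""
    graphs = []
    i = 0
    while len(graphs) < count:
        rng = np.random.default_rng(seed + i)
        i += 1
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.3, 0.9))
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for a in range(n):
            for b in range(a + 1, n):
                if rng.random() < p:
                    G.add_edge(a, b)
        if nx.is_connected(G):
            graphs.append(nx.relabel_nodes(G, {v: f"n{v}" for v in G.nodes}))
    return graphs


def _all_shortest_paths(G: nx.Graph):
    """Dict (s, t) -> list of shortest paths (node tuples), unordered pairs."""
    out = {}
    nodes = sorted(G.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if nx.has_path(G, s, t):
                out[(s, t)] = [tuple(p) for p in nx.all_shortest_paths(G, s, t)]
    return out


def betweenness_oracle(G: nx.Graph) -> dict[str, float]:
    paths = _all_shortest_paths(G)
    scores = {v: 0.0 for v in G.nodes}
    for (s, t), plist in paths.items():
        for v in G.nodes:
            if v in (s, t):
                continue
            hit = sum(1 for p in plist if v in p)
            if hit:
                scores[v] += hit / len(plist)
    return scores


def stress_oracle(G: nx.Graph) -> dict[str, float]:
    paths = _all_shortest_paths(G)
    scores = {v: 0.0 for v in G.nodes}
    for (s, t), plist in paths.items():
        for p in plist:
            for v in p[1:-1]:
                scores[v] += 1
    return scores


def closeness_oracle(G: nx.Graph) -> dict[str, float]:
    scores = {}
    for v in G.nodes:
        d = nx.single_source_shortest_path_length(G, v)
        scores[v] = sum(1.0 / dd for w, dd in d.items() if w != v)
    return scores


def radiality_oracle(G: nx.Graph) -> dict[str, float]:
    scores = {}
    for comp in nx.connected_components(G):
        H = G.subgraph(comp)
        diam = nx.diameter(H)
        for v in comp:
            d = nx.single_source_shortest_path_length(H, v)
            scores[v] = sum(diam + 1 - dd for w, dd in d.items() if w != v) / (
                len(comp) - 1
            )
    return scores


def eccentricity_oracle(G: nx.Graph) -> dict[str, float]:
    scores = {}
    for comp in nx.connected_components(G):
        H = G.subgraph(comp)
        for v, e in nx.eccentricity(H).items():
            scores[v] = 1.0 / e
    return scores


def clustering_oracle(G: nx.Graph) -> dict[str, float]:
    return {v: float(c) for v, c in nx.clustering(G).items()}


def degree_oracle(G: nx.Graph) -> dict[str, float]:
    return {v: float(d) for v, d in G.degree()}


def _neighborhood_components(G: nx.Graph, v):
    H = G.subgraph(set(G.neighbors(v)))
    return list(nx.connected_components(H))


def mnc_oracle(G: nx.Graph) -> dict[str, float]:
    return {
        v: float(max(len(c) for c in _neighborhood_components(G, v)))
        for v in G.nodes
    }


def dmnc_oracle(G: nx.Graph, epsilon: float = 1.7) -> dict[str, float]:
    scores = {}
    for v in G.nodes:
        comps = _neighborhood_components(G, v)
        best = max(
            comps,
            key=lambda c: (len(c), G.subgraph(c).number_of_edges(), min(c)),
        )
        e = G.subgraph(best).number_of_edges()
        scores[v] = e / len(best) ** epsilon if e else 0.0
    return scores


def maximal_cliques_bruteforce(G: nx.Graph) -> list[frozenset]:
    """All maximal cliques by subset enumeration (n <= ~12)."""
    nodes = sorted(G.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            s = set(combo)
            if all(G.has_edge(a, b) for a, b in itertools.combinations(combo, 2)):
                cliques.append(s)
    return [
        frozenset(c)
        for c in cliques
        if not any(c < other for other in cliques)
    ]


def mcc_oracle(G: nx.Graph) -> dict[str, int]:
    cliques = maximal_cliques_bruteforce(G)
    scores = {v: 0 for v in G.nodes}
    for c in cliques:
        if len(c) < 2:
            continue
        w = math.factorial(len(c) - 1)
        for v in c:
            scores[v] += w
    return scores


def bottleneck_oracle(G: nx.Graph) -> dict[str, float]:
    """Same deterministic BFS-tree convention as the implementation, but an
    independent realization: explicit path walking instead of subtree sizes."""
    scores = {v: 0.0 for v in G.nodes}
    for s in sorted(G.nodes):
        if not nx.has_path(G, s, s):  # always true; keeps parity with roots loop
            continue
        parent = {s: s}
        order = [s]
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in sorted(G.neighbors(v)):
                if w not in parent:
                    parent[w] = v
                    order.append(w)
                    queue.append(w)
        tree_nodes = list(parent)
        meet = {v: 0 for v in tree_nodes}
        for w in tree_nodes:
            if w == s:
                continue
            x = w
            while x != s:  # walk the tree path from w back to the root
                meet[x] += 1
                x = parent[x]
        for v in tree_nodes:
            if v != s and meet[v] > len(tree_nodes) / 4.0:
                scores[v] += 1
    return scores


def epc_exact_expectation(G: nx.Graph, threshold: float) -> dict[str, float]:
    """Exact expected component size per node over all 2^m edge subsets,
    divided by n (edge survives with probability 1 - threshold)."""
    edges = list(G.edges)
    n = G.number_of_nodes()
    p_keep = 1.0 - threshold
    scores = {v: 0.0 for v in G.nodes}
    for mask in range(2 ** len(edges)):
        kept = [e for i, e in enumerate(edges) if mask >> i & 1]
        prob = p_keep ** len(kept) * (1 - p_keep) ** (len(edges) - len(kept))
        H = nx.Graph()
        H.add_nodes_from(G.nodes)
        H.add_edges_from(kept)
        for comp in nx.connected_components(H):
            for v in comp:
                scores[v] += prob * len(comp)
    return {v: s / n for v, s in scores.items()}


def epc_same_stream_oracle(G: nx.Graph, params) -> dict[str, float]:
    """Naive replicate-by-replicate EPC consuming the identical uniform
    stream contract: one (T, m) block in sorted-edge order."""
    nodes = sorted(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted((min(index[a], index[b]), max(index[a], index[b])) for a, b in G.edges)
    rng = np.random.default_rng(params.rng_seed)
    keep = rng.random((params.epc_iterations, len(edges))) >= params.epc_threshold
    totals = {v: 0.0 for v in nodes}
    for k in range(params.epc_iterations):
        H = nx.Graph()
        H.add_nodes_from(range(len(nodes)))
        H.add_edges_from(e for e, kp in zip(edges, keep[k]) if kp)
        for comp in nx.connected_components(H):
            for i in comp:
                totals[nodes[i]] += len(comp)
    return {v: t / len(nodes) for v, t in totals.items()}


def highest_kcore_bruteforce(G: nx.Graph, subset) -> tuple[int, set]:
    """Highest-k core by subset enumeration: k* is the max over induced
    subgraphs of the minimum degree; the core is the union of all subsets
    achieving k*."""
    subset = sorted(subset)
    best_k = 0
    for r in range(1, len(subset) + 1):
        for combo in itertools.combinations(subset, r):
            H = G.subgraph(combo)
            if len(combo) == 1:
                continue
            mindeg = min(d for _, d in H.degree())
            best_k = max(best_k, mindeg)
    if best_k == 0:
        return 0, set(subset)
    members: set = set()
    for r in range(1, len(subset) + 1):
        for combo in itertools.combinations(subset, r):
            H = G.subgraph(combo)
            if H.number_of_nodes() and min(d for _, d in H.degree()) >= best_k:
                members |= set(combo)
    return best_k, members


def node_score_oracle(G: nx.Graph, v) -> float:
    closed = set(G.neighbors(v)) | {v}
    k, members = highest_kcore_bruteforce(G, closed)
    if k == 0 or len(members) < 2:
        return 0.0
    H = G.subgraph(members)
    dens = H.number_of_edges() / (len(members) * (len(members) - 1) / 2.0)
    return k * dens


ORACLES = {
    "Betweenness": betweenness_oracle,
    "BottleNeck": bottleneck_oracle,
    "CC": clustering_oracle,
    "Closeness": closeness_oracle,
    "Degree": degree_oracle,
    "DMNC": dmnc_oracle,
    "EcCentricity": eccentricity_oracle,
    "MCC": mcc_oracle,
    "MNC": mnc_oracle,
    "Radiality": radiality_oracle,
    "Stress": stress_oracle,
}

EXACT_METRICS = {"Degree", "Stress", "MCC", "MNC", "BottleNeck"}
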