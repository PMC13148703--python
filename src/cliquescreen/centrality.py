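"""The twelve hub-ranking centrality measures.

Five local measures (Degree, Clustering Coefficient, MNC, DMNC, MCC) score a
node from its immediate neighborhood; seven global measures (Betweenness,
BottleNeck, Closeness, EcCentricity, EPC, Radiality, Stress) score it from
shortest-path or percolation structure of the whole graph.  All distances are
unweighted hop counts; unreachable pairs contribute 0 wherever a reciprocal
is summed, and component-local quantities (radiality, eccentricity) are
restricted to the node's connected component.

Maximal clique centrality (MCC) is the headline measure::

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!

so membership in one large clique, or in many small ones, both raise the
score.  A node whose neighborhood contains no edge degenerates to its degree
(every incident edge is its own maximal 2-clique contributing 1! = 1).
Factorials are exact integers: clique sizes beyond 170 would overflow any
float representation.

Only nodes of degree >= 1 are ranked.  Ranks are competition ("1224") ranks:
tied scores share the best rank and the next distinct score's rank counts
every preceding gene.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .netcore import Network

METRIC_NAMES = (
    "Betweenness",
    "BottleNeck",
    "CC",
    "Closeness",
    "Degree",
    "DMNC",
    "EcCentricity",
    "EPC",
    "MCC",
    "MNC",
    "Radiality",
    "Stress",
)

LOCAL_METRICS = frozenset({"Degree", "CC", "DMNC", "MCC", "MNC"})
GLOBAL_METRICS = frozenset(METRIC_NAMES) - LOCAL_METRICS


@dataclass(frozen=True)
class MetricParams:
    """Tunable parameters of the stochastic / parametric measures.

    epc_iterations : Monte-Carlo replicates for EPC.
    epc_threshold  : an edge survives a replicate iff its uniform(0,1) draw
                     is >= this threshold; 0.5 is the conventional default.
    dmnc_epsilon   : exponent of the DMNC denominator |V|**epsilon (1.7).
    rng_seed       : seed of the EPC percolation stream.
    closeness_variant : "harmonic" (reciprocal-sum, robust to disconnected
                     graphs) or "classic" (component-restricted (n_C-1)/sum d).
    """

    epc_iterations: int = 1000
    epc_threshold: float = 0.5
    dmnc_epsilon: float = 1.7
    rng_seed: int = 0
    closeness_variant: str = "harmonic"

    def __post_init__(self):
        if self.epc_iterations < 1:
            raise ParameterError("epc_iterations must be >= 1")
        if not 0.0 <= self.epc_threshold <= 1.0:
            raise ParameterError("epc_threshold must be in [0, 1]")
        if self.closeness_variant not in ("harmonic", "classic"):
            raise ParameterError(f"unknown closeness variant {self.closeness_variant!r}")


DEFAULT_PARAMS = MetricParams()


def competition_ranks(scores: Mapping[str, float]) -> dict[str, int]:
    """Competition ("1224") ranking: rank(v) = 1 + #{u : score(u) > score(v)}."""
    values = sorted(scores.values(), reverse=True)
    first_at: dict[float, int] = {}
    for i, s in enumerate(values):
        if s not in first_at:
            first_at[s] = i + 1
    return {g: first_at[s] for g, s in scores.items()}


@dataclass(frozen=True)
class CentralityTable:
    """Per-gene scores and competition ranks for one metric."""

    metric: str
    scores: dict[str, float]
    ranks: dict[str, int]
    params: MetricParams | None = None

    @classmethod
    def from_scores(
        cls, metric: str, scores: Mapping[str, float], params: MetricParams | None = None
    ) -> "CentralityTable":
        scores = dict(scores)
        return cls(metric, scores, competition_ranks(scores), params)

    def __len__(self) -> int:
        return len(self.scores)

    def ordered_genes(self) -> list[str]:
        """Genes best-first: descending score, lexicographic tie-break."""
        return sorted(self.scores, key=lambda g: (-self.scores[g], g))

    def to_frame(self) -> pd.DataFrame:
        genes = self.ordered_genes()
        return pd.DataFrame(
            {
                "gene": genes,
                "score": [self.scores[g] for g in genes],
                "rank": [self.ranks[g] for g in genes],
            }
        )


def rank_table(scores: Mapping[str, float], metric: str = "custom") -> CentralityTable:
    """Wrap an arbitrary score map in a competition-ranked table."""
    return CentralityTable.from_scores(metric, scores)


# ---------------------------------------------------------------------------
# indexed representation: ranked (degree >= 1) nodes, sorted lexicographically
# so index order doubles as the deterministic BFS visiting order.


def _prepare(net: Network) -> tuple[list[str], list[list[int]]]:
    nodes = net.ranked_nodes()
    index = {v: i for i, v in enumerate(nodes)}
    adj = [sorted(index[u] for u in net.neighbors(v)) for v in nodes]
    return nodes, adj


def _bfs(adj: list[list[int]], s: int):
    """Shortest-path BFS from s: distances, path counts, visit order, preds."""
    n = len(adj)
    dist = [-1] * n
    sigma = [0.0] * n
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[s] = 0
    sigma[s] = 1.0
    order = [s]
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
                order.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, order, preds


def _distance_matrix(adj: list[list[int]]) -> np.ndarray:
    """All-pairs hop counts; -1 marks unreachable pairs."""
    n = len(adj)
    D = np.full((n, n), -1, dtype=np.int32)
    for s in range(n):
        dist = [-1] * n
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        D[s] = dist
    return D


# ---------------------------------------------------------------------------
# local measures


def degree_centrality(net: Network, params: MetricParams | None = None) -> CentralityTable:
    nodes, adj = _prepare(net)
    return CentralityTable.from_scores(
        "Degree", {v: float(len(a)) for v, a in zip(nodes, adj)}, params
    )


def clustering_coefficient(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """CC(v) = 2 e_v / (k_v (k_v - 1)); 0 for degree < 2."""
    nodes, _ = _prepare(net)
    scores = {}
    for v in nodes:
        nbrs = net.neighbors(v)
        k = len(nbrs)
        if k < 2:
            scores[v] = 0.0
            continue
        e = sum(1 for u in nbrs for w in net.neighbors(u) if w in nbrs) // 2
        scores[v] = 2.0 * e / (k * (k - 1))
    return CentralityTable.from_scores("CC", scores, params)


def _neighborhood_components(net: Network, v: str) -> list[set[str]]:
    """Connected components of the open-neighborhood-induced subgraph."""
    nbrs = net.neighbors(v)
    comps: list[set[str]] = []
    seen: set[str] = set()
    for start in sorted(nbrs):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in net.neighbors(x):
                if y in nbrs and y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comps.append(comp)
    return comps


def _mnc_component(net: Network, v: str) -> set[str]:
    """Largest neighborhood component; ties broken by (edge count, members)."""
    comps = _neighborhood_components(net, v)

    def edge_count(comp: set[str]) -> int:
        return sum(1 for u in comp for w in net.neighbors(u) if w in comp) // 2

    return max(comps, key=lambda c: (len(c), edge_count(c), min(c)))


def mnc(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Maximum neighborhood component: size of the largest connected
    component of the subgraph induced by N(v), v excluded."""
    nodes, _ = _prepare(net)
    scores = {v: float(len(_mnc_component(net, v))) for v in nodes}
    return CentralityTable.from_scores("MNC", scores, params)


def dmnc(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Density of the maximum neighborhood component: |E(H)| / |V(H)|**eps."""
    params = params or DEFAULT_PARAMS
    nodes, _ = _prepare(net)
    scores = {}
    for v in nodes:
        comp = _mnc_component(net, v)
        e = sum(1 for u in comp for w in net.neighbors(u) if w in comp) // 2
        scores[v] = e / len(comp) ** params.dmnc_epsilon if e else 0.0
    return CentralityTable.from_scores("DMNC", scores, params)


def _maximal_cliques(neigh: list[set[int]]) -> list[list[int]]:
    """Bron--Kerbosch with pivoting over an indexed adjacency-set list."""
    cliques: list[list[int]] = []

    def expand(R: list[int], P: set[int], X: set[int]) -> None:
        if not P and not X:
            cliques.append(R.copy())
            return
        pivot = max(P | X, key=lambda u: (len(P & neigh[u]), -u))
        for v in sorted(P - neigh[pivot]):
            expand(R + [v], P & neigh[v], X & neigh[v])
            P.remove(v)
            X.add(v)

    expand([], set(range(len(neigh))), set())
    return cliques


def mcc(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Maximal clique centrality: sum of (|C|-1)! over maximal cliques
    containing v.  Exact integer arithmetic throughout."""
    nodes, adj = _prepare(net)
    neigh = [set(a) for a in adj]
    scores: dict[str, int] = {v: 0 for v in nodes}
    for clique in _maximal_cliques(neigh):
        if len(clique) < 2:  # isolated vertices are not ranked anyway
            continue
        w = math.factorial(len(clique) - 1)
        for i in clique:
            scores[nodes[i]] += w
    return CentralityTable.from_scores("MCC", scores, params)


# ---------------------------------------------------------------------------
# global measures


def betweenness(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Raw (unnormalized) shortest-path betweenness over unordered pairs,
    computed with Brandes' dependency accumulation."""
    nodes, adj = _prepare(net)
    n = len(nodes)
    bc = [0.0] * n
    for s in range(n):
        _, sigma, order, preds = _bfs(adj, s)
        delta = [0.0] * n
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return CentralityTable.from_scores(
        "Betweenness", {nodes[i]: bc[i] / 2.0 for i in range(n)}, params
    )


def stress(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Number of shortest paths (unordered pairs) passing through v."""
    nodes, adj = _prepare(net)
    n = len(nodes)
    st = [0.0] * n
    for s in range(n):
        _, sigma, order, preds = _bfs(adj, s)
        acc = [0.0] * n
        delta = [0.0] * n
        for w in reversed(order):
            delta[w] = sigma[w] * acc[w]
            for v in preds[w]:
                acc[v] += 1.0 + delta[w] / sigma[w]
            if w != s:
                st[w] += delta[w]
    return CentralityTable.from_scores(
        "Stress", {nodes[i]: st[i] / 2.0 for i in range(n)}, params
    )


def closeness(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Harmonic closeness sum_w 1/d(v, w) by default; the classic
    component-restricted form (n_C - 1) / sum_w d(v, w) behind the
    ``closeness_variant`` flag."""
    params = params or DEFAULT_PARAMS
    nodes, adj = _prepare(net)
    D = _distance_matrix(adj)
    scores = {}
    for i, v in enumerate(nodes):
        d = D[i]
        reach = d > 0
        if params.closeness_variant == "harmonic":
            scores[v] = float(np.sum(1.0 / d[reach]))
        else:
            total = float(np.sum(d[reach]))
            scores[v] = float(np.count_nonzero(reach)) / total if total else 0.0
    return CentralityTable.from_scores("Closeness", scores, params)


def radiality(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Within v's component C (size n_C, diameter D_C):
    sum_{w in C, w != v} (D_C + 1 - d(v, w)) / (n_C - 1)."""
    nodes, adj = _prepare(net)
    index = {v: i for i, v in enumerate(nodes)}
    D = _distance_matrix(adj)
    scores: dict[str, float] = {}
    for comp in net.subgraph(nodes).components():
        idx = np.array(sorted(index[v] for v in comp))
        sub = D[np.ix_(idx, idx)]
        diam = int(sub.max())
        n_c = len(idx)
        for k, i in enumerate(idx):
            row = sub[k]
            scores[nodes[i]] = float(np.sum(diam + 1 - row[row > 0]) / (n_c - 1))
    return CentralityTable.from_scores("Radiality", scores, params)


def eccentricity_centrality(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """1 / (maximum hop distance within v's component)."""
    nodes, adj = _prepare(net)
    D = _distance_matrix(adj)
    scores = {}
    for i, v in enumerate(nodes):
        d = D[i]
        scores[v] = 1.0 / float(d.max())
    return CentralityTable.from_scores("EcCentricity", scores, params)


def epc(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """Edge percolated component, Monte Carlo.

    Each replicate retains every edge independently iff its uniform(0,1)
    draw is >= ``epc_threshold`` (threshold 0 keeps everything, 1 removes
    everything).  The score is the replicate-summed size of v's connected
    component (v counts itself), divided by the number of ranked nodes.
    The uniform stream is drawn as one (T, m) block in sorted-edge order,
    which fixes the sampling contract for reproducibility.
    """
    params = params or DEFAULT_PARAMS
    nodes, adj = _prepare(net)
    n = len(nodes)
    if n == 0:
        return CentralityTable.from_scores("EPC", {}, params)
    edges = [(u, v) for u in range(n) for v in adj[u] if u < v]
    m = len(edges)
    rng = np.random.default_rng(params.rng_seed)
    keep = rng.random((params.epc_iterations, m)) >= params.epc_threshold
    totals = np.zeros(n)
    eu = np.array([e[0] for e in edges], dtype=np.int64)
    ev = np.array([e[1] for e in edges], dtype=np.int64)
    for k in range(params.epc_iterations):
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in zip(eu[keep[k]], ev[keep[k]]):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[rb] = ra
        roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
        sizes = np.bincount(roots, minlength=n)
        totals += sizes[roots]
    return CentralityTable.from_scores(
        "EPC", {nodes[i]: float(totals[i] / n) for i in range(n)}, params
    )


def bottleneck(net: Network, params: MetricParams | None = None) -> CentralityTable:
    """BottleNeck: for each root s, grow the BFS shortest-path tree T_s
    (neighbors visited in lexicographic order, single parent at first
    discovery).  v != s is a bottleneck of T_s iff the number of tree nodes
    whose path from s passes through v (v itself included) strictly exceeds
    |V(T_s)| / 4.  The score counts the roots for which v is a bottleneck."""
    nodes, adj = _prepare(net)
    n = len(nodes)
    score = [0] * n
    for s in range(n):
        parent = [-1] * n
        parent[s] = s
        order = [s]
        for v in order:
            for w in adj[v]:
                if parent[w] < 0:
                    parent[w] = v
                    order.append(w)
        tree_size = len(order)
        sub = [1] * n
        for v in reversed(order[1:]):
            sub[parent[v]] += sub[v]
        quarter = tree_size / 4.0
        for v in order[1:]:
            if sub[v] > quarter:
                score[v] += 1
    return CentralityTable.from_scores(
        "BottleNeck", {nodes[i]: float(score[i]) for i in range(n)}, params
    )


# ---------------------------------------------------------------------------

METRICS: dict[str, Callable[[Network, MetricParams | None], CentralityTable]] = {
    "Betweenness": betweenness,
    "BottleNeck": bottleneck,
    "CC": clustering_coefficient,
    "Closeness": closeness,
    "Degree": degree_centrality,
    "DMNC": dmnc,
    "EcCentricity": eccentricity_centrality,
    "EPC": epc,
    "MCC": mcc,
    "MNC": mnc,
    "Radiality": radiality,
    "Stress": stress,
}


def compute_all(
    net: Network,
    params: MetricParams | None = None,
    metrics: Iterable[str] | None = None,
) -> dict[str, CentralityTable]:
    """Compute the requested measures (default: all twelve) over the
    degree >= 1 nodes of ``net``."""
    names = tuple(metrics) if metrics is not None else METRIC_NAMES
    unknown = [m for m in names if m not in METRICS]
    if unknown:
        raise ParameterError(f"unknown metric(s): {unknown}")
    return {name: METRICS[name](net, params) for name in names}


def wide_table(tables: Mapping[str, CentralityTable]) -> pd.DataFrame:
    """Genes x metrics score table (ranked genes only)."""
    frames = {
        name: pd.Series(t.scores, name=name) for name, t in tables.items()
    }
    return pd.DataFrame(frames).sort_index()
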