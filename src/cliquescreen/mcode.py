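"""MCODE vertex weighting: the node score used as a complex-formation proxy.

Only the vertex-weighting stage of the molecular-complex-detection algorithm
is implemented: score(v) = k(H) * density(H), where H is the highest k-core
of the subgraph induced by v's closed neighborhood N[v] and density is
|E(H)| / (|V(H)| (|V(H)|-1) / 2).  Complex expansion, haircut and fluff
stages are out of scope; the node score alone serves as the per-protein
measure of local interaction density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ExcludedNodeError, ValidationError
from .netcore import Network


@dataclass(frozen=True)
class MCODEParams:
    include_loops: bool = False  # loops are never constructed; recorded for parity
    degree_cutoff: int = 2


DEFAULT_MCODE_PARAMS = MCODEParams()


@dataclass(frozen=True)
class NodeScoreTable:
    scores: dict[str, float]
    params: MCODEParams = DEFAULT_MCODE_PARAMS

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.scores)
        return pd.DataFrame(
            {"gene": genes, "node_score": [self.scores[g] for g in genes]}
        )


def kcore(net: Network, subset: Iterable[str]) -> tuple[int, set[str]]:
    """Highest-k core of the subgraph induced by ``subset``.

    Iterative minimum-degree pruning: remove vertices of degree < k for
    increasing k; the last non-empty survivor set is the highest-k core.
    Empty subset -> (0, empty set).
    """
    subset = set(subset)
    if not subset <= net.nodes:
        raise ValidationError("subset contains genes outside the network")
    if not subset:
        return 0, set()
    adj = {v: net.neighbors(v) & subset for v in subset}
    best_k, best_members = 0, set(subset)
    alive = set(subset)
    k = 1
    while alive:
        # prune everything below degree k
        queue = [v for v in alive if len(adj[v]) < k]
        while queue:
            v = queue.pop()
            if v not in alive:
                continue
            alive.discard(v)
            for u in adj[v]:
                adj[u].discard(v)
                if u in alive and len(adj[u]) < k:
                    queue.append(u)
            adj[v] = set()
        if alive:
            best_k, best_members = k, set(alive)
        k += 1
    return best_k, best_members


def node_score(net: Network, v: str) -> float:
    """k * density of the highest k-core of v's closed neighborhood."""
    if net.degree(v) < 1:
        raise ExcludedNodeError(f"{v} has degree 0; node score undefined")
    closed = net.neighbors(v) | {v}
    k, members = kcore(net, closed)
    if k == 0 or len(members) < 2:
        return 0.0
    sub = net.subgraph(members)
    dens = sub.edge_count / (len(members) * (len(members) - 1) / 2.0)
    return k * dens


def score_all(net: Network, params: MCODEParams | None = None) -> NodeScoreTable:
    """Node scores for every degree >= 1 gene."""
    params = params or DEFAULT_MCODE_PARAMS
    return NodeScoreTable(
        {v: node_score(net, v) for v in net.ranked_nodes()}, params
    )
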