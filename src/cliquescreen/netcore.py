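"""Graph model and ingestion for disease-gene interaction networks.

A screening network is assembled in two steps: take the top-``N`` genes of a
disease-scored gene list (scores on the 0--5 confidence scale used by
disease--gene association databases), then keep every interaction between
selected genes whose combined confidence score clears a cutoff.  The
conventional cutoffs are 0.4 (medium), 0.7 (high) and 0.9 (highest
confidence), which produce nested edge sets on the same gene list.

Genes present in the interaction vocabulary that lose all their edges at the
chosen cutoff are retained as degree-0 nodes: they count toward network size
and toward the biomarker denominator, but are excluded from centrality
ranking, which only covers genes with degree >= 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .errors import (
    FormatError,
    ParameterError,
    RowError,
    UndefinedDensityError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENE_NAMES = ("gene", "gene_id", "symbol", "node")
_EDGE_ENDPOINT_NAMES = (("gene_a", "gene_b"), ("protein1", "protein2"), ("node1", "node2"))


def _detect_delimiter(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _find_column(columns, candidates) -> str | None:
    lowered = {c.lower().lstrip("#"): c for c in columns}
    for name in candidates:
        if name in lowered:
            return lowered[name]
    return None


def _find_score_column(columns, exclude=()) -> str | None:
    for c in columns:
        if c in exclude:
            continue
        if "score" in c.lower() or c.lower() == "confidence":
            return c
    return None


@dataclass(frozen=True)
class ScoredGeneTable:
    """Gene list with disease scores in [0, 5], in input order.

    Gene identifiers are unique; the table is retrievable in descending
    disease-score order with lexicographic gene-id tie-break.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        counts = Counter(g for g, _ in self.entries)
        dup = sorted(g for g, c in counts.items() if c > 1)
        if dup:
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        bad = [g for g, s in self.entries if not 0.0 <= s <= 5.0]
        if bad:
            raise ValidationError(f"disease scores outside [0, 5] for: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    def score_of(self, gene: str) -> float:
        for g, s in self.entries:
            if g == gene:
                return s
        raise KeyError(gene)

    def by_score(self) -> list[tuple[str, float]]:
        """Entries in descending score order, ties broken by gene id."""
        return sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def top(self, n: int) -> list[str]:
        """Top-``n`` genes by descending disease score.

        A score tie straddling the boundary is resolved lexicographically
        and logged, since the selection then depends on the tie rule.
        """
        if n <= 0:
            raise ParameterError(f"top_n must be positive, got {n}")
        if n > len(self.entries):
            raise ParameterError(
                f"top_n={n} exceeds table size {len(self.entries)}"
            )
        ordered = self.by_score()
        if n < len(ordered) and ordered[n - 1][1] == ordered[n][1]:
            logger.info(
                "disease-score tie at top-%d boundary (score %.4g); "
                "broken lexicographically",
                n,
                ordered[n - 1][1],
            )
        return [g for g, _ in ordered[:n]]

    def threshold(self, n: int) -> float:
        """Disease score of the ``n``-th ranked gene (the selection cutoff)."""
        return self.by_score()[n - 1][1]


@dataclass(frozen=True)
class EdgeTable:
    """Undirected weighted edge list; endpoints ordered, pairs unique."""

    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        seen = set()
        for a, b, c in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a > b:
                raise ValidationError(f"endpoints not ordered: ({a}, {b})")
            if (a, b) in seen:
                raise ValidationError(f"duplicate pair ({a}, {b})")
            seen.add((a, b))
            if not 0.0 <= c <= 1.0:
                raise ValidationError(f"confidence {c} outside [0, 1] on ({a}, {b})")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "EdgeTable":
        """Normalize raw records: drop self-loops, collapse duplicate
        unordered pairs keeping the maximum confidence."""
        best: dict[tuple[str, str], float] = {}
        loops = 0
        dups = 0
        for a, b, c in records:
            if a == b:
                loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in best:
                dups += 1
                best[key] = max(best[key], c)
            else:
                best[key] = c
        if loops:
            logger.info("dropped %d self-loop edge(s)", loops)
        if dups:
            logger.info("collapsed %d duplicate unordered pair(s) to max confidence", dups)
        return cls(tuple((a, b, best[(a, b)]) for a, b in sorted(best)))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(g for a, b, _ in self.edges for g in (a, b))

    def at_confidence(self, min_confidence: float) -> list[tuple[str, str, float]]:
        return [(a, b, c) for a, b, c in self.edges if c >= min_confidence]


@dataclass(frozen=True)
class BiomarkerSet:
    """Reference panel of validated biomarker genes."""

    gene_ids: frozenset[str]

    def __post_init__(self):
        if not self.gene_ids:
            raise ValidationError("biomarker set must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    def __iter__(self):
        return iter(sorted(self.gene_ids))

    def in_network(self, net: "Network") -> set[str]:
        return self.gene_ids & net.nodes


class Network:
    """Undirected simple graph of gene nodes with a symmetric adjacency map.

    Degree-0 nodes are legal members (empty neighbor set).
    """

    __slots__ = ("adjacency",)

    def __init__(self, adjacency: dict[str, set[str]]):
        for v, nbrs in adjacency.items():
            if v in nbrs:
                raise ValidationError(f"self-loop on {v}")
            for u in nbrs:
                if v not in adjacency.get(u, ()):  # symmetry
                    raise ValidationError(f"asymmetric adjacency: {v} -> {u}")
        self.adjacency = adjacency

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "Network":
        adj: dict[str, set[str]] = {v: set() for v in nodes}
        for a, b in edges:
            if a not in adj or b not in adj:
                raise ValidationError(f"edge endpoint not in node set: ({a}, {b})")
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            adj[a].add(b)
            adj[b].add(a)
        return cls(adj)

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency)

    @property
    def node_count(self) -> int:
        return len(self.adjacency)

    @property
    def edge_count(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency.values()) // 2

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def neighbors(self, v: str) -> set[str]:
        return self.adjacency[v]

    def edges(self) -> Iterator[tuple[str, str]]:
        for v, nbrs in self.adjacency.items():
            for u in nbrs:
                if v < u:
                    yield (v, u)

    def ranked_nodes(self) -> list[str]:
        """Nodes eligible for centrality ranking (degree >= 1), sorted."""
        return sorted(v for v, nbrs in self.adjacency.items() if nbrs)

    def isolated_nodes(self) -> list[str]:
        return sorted(v for v, nbrs in self.adjacency.items() if not nbrs)

    def subgraph(self, keep: Iterable[str]) -> "Network":
        keep = set(keep)
        return Network(
            {v: self.adjacency[v] & keep for v in keep if v in self.adjacency}
        )

    def components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps = []
        for start in sorted(self.adjacency):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for u in self.adjacency[v]:
                    if u not in comp:
                        comp.add(u)
                        stack.append(u)
            seen |= comp
            comps.append(comp)
        return comps


# ---------------------------------------------------------------------------
# ingestion


def read_scored_genes(path) -> ScoredGeneTable:
    """Read a delimited gene/disease-score table (delimiter auto-detected)."""
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    gene_col = _find_column(df.columns, _GENE_NAMES)
    score_col = _find_score_column(df.columns, exclude=(gene_col,))
    if gene_col is None or score_col is None:
        raise FormatError(
            f"need a gene column and a score column; found {list(df.columns)}"
        )
    if df.empty:
        return ScoredGeneTable(())
    scores = pd.to_numeric(df[score_col], errors="coerce")
    bad = [i + 2 for i in df.index[scores.isna()]]  # +2: header is line 1
    if bad:
        raise RowError("non-numeric disease score", bad)
    out = [i + 2 for i in df.index[(scores < 0) | (scores > 5)]]
    if out:
        raise RowError("disease score outside [0, 5]", out)
    return ScoredGeneTable(tuple(zip(df[gene_col], scores.astype(float))))


def read_edge_table(path) -> EdgeTable:
    """Read a delimited interaction table with a combined confidence score."""
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    pair = None
    for a, b in _EDGE_ENDPOINT_NAMES:
        ca = _find_column(df.columns, (a,))
        cb = _find_column(df.columns, (b,))
        if ca is not None and cb is not None:
            pair = (ca, cb)
            break
    score_col = _find_score_column(df.columns, exclude=pair or ())
    if pair is None or score_col is None:
        raise FormatError(
            f"need two gene columns and a score column; found {list(df.columns)}"
        )
    if df.empty:
        return EdgeTable(())
    conf = pd.to_numeric(df[score_col], errors="coerce")
    bad = [i + 2 for i in df.index[conf.isna()]]
    if bad:
        raise RowError("non-numeric confidence score", bad)
    out = [i + 2 for i in df.index[(conf < 0) | (conf > 1)]]
    if out:
        raise RowError("confidence score outside [0, 1]", out)
    return EdgeTable.from_records(
        zip(df[pair[0]], df[pair[1]], conf.astype(float))
    )


def read_biomarkers(path) -> BiomarkerSet:
    """Read a biomarker reference list, one gene id per line."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return BiomarkerSet(frozenset(genes))


# ---------------------------------------------------------------------------
# assembly and statistics


def build_network(
    genes: ScoredGeneTable,
    top_n: int,
    edges: EdgeTable,
    min_confidence: float,
) -> Network:
    """Assemble the disease network for one (top_n, confidence) grid cell.

    The node set is the top-``top_n`` genes by descending disease score,
    restricted to the edge table's vocabulary (exact identifier match; no
    alias resolution).  Genes whose every edge falls below the cutoff stay
    in the network as degree-0 nodes.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ParameterError(f"min_confidence must be in [0, 1], got {min_confidence}")
    selected = genes.top(top_n)
    vocab = edges.vocabulary
    nodes = [g for g in selected if g in vocab]
    unmapped = top_n - len(nodes)
    if unmapped:
        logger.info("%d of %d query genes absent from edge vocabulary", unmapped, top_n)
    node_set = set(nodes)
    kept = [
        (a, b)
        for a, b, c in edges.edges
        if c >= min_confidence and a in node_set and b in node_set
    ]
    return Network.from_edges(nodes, kept)


def density(net: Network) -> float:
    """Graph density 2m / n(n-1)."""
    n = net.node_count
    if n < 2:
        raise UndefinedDensityError(f"density undefined for n={n}")
    return 2.0 * net.edge_count / (n * (n - 1))


def connected_biomarkers(net: Network, biomarkers: BiomarkerSet) -> set[str]:
    """Biomarkers present in the network with degree >= 1."""
    return {g for g in biomarkers.in_network(net) if net.degree(g) >= 1}


def network_summary(net: Network, biomarkers: BiomarkerSet | None = None) -> dict:
    """One summary row per grid cell: node/edge counts, density, biomarkers.

    Both node totals are reported: including and excluding degree-0 genes,
    so either reading of network size is available downstream.
    """
    ranked = net.ranked_nodes()
    row = {
        "nodes_total": net.node_count,
        "nodes_connected": len(ranked),
        "edges": net.edge_count,
        "density": density(net) if net.node_count >= 2 else float("nan"),
    }
    if biomarkers is not None:
        row["biomarkers_total"] = len(biomarkers.in_network(net))
        row["biomarkers_connected"] = len(connected_biomarkers(net, biomarkers))
    return row


# ---------------------------------------------------------------------------
# on-disk network layout (used by the CLI)


def write_network(net: Network, out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    nodes = pd.DataFrame(
        {"gene": sorted(net.nodes), "degree": [net.degree(v) for v in sorted(net.nodes)]}
    )
    nodes.to_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t", index=False)
    edges = pd.DataFrame(sorted(net.edges()), columns=["gene_a", "gene_b"])
    edges.to_csv(os.path.join(out_dir, "edges.tsv"), sep="\t", index=False)


def read_network(in_dir) -> Network:
    import os

    nodes = pd.read_csv(os.path.join(in_dir, "nodes.tsv"), sep="\t")["gene"]
    edges = pd.read_csv(os.path.join(in_dir, "edges.tsv"), sep="\t")
    return Network.from_edges(
        nodes, list(zip(edges["gene_a"], edges["gene_b"]))
    )
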