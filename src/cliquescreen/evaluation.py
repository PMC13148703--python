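"""Headline evaluation statistics of the biomarker screen.

Covers the tie-aware top-q% biomarker inclusion rate over the
(query-size x confidence-cutoff) grid, the Spearman/Ward characterization of
metric ranking patterns on biomarkers, the per-species evolutionary
conservation score, and the high-vs-low rank-group comparisons of
conservation and complex-formation values.

Tie handling in the top set follows the convention used for low-resolution
metrics (EcCentricity being the canonical offender): every gene whose score
equals the score at the nominal top-q% boundary joins the set, and the
inclusion rate is rescaled by nominal_k / extended_size so that the expected
rate under random tie-breaking is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import centrality as _centrality
from . import netcore as _netcore
from .centrality import CentralityTable, MetricParams
from .errors import (
    ConsistencyError,
    CoverageError,
    InsufficientDataError,
    ParameterError,
    UndefinedRateError,
    ValidationError,
)
from .netcore import BiomarkerSet, EdgeTable, Network, ScoredGeneTable

logger = logging.getLogger(__name__)

#: Species panel for the conservation score (0.2 points per species).
SPECIES_PANEL = (
    "S.cerevisiae",
    "D.melanogaster",
    "C.elegans",
    "A.thaliana",
    "D.rerio",
)

#: Seed-ortholog gate: inparalog score 1.0 and seed score >= 0.95.
SEED_SCORE_MIN = 0.95
INPARALOG_REQUIRED = 1.0


# ---------------------------------------------------------------------------
# top sets and inclusion rates


@dataclass(frozen=True)
class TopSet:
    metric: str
    nominal_k: int
    members: frozenset[str]
    tie_extended: bool
    extended_size: int


def top_fraction(table: CentralityTable, q: float) -> TopSet:
    """Best floor(q * n) genes of a ranking, extended across boundary ties."""
    if not 0.0 < q < 1.0:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    if len(table) == 0:
        raise InsufficientDataError("empty centrality table")
    ordered = table.ordered_genes()
    nominal_k = math.floor(q * len(ordered))
    if nominal_k == 0:
        return TopSet(table.metric, 0, frozenset(), False, 0)
    boundary = table.scores[ordered[nominal_k - 1]]
    members = frozenset(g for g in ordered if table.scores[g] >= boundary)
    extended = len(members)
    return TopSet(table.metric, nominal_k, members, extended > nominal_k, extended)


@dataclass(frozen=True)
class InclusionResult:
    metric: str
    biomarkers_in_top: int
    biomarkers_in_network: int
    rate_percent: float          # tie-normalized, rounded to one decimal
    rate_percent_raw: float      # unnormalized, rounded to one decimal
    top_n: int | None = None
    confidence: float | None = None
    tie_extended: bool = False


def inclusion_rate(
    top: TopSet,
    biomarkers: BiomarkerSet,
    net: Network,
    top_n: int | None = None,
    confidence: float | None = None,
) -> InclusionResult:
    """Percentage of in-network biomarkers captured by the top set."""
    denom = len(biomarkers.in_network(net))
    if denom == 0:
        raise UndefinedRateError("no biomarkers present in the network")
    hits = len(top.members & biomarkers.gene_ids)
    raw = hits / denom * 100.0
    norm = raw
    if top.tie_extended and top.extended_size:
        norm = raw * top.nominal_k / top.extended_size
    return InclusionResult(
        metric=top.metric,
        biomarkers_in_top=hits,
        biomarkers_in_network=denom,
        rate_percent=round(norm, 1),
        rate_percent_raw=round(raw, 1),
        top_n=top_n,
        confidence=confidence,
        tie_extended=top.tie_extended,
    )


def marginal_average(rates: Sequence[float]) -> float:
    """Average of already-rounded per-cell rates, rounded to one decimal."""
    return round(float(np.mean(rates)), 1)


@dataclass
class GridResult:
    results: list[InclusionResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def average_over_top_ns(self) -> pd.DataFrame:
        """Per (metric, confidence) average across query sizes."""
        df = self.to_frame()
        return (
            df.groupby(["metric", "confidence"])
            .agg(
                rate_percent=("rate_percent", marginal_average),
                rate_sd=("rate_percent", lambda s: round(float(np.std(s)), 1)),
            )
            .reset_index()
        )

    def average_over_confidences(self) -> pd.DataFrame:
        """Per (metric, top_n) average across confidence cutoffs."""
        df = self.to_frame()
        return (
            df.groupby(["metric", "top_n"])
            .agg(
                rate_percent=("rate_percent", marginal_average),
                rate_sd=("rate_percent", lambda s: round(float(np.std(s)), 1)),
            )
            .reset_index()
        )


def grid_evaluate(
    genes: ScoredGeneTable,
    edges: EdgeTable,
    biomarkers: BiomarkerSet,
    top_ns: Sequence[int],
    confidences: Sequence[float],
    metrics: Sequence[str] | None = None,
    q: float = 0.05,
    params: MetricParams | None = None,
) -> GridResult:
    """One inclusion result per (top_n x confidence x metric) grid cell."""
    results: list[InclusionResult] = []
    for top_n in top_ns:
        for conf in confidences:
            net = _netcore.build_network(genes, top_n, edges, conf)
            tables = _centrality.compute_all(net, params, metrics)
            for name, table in tables.items():
                top = top_fraction(table, q)
                results.append(
                    inclusion_rate(top, biomarkers, net, top_n=top_n, confidence=conf)
                )
    return GridResult(results)


# ---------------------------------------------------------------------------
# rank-pattern characterization


def biomarker_rank_matrix(
    tables: Mapping[str, CentralityTable] | Sequence[CentralityTable],
    biomarkers: BiomarkerSet,
) -> pd.DataFrame:
    """(biomarker x metric) matrix of full-network competition ranks.

    Biomarkers are ranked within the complete gene ranking of each metric,
    not re-ranked within the biomarker subset.  Degree-0 biomarkers (absent
    from every table) are dropped with a log message; a biomarker present
    in some tables but not others is a consistency error.
    """
    if not isinstance(tables, Mapping):
        tables = {t.metric: t for t in tables}
    if not tables:
        raise InsufficientDataError("no centrality tables given")
    ranked_sets = {name: set(t.ranks) for name, t in tables.items()}
    universe = set.union(*ranked_sets.values())
    for name, genes in ranked_sets.items():
        if genes != universe:
            missing = sorted(universe - genes)
            raise ConsistencyError(
                f"metric {name} is missing ranked genes: {missing[:5]}"
            )
    present = sorted(biomarkers.gene_ids & universe)
    dropped = sorted(biomarkers.gene_ids - universe)
    if dropped:
        logger.info("dropping %d degree-0/absent biomarker(s): %s", len(dropped), dropped)
    matrix = {
        name: [t.ranks[g] for g in present] for name, t in tables.items()
    }
    return pd.DataFrame(matrix, index=present)


def spearman_matrix(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rho (average-rank tie correction, unit diagonal)."""
    if rank_matrix.shape[0] < 3:
        raise InsufficientDataError("need at least 3 biomarkers for correlations")
    cols = list(rank_matrix.columns)
    k = len(cols)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = sps.spearmanr(rank_matrix.iloc[:, i], rank_matrix.iloc[:, j]).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=cols, columns=cols)


def ward_clusters(rho: pd.DataFrame, threshold: float = 0.8) -> list[set[str]]:
    """Ward agglomeration on d = 1 - rho, cut at height 1 - threshold.

    Classic Ward linkage on the correlation-derived distances; clusters are
    returned in order of first appearance of their members, so the result is
    deterministic for a fixed metric input order.
    """
    values = rho.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-8):
        raise ValidationError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh((values + values.T) / 2).min() < -1e-8:
        raise ValidationError("correlation matrix is not positive semidefinite")
    d = 1.0 - values
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    clusters: dict[int, set[str]] = {}
    order: list[int] = []
    for metric, lab in zip(rho.columns, labels):
        if lab not in clusters:
            clusters[lab] = set()
            order.append(lab)
        clusters[lab].add(metric)
    return [clusters[lab] for lab in order]


# ---------------------------------------------------------------------------
# conservation scoring


def conservation_scores(
    orthologs: pd.DataFrame, genes: Iterable[str]
) -> pd.DataFrame:
    """0.2 points per panel species with a qualifying seed-ortholog pair.

    A qualifying record has inparalog score 1.0 and seed score >= 0.95; the
    score therefore lives on {0, 0.2, ..., 1.0} over the five-species panel.
    ``orthologs`` needs columns gene, species, inparalog_score, seed_score.
    """
    required = {"gene", "species", "inparalog_score", "seed_score"}
    if not required <= set(orthologs.columns):
        raise ValidationError(
            f"ortholog table needs columns {sorted(required)}"
        )
    unknown = set(orthologs["species"]) - set(SPECIES_PANEL)
    if unknown:
        raise ValidationError(f"unknown species label(s): {sorted(unknown)}")
    genes = sorted(set(genes))
    qual = orthologs[
        (orthologs["inparalog_score"] >= INPARALOG_REQUIRED - 1e-12)
        & (orthologs["seed_score"] >= SEED_SCORE_MIN)
    ]
    table = pd.DataFrame(0, index=genes, columns=list(SPECIES_PANEL), dtype=int)
    hits = (
        qual[qual["gene"].isin(genes)]
        .groupby(["gene", "species"], observed=True)
        .size()
        .clip(upper=1)
    )
    for (g, sp), flag in hits.items():
        table.loc[g, sp] = int(flag)
    table["score"] = (0.2 * table[list(SPECIES_PANEL)].sum(axis=1)).round(1)
    table.index.name = "gene"
    return table


# ---------------------------------------------------------------------------
# high/low rank-group comparison


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    high_genes: tuple[str, ...]
    low_genes: tuple[str, ...]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum.

    Exact null distribution when the combined sample is small (n <= 20) and
    tie-free; tie-corrected normal approximation otherwise.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x) + len(y)
    has_ties = len(set(x + y)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def high_low_compare(
    values: Mapping[str, float],
    ranking: CentralityTable,
    biomarkers: BiomarkerSet,
) -> GroupComparison:
    """Split biomarkers into equal high/low halves by metric rank and compare
    ``values`` between halves with a two-sided Wilcoxon rank-sum test."""
    missing_rank = [g for g in biomarkers if g not in ranking.ranks]
    if missing_rank:
        raise CoverageError("biomarkers missing from the ranking", missing_rank)
    missing_val = [g for g in biomarkers if g not in values]
    if missing_val:
        raise CoverageError("biomarkers missing a value", missing_val)
    ordered = sorted(biomarkers, key=lambda g: (ranking.ranks[g], g))
    n = len(ordered)
    n_high = (n + 1) // 2
    high, low = ordered[:n_high], ordered[n_high:]
    if len(high) < 2 or len(low) < 2:
        raise InsufficientDataError("need at least 2 biomarkers per group")
    if n % 2 == 0 and ranking.ranks[high[-1]] == ranking.ranks[low[0]]:
        logger.info(
            "rank tie at the median split boundary; broken by gene id "
            "(%s | %s)", high[-1], low[0],
        )
    stat, p = rank_sum_test([values[g] for g in high], [values[g] for g in low])
    return GroupComparison(
        metric=ranking.metric,
        statistic=stat,
        p_value=p,
        group_sizes=(len(high), len(low)),
        high_genes=tuple(high),
        low_genes=tuple(low),
    )


# ---------------------------------------------------------------------------
# optional plotting (thin convenience; styling is not the point)


def plot_inclusion_bars(grid: GridResult, path, margin: str = "confidence") -> None:
    """Bar chart of marginal inclusion-rate averages per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = (
        grid.average_over_top_ns()
        if margin == "confidence"
        else grid.average_over_confidences()
    )
    key = "confidence" if margin == "confidence" else "top_n"
    fig, ax = plt.subplots(figsize=(10, 4))
    pivot = df.pivot(index="metric", columns=key, values="rate_percent")
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("biomarkers in top 5% (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
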