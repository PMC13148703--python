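"""Novel-candidate funnel: survival and expression filters plus connectivity.

The non-biomarker genes of the top-MCC set are filtered on four p-values:
median-split log-rank tests against relapse-free and overall survival, and
Dunn post-hoc contrasts (after a Kruskal--Wallis omnibus) for normal-vs-tumor
and tumor-vs-metastatic expression.  A candidate passes when all four are
below 0.05.  Surviving candidates are profiled by how many genes of the
biomarker reference panel they touch directly in the confidence-filtered
edge table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .errors import (
    CoverageError,
    DegenerateSplitError,
    ValidationError,
)
from .evaluation import TopSet
from .netcore import BiomarkerSet, EdgeTable

logger = logging.getLogger(__name__)

EXPRESSION_GROUPS = ("normal", "tumor", "metastatic")
ALPHA = 0.05

FLAG_COLUMNS = ("rfs_p", "os_p", "normal_tumor_p", "tumor_metastatic_p")


def _validate_survival(rec: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "expression"}
    if not required <= set(rec.columns):
        raise ValidationError(f"survival table needs columns {sorted(required)}")
    if (rec["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not rec["event"].isin((0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    return rec


def median_split_logrank(rec: pd.DataFrame) -> float:
    """Two-sided log-rank p between above-median and <=-median expression.

    Patients exactly at the median go to the low group.  Tied event times
    are handled by the standard hypergeometric variance of the log-rank
    statistic (1 df chi-square).
    """
    rec = _validate_survival(rec)
    med = float(rec["expression"].median())
    low = rec["expression"] <= med
    n_low, n_high = int(low.sum()), int((~low).sum())
    if min(n_low, n_high) < 2:
        raise DegenerateSplitError(
            f"median split produced groups of size ({n_low}, {n_high})"
        )
    res = _lifelines_logrank(
        rec.loc[low, "time"],
        rec.loc[~low, "time"],
        event_observed_A=rec.loc[low, "event"],
        event_observed_B=rec.loc[~low, "event"],
    )
    return float(res.p_value)


@dataclass(frozen=True)
class KWDunnResult:
    kw_statistic: float
    kw_p: float
    dunn_z_normal_tumor: float
    dunn_p_normal_tumor: float
    dunn_z_tumor_metastatic: float
    dunn_p_tumor_metastatic: float


def _dunn_pair(
    ranks: np.ndarray,
    groups: np.ndarray,
    a: str,
    b: str,
    tie_term: float,
    n_total: int,
) -> tuple[float, float]:
    ra = ranks[groups == a]
    rb = ranks[groups == b]
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
    z = (ra.mean() - rb.mean()) / math.sqrt(var)
    return z, 2.0 * sps.norm.sf(abs(z))


def kw_dunn(
    groups: Mapping[str, Sequence[float]], bonferroni: bool = False
) -> KWDunnResult:
    """Kruskal--Wallis omnibus plus Dunn z-tests on joint ranks for the
    normal-vs-tumor and tumor-vs-metastatic contrasts.

    Dunn p-values are reported unadjusted by default (the screening rule is
    a raw p < 0.05 per contrast); ``bonferroni=True`` multiplies by the
    number of pairwise comparisons among the three groups.
    """
    missing = [g for g in EXPRESSION_GROUPS if g not in groups or len(groups[g]) == 0]
    if missing:
        raise ValidationError(f"empty or missing expression group(s): {missing}")
    samples = {g: np.asarray(groups[g], dtype=float) for g in EXPRESSION_GROUPS}
    kw = sps.kruskal(*(samples[g] for g in EXPRESSION_GROUPS))
    pooled = np.concatenate([samples[g] for g in EXPRESSION_GROUPS])
    labels = np.concatenate(
        [np.repeat(g, len(samples[g])) for g in EXPRESSION_GROUPS]
    )
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    z_nt, p_nt = _dunn_pair(ranks, labels, "normal", "tumor", tie_term, n)
    z_tm, p_tm = _dunn_pair(ranks, labels, "tumor", "metastatic", tie_term, n)
    if bonferroni:
        p_nt = min(1.0, 3.0 * p_nt)
        p_tm = min(1.0, 3.0 * p_tm)
    return KWDunnResult(
        kw_statistic=float(kw.statistic),
        kw_p=float(kw.pvalue),
        dunn_z_normal_tumor=float(z_nt),
        dunn_p_normal_tumor=float(p_nt),
        dunn_z_tumor_metastatic=float(z_tm),
        dunn_p_tumor_metastatic=float(p_tm),
    )


# ---------------------------------------------------------------------------
# flags and screening


def compute_flags(
    survival: Mapping[str, Mapping[str, pd.DataFrame]],
    expression: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Four p-values and the pass flag per gene, computed from raw tables.

    ``survival[gene]`` maps endpoint ("RFS"/"OS") to a (time, event,
    expression) table; ``expression[gene]`` maps group label to values.
    """
    rows = {}
    for gene in sorted(survival):
        kd = kw_dunn(expression[gene])
        rows[gene] = {
            "rfs_p": median_split_logrank(survival[gene]["RFS"]),
            "os_p": median_split_logrank(survival[gene]["OS"]),
            "normal_tumor_p": kd.dunn_p_normal_tumor,
            "tumor_metastatic_p": kd.dunn_p_tumor_metastatic,
        }
    flags = pd.DataFrame.from_dict(rows, orient="index")
    flags.index.name = "gene"
    flags["pass"] = (flags[list(FLAG_COLUMNS)] < alpha).all(axis=1)
    return flags


def read_flags(path) -> pd.DataFrame:
    """Read a precomputed per-gene flags table (gene + four p columns)."""
    flags = pd.read_csv(path, sep=None, engine="python").set_index("gene")
    missing = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise ValidationError(f"flags table missing columns {missing}")
    flags["pass"] = (flags[list(FLAG_COLUMNS)] < ALPHA).all(axis=1)
    return flags


def screen_candidates(
    top: TopSet,
    biomarkers: BiomarkerSet,
    flags: pd.DataFrame,
    ranks: Mapping[str, int] | None = None,
    alpha: float = ALPHA,
) -> list[str]:
    """Non-biomarker top-set genes whose four p-values are all < alpha.

    Returned in ascending metric-rank order (gene id breaking ties) when
    ``ranks`` is given, else lexicographically.
    """
    pool = sorted(top.members - biomarkers.gene_ids)
    missing = [g for g in pool if g not in flags.index]
    if missing:
        raise CoverageError("flags missing for screened gene(s)", missing)
    passed = [
        g
        for g in pool
        if all(flags.loc[g, c] < alpha for c in FLAG_COLUMNS)
    ]
    if ranks is not None:
        passed.sort(key=lambda g: (ranks[g], g))
    return passed


@dataclass(frozen=True)
class ConnectivityProfile:
    gene: str
    linked_biomarkers: int
    percent_of_reference: float


def biomarker_connectivity(
    candidates: Sequence[str],
    reference: BiomarkerSet,
    edges: EdgeTable,
    min_confidence: float,
) -> list[ConnectivityProfile]:
    """Direct reference-panel interactions per candidate at a confidence
    cutoff, as a count and a percentage of the full panel."""
    adj: dict[str, set[str]] = {}
    for a, b, c in edges.at_confidence(min_confidence):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    profiles = []
    for gene in candidates:
        if gene not in adj:
            logger.info("candidate %s absent from edge vocabulary at cutoff", gene)
        linked = len(adj.get(gene, set()) & reference.gene_ids - {gene})
        profiles.append(
            ConnectivityProfile(
                gene=gene,
                linked_biomarkers=linked,
                percent_of_reference=round(linked / len(reference) * 100.0, 1),
            )
        )
    return profiles


def candidate_report(
    candidates: Sequence[str],
    flags: pd.DataFrame,
    profiles: Sequence[ConnectivityProfile],
    ranks: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Combined report: rank, four p-values, pass flag, connectivity."""
    by_gene = {p.gene: p for p in profiles}
    rows = []
    for g in candidates:
        row = {"gene": g}
        if ranks is not None:
            row["rank"] = ranks[g]
        row.update({c: flags.loc[g, c] for c in FLAG_COLUMNS})
        row["pass"] = bool(flags.loc[g, "pass"]) if "pass" in flags.columns else True
        if g in by_gene:
            row["linked_biomarkers"] = by_gene[g].linked_biomarkers
            row["percent_of_reference"] = by_gene[g].percent_of_reference
        rows.append(row)
    return pd.DataFrame(rows)
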