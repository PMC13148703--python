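"""Seeded generators for every input class the pipeline consumes.

The generators emulate the statistical structure the analysis assumes rather
than any particular database's marginals:

* a scored gene list whose top ranks are enriched for biomarkers;
* an interaction table with planted vertex-disjoint cliques on a sparse
  Erdos--Renyi background, clique edges drawn with higher confidence so the
  cliques persist at the highest cutoff while the background thins out;
* a biomarker panel preferentially embedded in the planted cliques;
* an ortholog table in which clique members qualify as seed orthologs with
  elevated probability (conservation--clique coupling);
* per-gene survival tables whose hazard doubles-or-more above median
  expression for hazard-linked genes, and three-group expression tables with
  mean shifts for designated true candidates.

All randomness flows from a single integer seed per generator call, so every
output is bit-reproducible.  A ground-truth manifest is produced alongside
each dataset for recovery testing.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evaluation import SPECIES_PANEL
from .netcore import BiomarkerSet, EdgeTable, ScoredGeneTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults are desk-scale: 500 genes, three planted 8-cliques (24 clique
    positions), a 20-gene biomarker panel of which 75% sit inside cliques,
    and a G(n, 0.01) background.  Clique edges draw confidence from
    U(0.7, 1.0) and background edges from U(0.4, 0.9), so the 0.4/0.7/0.9
    cutoffs give nested networks in which cliques survive the highest cutoff
    while the background does not.
    """

    n_genes: int = 500
    n_biomarkers: int = 20
    n_cliques: int = 3
    clique_size: int = 8
    biomarker_clique_fraction: float = 0.75
    background_edge_prob: float = 0.01
    clique_confidence: tuple[float, float] = (0.7, 1.0)
    background_confidence: tuple[float, float] = (0.4, 0.9)
    conservation_base: float = 0.3
    conservation_boost: float = 0.4
    hazard_ratio: float = 2.5
    baseline_hazard: float = 0.02
    censor_horizon: float = 120.0
    n_patients: int = 200
    group_shifts: tuple[float, float, float] = (0.0, 1.0, 2.0)
    n_per_group: int = 50
    n_candidates: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.clique_size < 3:
            raise ValidationError("clique_size must be >= 3")
        if self.n_cliques * self.clique_size > self.n_genes:
            raise ValidationError("planted cliques exceed the gene universe")
        for p in (
            self.biomarker_clique_fraction,
            self.background_edge_prob,
            self.conservation_base,
            self.conservation_boost,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.clique_confidence, self.background_confidence):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValidationError("confidence ranges must be within [0, 1]")
        if self.n_biomarkers > self.n_genes:
            raise ValidationError("more biomarkers than genes")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazard parameters must be positive")


@dataclass(frozen=True)
class GeneTruth:
    gene: str
    is_biomarker: bool
    clique_id: int  # -1 for background
    is_candidate: bool
    conservation_p: float
    hazard_linked: bool


@dataclass(frozen=True)
class GroundTruth:
    genes: tuple[GeneTruth, ...]

    def __getitem__(self, gene: str) -> GeneTruth:
        return self._index()[gene]

    def _index(self) -> dict[str, GeneTruth]:
        return {t.gene: t for t in self.genes}

    def biomarkers(self) -> list[str]:
        return sorted(t.gene for t in self.genes if t.is_biomarker)

    def clique_members(self) -> list[str]:
        return sorted(t.gene for t in self.genes if t.clique_id >= 0)

    def candidates(self) -> list[str]:
        return sorted(t.gene for t in self.genes if t.is_candidate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.genes]).set_index("gene")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_network(
    spec: SyntheticSpec,
) -> tuple[ScoredGeneTable, EdgeTable, BiomarkerSet, GroundTruth]:
    """Plant disjoint cliques on a sparse background and emit all four
    network-side inputs, fully determined by ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    genes = np.array(_gene_ids(n))

    # vertex-disjoint cliques
    n_slots = spec.n_cliques * spec.clique_size
    clique_idx = rng.choice(n, size=n_slots, replace=False)
    clique_of = np.full(n, -1, dtype=int)
    for c in range(spec.n_cliques):
        clique_of[clique_idx[c * spec.clique_size : (c + 1) * spec.clique_size]] = c

    # biomarker placement: a fixed share inside cliques, remainder outside
    n_in = min(round(spec.n_biomarkers * spec.biomarker_clique_fraction), n_slots)
    n_out = spec.n_biomarkers - n_in
    is_biomarker = np.zeros(n, dtype=bool)
    inside = rng.choice(clique_idx, size=n_in, replace=False)
    is_biomarker[inside] = True
    background_idx = np.flatnonzero(clique_of < 0)
    if n_out > len(background_idx):
        raise ValidationError("not enough background genes for biomarker placement")
    outside = rng.choice(background_idx, size=n_out, replace=False)
    is_biomarker[outside] = True

    # full-effect candidates: clique members that are not biomarkers
    free = np.flatnonzero((clique_of >= 0) & ~is_biomarker)
    if spec.n_candidates > len(free):
        raise ValidationError("not enough non-biomarker clique slots for candidates")
    cand_idx = rng.choice(free, size=spec.n_candidates, replace=False)
    is_candidate = np.zeros(n, dtype=bool)
    is_candidate[cand_idx] = True

    # disease scores: clique members concentrate in the top ranks
    score = rng.uniform(0.5, 4.0, size=n)
    score[clique_of >= 0] = rng.uniform(3.0, 5.0, size=n_slots)
    score[is_biomarker & (clique_of < 0)] = rng.uniform(2.5, 4.5, size=n_out)

    # edges: all clique pairs, plus Bernoulli background pairs
    records: list[tuple[str, str, float]] = []
    lo, hi = spec.clique_confidence
    for c in range(spec.n_cliques):
        members = np.sort(clique_idx[c * spec.clique_size : (c + 1) * spec.clique_size])
        for i_pos, i in enumerate(members):
            for j in members[i_pos + 1 :]:
                records.append((genes[i], genes[j], float(rng.uniform(lo, hi))))
    iu, ju = np.triu_indices(n, k=1)
    same_clique = (clique_of[iu] >= 0) & (clique_of[iu] == clique_of[ju])
    draw = rng.random(len(iu)) < spec.background_edge_prob
    blo, bhi = spec.background_confidence
    for i, j in zip(iu[draw & ~same_clique], ju[draw & ~same_clique]):
        records.append((genes[i], genes[j], float(rng.uniform(blo, bhi))))

    truth = GroundTruth(
        tuple(
            GeneTruth(
                gene=genes[i],
                is_biomarker=bool(is_biomarker[i]),
                clique_id=int(clique_of[i]),
                is_candidate=bool(is_candidate[i]),
                conservation_p=min(
                    1.0,
                    spec.conservation_base
                    + (spec.conservation_boost if clique_of[i] >= 0 else 0.0),
                ),
                hazard_linked=bool(is_candidate[i]),
            )
            for i in range(n)
        )
    )
    table = ScoredGeneTable(
        tuple(
            sorted(zip(genes, score.astype(float)), key=lambda e: (-e[1], e[0]))
        )
    )
    return (
        table,
        EdgeTable.from_records(records),
        BiomarkerSet(frozenset(genes[is_biomarker])),
        truth,
    )


def generate_orthologs(truth: GroundTruth, spec: SyntheticSpec) -> pd.DataFrame:
    """Ortholog records per gene x species.

    A qualifying seed pair (inparalog 1.0, seed score in [0.95, 1.0]) is
    emitted with probability base + boost for clique members.  Half of the
    failures still emit a near-miss record straddling the 0.95 gate (either
    a sub-threshold seed score or a sub-unit inparalog score), so the gate
    itself is exercised by downstream scoring.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    rows = []
    for t in truth.genes:
        for sp in SPECIES_PANEL:
            if rng.random() < t.conservation_p:
                rows.append((t.gene, sp, 1.0, float(rng.uniform(0.95, 1.0))))
            elif rng.random() < 0.5:
                if rng.random() < 0.5:
                    rows.append((t.gene, sp, 1.0, float(rng.uniform(0.5, 0.9499))))
                else:
                    rows.append(
                        (t.gene, sp, float(rng.uniform(0.3, 0.99)), float(rng.uniform(0.95, 1.0)))
                    )
    return pd.DataFrame(
        rows, columns=["gene", "species", "inparalog_score", "seed_score"]
    )


def _survival_table(
    rng: np.random.Generator, spec: SyntheticSpec, linked: bool
) -> pd.DataFrame:
    x = rng.normal(0.0, 1.0, size=spec.n_patients)
    hr = spec.hazard_ratio if linked else 1.0
    lam = np.where(x > np.median(x), spec.baseline_hazard * hr, spec.baseline_hazard)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0.0, spec.censor_horizon, size=spec.n_patients)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event, "expression": x})


def generate_survival_expression(
    truth: GroundTruth,
    spec: SyntheticSpec,
    genes: Iterable[str] | None = None,
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, dict[str, np.ndarray]]]:
    """Survival tables (RFS and OS endpoints) and three-group expression
    samples for the requested genes (default: all)."""
    rng = np.random.default_rng(spec.rng_seed + 2)
    index = truth._index()
    selected = sorted(genes) if genes is not None else sorted(index)
    survival: dict[str, dict[str, pd.DataFrame]] = {}
    expression: dict[str, dict[str, np.ndarray]] = {}
    for gene in selected:
        t = index[gene]
        survival[gene] = {
            "RFS": _survival_table(rng, spec, t.hazard_linked),
            "OS": _survival_table(rng, spec, t.hazard_linked),
        }
        shifts = spec.group_shifts if t.is_candidate else (0.0, 0.0, 0.0)
        expression[gene] = {
            label: rng.normal(shift, 1.0, size=spec.n_per_group)
            for label, shift in zip(("normal", "tumor", "metastatic"), shifts)
        }
    return survival, expression


# ---------------------------------------------------------------------------
# on-disk fixture


def write_inputs(
    out_dir,
    table: ScoredGeneTable,
    edges: EdgeTable,
    biomarkers: BiomarkerSet,
    truth: GroundTruth,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(table.entries, columns=["gene", "disease_score"]).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False
    )
    pd.DataFrame(edges.edges, columns=["gene_a", "gene_b", "combined_score"]).to_csv(
        os.path.join(out_dir, "edges.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "biomarkers.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(sorted(biomarkers.gene_ids)) + "\n")
    truth.to_frame().to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")


def end_to_end_fixture(spec: SyntheticSpec, out_dir) -> dict:
    """Write the full input bundle plus an expected-recovery manifest.

    Survival/expression tables are generated for the non-biomarker genes of
    the top-5% maximal-clique-centrality set of the assembled medium-
    confidence network, i.e. exactly the genes the screening stage reads.
    """
    from . import centrality as _centrality
    from . import evaluation as _evaluation
    from . import netcore as _netcore

    table, edges, biomarkers, truth = generate_network(spec)
    write_inputs(out_dir, table, edges, biomarkers, truth)
    orthologs = generate_orthologs(truth, spec)
    orthologs.to_csv(os.path.join(out_dir, "orthologs.tsv"), sep="\t", index=False)

    net = _netcore.build_network(table, len(table), edges, 0.4)
    mcc_table = _centrality.mcc(net)
    top = _evaluation.top_fraction(mcc_table, 0.05)
    screened = sorted(top.members - biomarkers.gene_ids)
    survival, expression = generate_survival_expression(truth, spec, screened)
    surv_dir = os.path.join(out_dir, "survival")
    expr_dir = os.path.join(out_dir, "expression")
    os.makedirs(surv_dir, exist_ok=True)
    os.makedirs(expr_dir, exist_ok=True)
    for gene in screened:
        for endpoint, df in survival[gene].items():
            df.to_csv(
                os.path.join(surv_dir, f"{gene}_{endpoint.lower()}.csv"), index=False
            )
        rows = [
            {"value": v, "group": label}
            for label, values in expression[gene].items()
            for v in values
        ]
        pd.DataFrame(rows).to_csv(os.path.join(expr_dir, f"{gene}.csv"), index=False)

    manifest = {
        "seed": spec.rng_seed,
        "biomarkers": truth.biomarkers(),
        "clique_members": truth.clique_members(),
        "planted_candidates": truth.candidates(),
        "top_set": sorted(top.members),
        "screened": screened,
        "expected_to_pass": sorted(set(truth.candidates()) & set(screened)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
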