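# Methods

## Problem and model

`cliquescreen` implements a network-topology screen for disease biomarkers.
The premise: genes validated as clinical biomarkers of a disease tend to
occupy distinctive positions in the disease-specific protein–protein
interaction (PPI) network, and the position that best separates them from
other disease-associated genes is membership in large, dense cliques.  The
pipeline therefore (i) assembles PPI networks from a disease-scored gene
list at a grid of query sizes and interaction-confidence cutoffs, (ii) ranks
every connected gene by twelve hub-centrality measures, (iii) measures how
strongly each measure concentrates a reference biomarker panel in its top
5%, and (iv) funnels the non-biomarker members of the best-performing top
set (maximal clique centrality, MCC) through survival and differential-
expression significance filters to nominate novel candidates.

### Network assembly

Inputs are a scored gene table (disease score in [0, 5]), an undirected edge
table with combined confidence in [0, 1], and a biomarker reference list.
For a grid cell (N, c) the node set is the top-N genes by descending disease
score restricted to the edge vocabulary (exact identifier match, no alias
resolution), and the edge set is every interaction with confidence ≥ c
between selected genes.  The conventional cutoffs 0.4 / 0.7 / 0.9 give
nested edge sets.  Genes that lose every edge at a cutoff remain in the
network as degree-0 nodes — they count toward network size and toward the
biomarker denominator but are excluded from every ranking.  Disease-score
ties at the top-N boundary are broken lexicographically and logged.
Duplicate unordered edges keep the maximum confidence (conservative and
idempotent).  Density is 2m / n(n−1).

### Centrality measures

All twelve measures are computed from scratch over unweighted hop distances;
unreachable pairs contribute 0 to reciprocal sums, and component-local
quantities (radiality, eccentricity) are restricted to the node's component.

* **Degree** |N(v)|; **CC** 2e_v / k_v(k_v−1).
* **MNC** size of the largest connected component of the open-neighborhood
  subgraph; **DMNC** that component's edge count divided by its vertex count
  to the power ε = 1.7.  When several components tie in size, the one
  maximizing (size, edge count, lexicographically smallest member) is used —
  the convention is not fixed by precedent, so it is pinned here for
  determinism.
* **MCC** Σ_{C ∋ v} (|C|−1)! over *maximal* cliques, enumerated by pivoting
  Bron–Kerbosch; factorials are exact integers.  A node with an edgeless
  neighborhood degenerates to its degree.
* **Betweenness** raw Σ σ_st(v)/σ_st over unordered pairs (Brandes
  accumulation); **Stress** the analogous raw count of shortest paths
  through v.
* **Closeness** harmonic form Σ 1/d(v,w), chosen so disconnected networks
  are scored without arbitrary component restriction; the classic
  component-restricted form (n_C−1)/Σd is available via
  `MetricParams(closeness_variant="classic")` for sensitivity checks.
* **Radiality** Σ_{w∈C} (Δ_C + 1 − d(v,w)) / (n_C − 1) with component
  diameter Δ_C; **EcCentricity** 1 / max_w d(v,w).
* **EPC** Monte Carlo edge percolation: each replicate keeps an edge iff its
  uniform draw ≥ threshold (default 0.5, T = 1000 replicates, seeded); the
  score is the replicate-summed size of v's component divided by the number
  of ranked nodes.  The uniform stream is drawn as one (T, m) block in
  sorted-edge order, which fixes the sampling contract and makes the score
  bit-reproducible per seed.
* **BottleNeck** for each root, a deterministic BFS shortest-path tree
  (lexicographic neighbor order, first-discovery parent); v is a bottleneck
  of a tree when its subtree (v included) holds strictly more than a quarter
  of the tree's nodes; the root itself is never a candidate in its own tree.

Ranks are competition ("1224") ranks: tied scores share the best rank.

### Enrichment evaluation

The top-q% set (q = 0.05) takes the best floor(q·n) genes and is extended
across boundary score ties; the inclusion rate
|top ∩ biomarkers| / |biomarkers in network| × 100 is then rescaled by
nominal/extended size when extension occurred, which preserves the expected
rate under random tie-breaking.  Per-cell rates are rounded to one decimal
and marginal averages are taken over the rounded values.  Ranking patterns
are compared on the (biomarker × metric) matrix of full-network ranks with
tie-corrected Spearman ρ, followed by classic Ward linkage on d = 1 − ρ cut
at height 1 − 0.8 (so metrics correlated above ρ = 0.8 share a cluster).

### Conservation, complex formation and group tests

The conservation score awards 0.2 per panel species (five eukaryotes:
*S. cerevisiae*, *D. melanogaster*, *C. elegans*, *A. thaliana*,
*D. rerio*) that holds at least one qualifying seed-ortholog record
(inparalog score 1.0, seed score ≥ 0.95), giving values on
{0, 0.2, …, 1.0}.  The MCODE node score — k × density of the highest k-core
of the closed neighborhood N[v] — serves as the complex-formation proxy;
only the vertex-weighting stage of MCODE is implemented because the
downstream analysis uses nothing else.  High-vs-low comparisons split the
biomarkers at the median metric rank into equal halves (gene-id tie-break,
logged; the larger half is the high group for odd counts) and apply a
two-sided Wilcoxon rank-sum test: exact when the pooled sample is ≤ 20 and
tie-free, tie-corrected normal approximation otherwise.

### Candidate screen

Non-biomarker top-set genes must clear four p < 0.05 filters: median-split
log-rank against both relapse-free and overall survival (patients exactly at
the median go to the low group — the convention is pinned and logged), and
unadjusted Dunn post-hoc contrasts on joint ranks (after a Kruskal–Wallis
omnibus with tie correction) for normal-vs-tumor and tumor-vs-metastatic
expression.  A Bonferroni option exists behind a flag.  Survivors are
profiled by the number of reference-panel genes they touch directly at the
medium-confidence cutoff, as a count and as a percentage of the full panel.

## Synthetic study conditions

The generator plants `n_cliques` vertex-disjoint cliques of size
`clique_size` on a G(n, p) background and couples every downstream effect to
clique membership, mirroring the association the screen is designed to
detect.  Defaults (desk scale): 500 genes, three 8-cliques, a 20-gene
biomarker panel with 75 % of members in cliques, background edge probability
0.01.  Clique edges draw confidence from U(0.7, 1.0) and background edges
from U(0.4, 0.9), so cliques persist at the 0.9 cutoff while the background
thins — qualitatively reproducing the degradation of biomarker detection at
the highest-confidence setting.  Clique members' disease scores are drawn
from U(3, 5) against a U(0.5, 4) background so biomarkers concentrate in the
top ranks.  Ortholog qualification probability is 0.3 + 0.4·[clique member];
half the failures emit near-miss records straddling the 0.95 seed-score gate
so the gate itself is exercised.  Survival: expression ~ N(0, 1), event
times exponential with baseline hazard 0.02/month multiplied by 2.5 above
median expression for hazard-linked genes, uniform censoring on
(0, 120 months), n = 200 patients per endpoint.  Expression groups: 50
samples each at mean shifts (0, 1, 2) for planted full-effect candidates.
Three non-biomarker clique members carry all four effects.  All outputs are
functions of a single seed.

What the generator does *not* emulate: scale-free degree structure,
overlapping complexes/cliques, correlated edge-confidence channels,
identifier aliasing, and realistic censoring patterns.  Passing recovery
tests therefore demonstrates that the pipeline detects the planted
clique–biomarker–conservation–hazard coupling at these effect sizes, not
that it would achieve any particular rate on real interactome exports.

## Numerical choices and degenerate inputs

Scores are compared for tie purposes by exact floating equality; MCC scores
are exact integers.  Density is undefined (error) below two nodes; the
inclusion rate errors on a zero biomarker denominator; top-set extraction
errors on an empty ranking and returns an empty set when floor(q·n) = 0;
the log-rank split errors when a group has fewer than two patients; Ward
clustering validates symmetry, unit diagonal and positive semidefiniteness
of ρ.  Wilcoxon falls back to the asymptotic branch whenever ties are
present because the exact permutation distribution assumes distinct values.

## Problem sizes used by the shipped tests

Oracle-equivalence suites run over 200 seeded connected graphs of ≤ 8 nodes
plus the named toys (K3, K4, P3, K1,3); recovery suites use the default
500-gene spec over 50 seeds; calibration suites use 200 null replicates per
test.  These sizes were chosen so the full suite completes in well under
half an hour on one CPU while keeping binomial noise far from the asserted
margins.

## Known limitations

* Exact algorithms only: Brandes betweenness and Bron–Kerbosch are
  comfortable at desk scale (thousands of nodes) but no approximation path
  is provided for interactome-scale inputs.
* The EPC iteration count/threshold of the original plugin lineage are not
  documented anywhere authoritative; the defaults (1000, 0.5) are recorded
  in output metadata and configurable.
* Identifier mapping is exact string match; harmonizing gene symbols across
  sources is the caller's responsibility.
* Dunn p-values are unadjusted by default, matching the screening rule of a
  raw per-contrast threshold; this is anti-conservative if reused as a
  general post-hoc procedure.
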