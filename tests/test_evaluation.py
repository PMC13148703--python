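"""Top sets, inclusion rates, rank correlations, conservation, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cliquescreen import evaluation as ev
from cliquescreen.centrality import CentralityTable, rank_table
from cliquescreen.errors import (
    ConsistencyError,
    CoverageError,
    InsufficientDataError,
    ParameterError,
    UndefinedRateError,
    ValidationError,
)
from cliquescreen.netcore import BiomarkerSet, Network


def _table(scores, metric="MCC"):
    return CentralityTable.from_scores(metric, scores)


def _chain_network(genes):
    """Simple path over the given genes: everyone degree >= 1."""
    edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
    return Network.from_edges(genes, edges)


class TestTopFraction:
    def test_distinct_scores_yield_floor(self):
        scores = {f"g{i:04d}": 1362 - i for i in range(1362)}
        top = ev.top_fraction(_table(scores), 0.05)
        assert top.nominal_k == 68
        assert len(top.members) == 68 and not top.tie_extended

    def test_all_distinct_hundred(self):
        scores = {f"g{i:03d}": 100 - i for i in range(100)}
        top = ev.top_fraction(_table(scores), 0.05)
        assert len(top.members) == 5

    def test_tie_extension(self):
        scores = {f"a{i}": 2 for i in range(5)} | {f"b{i}": 1 for i in range(5)}
        top = ev.top_fraction(_table(scores), 0.3)
        assert top.nominal_k == 3
        assert top.tie_extended and top.extended_size == 5
        assert top.members == frozenset(f"a{i}" for i in range(5))

    def test_invalid_q(self):
        with pytest.raises(ParameterError):
            ev.top_fraction(_table({"a": 1, "b": 2}), 1.5)


class TestInclusionRate:
    def _run(self, hits, denom):
        genes = [f"g{i:03d}" for i in range(denom + 20)]
        net = _chain_network(genes)
        bm = BiomarkerSet(frozenset(genes[:denom]))
        members = frozenset(genes[:hits]) | frozenset(genes[denom:denom + 10])
        top = ev.TopSet("Betweenness", len(members), members, False, len(members))
        return ev.inclusion_rate(top, bm, net)

    def test_worked_arithmetic(self):
        assert self._run(4, 46).rate_percent == 8.7
        assert self._run(5, 64).rate_percent == 7.8
        assert self._run(6, 72).rate_percent == 8.3
        assert self._run(23, 64).rate_percent == 35.9

    def test_zero_hits(self):
        assert self._run(0, 46).rate_percent == 0.0

    def test_tie_normalization_rescales(self):
        genes = [f"g{i}" for i in range(10)]
        net = _chain_network(genes)
        bm = BiomarkerSet(frozenset(genes[:4]))
        top = ev.TopSet("EcCentricity", 2, frozenset(genes[:4]), True, 4)
        res = ev.inclusion_rate(top, bm, net)
        assert res.rate_percent_raw == 100.0
        assert res.rate_percent == 50.0  # rescaled by nominal/extended = 2/4

    def test_no_biomarkers_in_network(self):
        net = _chain_network(["a", "b"])
        bm = BiomarkerSet(frozenset(["zzz"]))
        top = ev.TopSet("MCC", 1, frozenset(["a"]), False, 1)
        with pytest.raises(UndefinedRateError):
            ev.inclusion_rate(top, bm, net)

    def test_marginal_average(self):
        assert ev.marginal_average([8.7, 7.8, 8.3]) == 8.3

    def test_hundred_percent_iff_all_captured(self):
        genes = [f"g{i}" for i in range(10)]
        net = _chain_network(genes)
        bm = BiomarkerSet(frozenset(genes[:3]))
        top = ev.TopSet("MCC", 3, frozenset(genes[:3]), False, 3)
        assert ev.inclusion_rate(top, bm, net).rate_percent == 100.0


class TestGridEvaluate:
    def test_single_cell_matches_inclusion_rate(self):
        from cliquescreen.synthetic_data import SyntheticSpec, generate_network
        from cliquescreen.netcore import build_network
        from cliquescreen.centrality import mcc

        spec = SyntheticSpec(n_genes=60, n_biomarkers=6, n_cliques=1,
                             clique_size=5, n_candidates=0, rng_seed=5)
        table, edges, bm, _ = generate_network(spec)
        grid = ev.grid_evaluate(table, edges, bm, [60], [0.4], ["MCC"], q=0.1)
        assert len(grid.results) == 1
        net = build_network(table, 60, edges, 0.4)
        top = ev.top_fraction(mcc(net), 0.1)
        direct = ev.inclusion_rate(top, bm, net)
        assert grid.results[0].rate_percent == direct.rate_percent


class TestRankMatrix:
    def test_columns_match_tables(self):
        t1 = _table({"a": 3, "b": 2, "c": 1}, "MCC")
        t2 = _table({"a": 1, "b": 2, "c": 3}, "Degree")
        bm = BiomarkerSet(frozenset(["a", "c"]))
        m = ev.biomarker_rank_matrix({"MCC": t1, "Degree": t2}, bm)
        assert list(m.index) == ["a", "c"]
        assert m.loc["a", "MCC"] == 1 and m.loc["a", "Degree"] == 3

    def test_degree_zero_biomarker_dropped(self):
        t1 = _table({"a": 3, "b": 2}, "MCC")
        bm = BiomarkerSet(frozenset(["a", "isolated"]))
        m = ev.biomarker_rank_matrix({"MCC": t1}, bm)
        assert list(m.index) == ["a"]

    def test_inconsistent_tables_raise(self):
        t1 = _table({"a": 3, "b": 2}, "MCC")
        t2 = _table({"a": 1}, "Degree")
        with pytest.raises(ConsistencyError):
            ev.biomarker_rank_matrix({"MCC": t1, "Degree": t2}, BiomarkerSet(frozenset(["a"])))

    def test_identical_scores_identical_columns(self):
        scores = {"a": 5, "b": 4, "c": 3}
        m = ev.biomarker_rank_matrix(
            {"MCC": _table(scores, "MCC"), "Degree": _table(scores, "Degree")},
            BiomarkerSet(frozenset(scores)),
        )
        assert (m["MCC"] == m["Degree"]).all()


def _spearman_hand(x, y):
    """Direct average-rank formula on 5 observations (Pearson on midranks)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_self_and_reversed(self):
        m = pd.DataFrame(
            {"A": [1, 2, 3, 4, 5], "B": [1, 2, 3, 4, 5], "C": [5, 4, 3, 2, 1]}
        )
        rho = ev.spearman_matrix(m)
        assert rho.loc["A", "A"] == 1.0
        assert rho.loc["A", "B"] == pytest.approx(1.0)
        assert rho.loc["A", "C"] == pytest.approx(-1.0)
        assert np.allclose(rho.values, rho.values.T)

    def test_tied_rank_fixture_matches_direct_formula(self):
        x = [1, 2, 2, 4, 5]
        y = [3, 1, 4, 4, 2]
        rho = ev.spearman_matrix(pd.DataFrame({"X": x, "Y": y, "Z": y}))
        assert rho.loc["X", "Y"] == pytest.approx(_spearman_hand(np.array(x), np.array(y)))

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            ev.spearman_matrix(pd.DataFrame({"A": [1, 2], "B": [2, 1]}))


class TestWardClusters:
    def test_correlated_pair_splits_from_anticorrelated(self):
        rho = pd.DataFrame(
            [[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]],
            index=list("mnp"), columns=list("mnp"),
        )
        clusters = ev.ward_clusters(rho, 0.8)
        assert {frozenset(c) for c in clusters} == {frozenset("mn"), frozenset("p")}

    def test_all_below_threshold_all_singletons(self):
        k = 4
        rho = pd.DataFrame(np.eye(k) * 0.9 + 0.1 * np.eye(k), index=list("abcd"), columns=list("abcd"))
        np_rho = np.full((k, k), 0.1)
        np.fill_diagonal(np_rho, 1.0)
        rho = pd.DataFrame(np_rho, index=list("abcd"), columns=list("abcd"))
        clusters = ev.ward_clusters(rho, 0.8)
        assert all(len(c) == 1 for c in clusters)

    def test_agrees_with_reference_linkage(self):
        """5-metric fixture vs an independently computed scipy cut."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(31)
        base = rng.normal(size=(30, 2))
        cols = {
            "a": base[:, 0],
            "b": base[:, 0] + rng.normal(scale=0.05, size=30),
            "c": base[:, 1],
            "d": base[:, 1] + rng.normal(scale=0.05, size=30),
            "e": rng.normal(size=30),
        }
        rho = pd.DataFrame(cols).corr(method="spearman")
        clusters = ev.ward_clusters(rho, 0.8)
        d = squareform(1 - rho.values, checks=False)
        labels = fcluster(linkage(d, method="ward"), t=0.2, criterion="distance")
        want = {}
        for m, lab in zip(rho.columns, labels):
            want.setdefault(lab, set()).add(m)
        assert {frozenset(c) for c in clusters} == {frozenset(c) for c in want.values()}

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError):
            ev.ward_clusters(bad, 0.8)


def _ortho(rows):
    return pd.DataFrame(rows, columns=["gene", "species", "inparalog_score", "seed_score"])


class TestConservation:
    def test_all_five_species_score_one(self):
        rows = [("CDC6", sp, 1.0, 0.97) for sp in ev.SPECIES_PANEL]
        scores = ev.conservation_scores(_ortho(rows), {"CDC6"})
        assert scores.loc["CDC6", "score"] == 1.0

    def test_no_records_zero(self):
        scores = ev.conservation_scores(_ortho([]), {"X"})
        assert scores.loc["X", "score"] == 0.0

    def test_seed_gate_disqualifies(self):
        rows = [("G", sp, 1.0, 0.97) for sp in ev.SPECIES_PANEL[:3]]
        rows.append(("G", ev.SPECIES_PANEL[3], 1.0, 0.90))  # below the 0.95 gate
        scores = ev.conservation_scores(_ortho(rows), {"G"})
        assert scores.loc["G", "score"] == pytest.approx(0.6)

    def test_inparalog_gate_disqualifies(self):
        rows = [("G", ev.SPECIES_PANEL[0], 0.8, 0.99)]
        scores = ev.conservation_scores(_ortho(rows), {"G"})
        assert scores.loc["G", "score"] == 0.0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError):
            ev.conservation_scores(_ortho([("G", "H.sapiens", 1.0, 1.0)]), {"G"})

    @given(st.lists(st.tuples(st.sampled_from(ev.SPECIES_PANEL),
                              st.floats(0, 1), st.floats(0, 1)), max_size=15))
    def test_scores_live_on_the_five_point_grid(self, records):
        rows = [("G", sp, ip, seed) for sp, ip, seed in records]
        score = ev.conservation_scores(_ortho(rows), {"G"}).loc["G", "score"]
        assert score in {0.0, 0.2, 0.4, 0.6, 0.8, 1.0}


def _exact_ranksum_pvalue(x, y):
    """Two-sided p by enumerating every assignment of the pooled values."""
    pooled = list(x) + list(y)
    n_x = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)  # rank sum, untied data
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:n_x].sum()
    mu = n_x * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


class TestHighLowCompare:
    def _ranking(self, genes):
        return CentralityTable.from_scores("MCC", {g: -i for i, g in enumerate(genes)})

    def test_exact_small_sample(self):
        # X={1,2} vs Y={3,4}: exact two-sided p = 1/3
        stat, p = ev.rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_mirror_symmetric_toy(self):
        _, p = ev.rank_sum_test([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_on_small_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            x = list(rng.normal(size=4))
            y = list(rng.normal(size=5))
            _, p = ev.rank_sum_test(x, y)
            assert p == pytest.approx(_exact_ranksum_pvalue(x, y))

    def test_group_sizes_even_and_odd(self):
        for n, sizes in ((64, (32, 32)), (62, (31, 31))):
            genes = [f"g{i:03d}" for i in range(n)]
            ranking = self._ranking(genes)
            bm = BiomarkerSet(frozenset(genes))
            values = {g: float(i) for i, g in enumerate(genes)}
            cmp = ev.high_low_compare(values, ranking, bm)
            assert cmp.group_sizes == sizes

    def test_high_group_is_better_ranked(self):
        genes = [f"g{i}" for i in range(8)]
        ranking = self._ranking(genes)
        bm = BiomarkerSet(frozenset(genes))
        values = {g: 0.0 for g in genes}
        cmp = ev.high_low_compare(values, ranking, bm)
        assert max(ranking.ranks[g] for g in cmp.high_genes) <= min(
            ranking.ranks[g] for g in cmp.low_genes
        )

    def test_missing_value_raises_coverage(self):
        genes = [f"g{i}" for i in range(6)]
        with pytest.raises(CoverageError):
            ev.high_low_compare(
                {g: 1.0 for g in genes[:-1]},
                self._ranking(genes),
                BiomarkerSet(frozenset(genes)),
            )
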