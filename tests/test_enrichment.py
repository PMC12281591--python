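import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sigscreen as ss
from sigscreen.enrichment import (
    DegenerateScoreError,
    EmptyEffectiveSetError,
    UndefinedMissError,
)
from conftest import brute_force_es, naive_bh


def geneset(*members):
    return ss.GeneSet("s", "", frozenset(members))


class TestEnrichmentScore:
    def test_top_gene_scores_one(self, ranked4):
        es, running, leading = ss.enrichment_score(ranked4, geneset("gA"), 1.0)
        assert es == pytest.approx(1.0)
        assert leading == ("gA",)
        assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_bottom_gene_scores_minus_one(self, ranked4):
        es, running, leading = ss.enrichment_score(ranked4, geneset("gD"), 1.0)
        assert es == pytest.approx(-1.0)
        assert leading == ("gD",)

    def test_matches_brute_force_on_mixed_set(self, ranked10):
        members = frozenset({"g2", "g6"})  # rank-3 and rank-7 genes
        es, _, _ = ss.enrichment_score(ranked10, geneset(*members), 1.0)
        expected = brute_force_es(ranked10.genes, list(ranked10.metrics), members)
        assert es == pytest.approx(expected, abs=1e-12)

    def test_all_subsets_match_brute_force(self, ranked10):
        """Oracle equivalence on every non-trivial subset of the 10-gene list."""
        genes = ranked10.genes
        metrics = list(ranked10.metrics)
        for r in range(1, len(genes)):
            for sub in itertools.combinations(genes, r):
                members = frozenset(sub)
                es, _, _ = ss.enrichment_score(ranked10, geneset(*members), 1.0)
                assert es == pytest.approx(
                    brute_force_es(genes, metrics, members), abs=1e-12)

    def test_error_cases(self, ranked4):
        with pytest.raises(EmptyEffectiveSetError):
            ss.enrichment_score(ranked4, geneset("gZ"), 1.0)
        with pytest.raises(UndefinedMissError):
            ss.enrichment_score(ranked4, geneset("gA", "gB", "gC", "gD"), 1.0)
        zero_ranked = ss.RankedSignature(entries=(("gA", 1.0), ("gB", 0.0), ("gC", 0.0)))
        with pytest.raises(DegenerateScoreError):
            ss.enrichment_score(zero_ranked, geneset("gB"), 1.0)

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_bounds_and_zero_sum(self, data):
        n = data.draw(st.integers(5, 30))
        metrics = sorted(data.draw(st.lists(
            st.floats(-10, 10), min_size=n, max_size=n)), reverse=True)
        genes = [f"g{i}" for i in range(n)]
        ranked = ss.RankedSignature(entries=tuple(zip(genes, metrics)))
        k = data.draw(st.integers(1, n - 1))
        members = frozenset(data.draw(st.permutations(genes))[:k])
        try:
            es, running, _ = ss.enrichment_score(ranked, geneset(*members), 1.0)
        except DegenerateScoreError:
            return
        assert abs(es) <= 1.0 + 1e-12
        assert abs(running[-1]) < 1e-9

    def test_antisymmetry(self, ranked10):
        """Reversing the list and negating metrics flips the ES sign."""
        rev = ss.RankedSignature(entries=tuple(
            (g, -v) for g, v in reversed(ranked10.entries)))
        for members in [{"g0"}, {"g2", "g6"}, {"g9", "g1", "g5"}]:
            es_f, _, _ = ss.enrichment_score(ranked10, geneset(*members), 1.0)
            es_r, _, _ = ss.enrichment_score(rev, geneset(*members), 1.0)
            assert es_r == pytest.approx(-es_f, abs=1e-12)


class TestPermutationNull:
    def test_reproducible(self, ranked10):
        params = ss.EnrichmentParams(n_perm=5, seed=11)
        a = ss.permutation_null(ranked10, 3, params)
        b = ss.permutation_null(ranked10, 3, params)
        assert np.array_equal(a, b)
        assert a.shape == (5,)

    def test_near_full_set_size_defined(self, ranked10):
        params = ss.EnrichmentParams(n_perm=3, seed=0)
        null = ss.permutation_null(ranked10, len(ranked10) - 1, params)
        assert np.all(np.isfinite(null))

    def test_null_mean_near_zero_on_symmetric_ranking(self):
        rng = np.random.default_rng(5)
        metrics = np.sort(rng.uniform(-1, 1, size=100))[::-1]
        ranked = ss.RankedSignature(entries=tuple(
            (f"g{i}", float(v)) for i, v in enumerate(metrics)))
        null = ss.permutation_null(ranked, 10, ss.EnrichmentParams(n_perm=1000, seed=5))
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se + 0.05


class TestNormalizeEs:
    def test_positive_stratum(self):
        null = [0.25, -0.5, 0.25, -0.1]
        nes, p = ss.normalize_es(0.5, null)
        assert nes == pytest.approx(2.0)

    def test_negative_stratum(self):
        nes, p = ss.normalize_es(-0.5, [-0.25, 0.3, -0.25])
        assert nes == pytest.approx(-2.0)

    def test_plus_one_corrected_tail(self):
        null = [0.5] * 99  # all |s| < 0.9
        nes, p = ss.normalize_es(0.9, null)
        assert p == pytest.approx(1 / 100)

    def test_zero_es(self, caplog):
        with caplog.at_level("WARNING", logger="sigscreen"):
            nes, p = ss.normalize_es(0.0, [0.1, -0.2])
        assert (nes, p) == (0.0, 1.0)

    def test_empty_same_sign_stratum(self, caplog):
        with caplog.at_level("WARNING", logger="sigscreen"):
            nes, p = ss.normalize_es(0.5, [-0.25, -0.75])
        assert nes == pytest.approx(1.0)  # normalized by mean |null|
        assert p == pytest.approx(1 / 3)


class TestGseaPreranked:
    def test_small_set_skipped(self, ranked10, caplog):
        params = ss.EnrichmentParams(n_perm=10, min_size=3, seed=0)
        with caplog.at_level("WARNING", logger="sigscreen"):
            results = ss.gsea_preranked(ranked10, [geneset("g0")], params)
        assert results == []
        assert any("SKIP" in m for m in caplog.messages)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_planted_set_detected(self, seed):
        """A set concentrated in the top decile of a simulated ranking has the
        largest NES and a significant p-value."""
        cfg = ss.SimulationConfig(n_genes=500, frac_de=0.3, seed=seed)
        records, truth = ss.simulate_de_table(cfg)
        ranked = ss.rank_genes(records)
        target = list(ranked.genes[:50])
        sets = ss.simulate_gene_sets(6, (20, 20), list(truth), 0.9, target, seed=seed)
        params = ss.EnrichmentParams(n_perm=200, seed=seed)
        results = ss.gsea_preranked(ranked, sets, params)
        assert results[0].set_id == "SET_1"
        assert results[0].pvalue <= 0.05

    def test_identical_sets_identical_results(self, ranked10):
        params = ss.EnrichmentParams(n_perm=50, min_size=1, seed=0)
        twin = [geneset("g0", "g1", "g2"), geneset("g0", "g1", "g2")]
        results = ss.gsea_preranked(ranked10, twin, params)
        assert results[0].es == results[1].es
        assert results[0].nes == results[1].nes
        assert results[0].padj == results[1].padj


class TestBhAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.2], [0.2]),
        ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
    ])
    def test_hand_checked_vectors(self, pvals, expected):
        assert ss.bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            assert ss.bh_adjust(p) == pytest.approx(naive_bh(p), abs=1e-12)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1.0, size=50)
        adj = ss.bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ss.bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            ss.bh_adjust([1.5])


class TestOraFisher:
    def test_exact_hypergeometric_tail(self):
        """Enumerated toy case: P(X >= 4) = (C(5,4)C(15,1) + C(5,5)) / C(20,5)."""
        background = [f"g{i}" for i in range(20)]
        gene_set = geneset(*background[:5])
        interest = background[1:5] + [background[10]]  # overlap 4
        results = ss.ora_fisher(interest, background, [gene_set])
        assert results[0].overlap == 4
        assert results[0].pvalue == pytest.approx(76 / 15504)

    def test_zero_overlap_pvalue_one(self):
        background = [f"g{i}" for i in range(20)]
        results = ss.ora_fisher(background[:3], background, [geneset(*background[10:12])])
        assert results[0].pvalue == pytest.approx(1.0)

    def test_interest_outside_background(self):
        with pytest.raises(ValueError, match="gX"):
            ss.ora_fisher(["gX"], ["g1", "g2"], [geneset("g1")])

    def test_gene_ratio(self):
        background = [f"g{i}" for i in range(20)]
        results = ss.ora_fisher(background[:4], background, [geneset(*background[:2])])
        assert results[0].gene_ratio == pytest.approx(2 / 4)


class TestMeanRankAggregate:
    def test_tie_broken_by_item_id(self):
        out = ss.mean_rank_aggregate({"L1": {"A": 1, "B": 2}, "L2": {"A": 2, "B": 1}})
        assert out == [("A", 1.5), ("B", 1.5)]

    def test_single_library_order(self):
        out = ss.mean_rank_aggregate({"L1": {"A": 1, "B": 3, "C": 2}})
        assert [item for item, _ in out] == ["A", "C", "B"]

    def test_missing_item_penalty(self):
        out = ss.mean_rank_aggregate({
            "L1": {"A": 1, "B": 2, "C": 3},
            "L2": {"B": 1, "C": 2, "D": 3},
        })
        means = dict(out)
        assert means["A"] == pytest.approx((1 + 4) / 2)

    def test_empty_rankings_error(self):
        with pytest.raises(ValueError):
            ss.mean_rank_aggregate({})


def test_permutation_pvalues_uniform_under_null():
    """Permutation p-values for random gene sets on a random ranking are
    approximately uniform (KS test at level 0.01)."""
    rng = np.random.default_rng(0)
    metrics = np.sort(rng.normal(size=2000))[::-1]
    genes = [f"g{i}" for i in range(2000)]
    ranked = ss.RankedSignature(entries=tuple(zip(genes, metrics)))
    params = ss.EnrichmentParams(n_perm=500, seed=0)
    cache = {}
    pvals = []
    for i in range(200):
        size = int(rng.integers(10, 51))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        es, _, _ = ss.enrichment_score(ranked, geneset(*members), 1.0)
        if size not in cache:
            cache[size] = ss.permutation_null(ranked, size, params)
        _, p = ss.normalize_es(es, cache[size])
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
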