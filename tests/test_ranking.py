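"""Relevance scores, elementwise integration, rank transforms, and aggregation."""

import numpy as np
import pytest

import minnetrank as m
from minnetrank.omics import OmicsScoreMatrix
from minnetrank.ranking import RelevanceScoreMatrix


def _scores(matrix, genes, samples, kind="mutation", normalized=True):
    return OmicsScoreMatrix(matrix=np.asarray(matrix, dtype=float),
                            gene_order=tuple(genes), samples=tuple(samples),
                            kind=kind, normalized=normalized)


def _rel(matrix, genes, samples, source="mutation", strategy=None):
    return RelevanceScoreMatrix(matrix=np.asarray(matrix, dtype=float),
                                gene_order=tuple(genes), samples=tuple(samples),
                                source=source, strategy=strategy)


class TestRelevanceScores:
    def test_identity_diffusion_returns_input(self, mutual_pair):
        d = m.compute_diffusion(m.normalize_adjacency(mutual_pair), 1.0)
        s = _scores([[1, 0], [0, 1]], mutual_pair.genes, ["a", "b"])
        w = m.relevance_scores(d, s)
        np.testing.assert_array_equal(w.matrix, s.matrix)
        assert w.source == "mutation"

    def test_mutual_pair_hand_product(self, mutual_pair):
        d = m.compute_diffusion(m.normalize_adjacency(mutual_pair), 0.5)
        s = _scores([[1], [0]], mutual_pair.genes, ["a"])
        w = m.relevance_scores(d, s)
        np.testing.assert_allclose(w.matrix[:, 0], [2 / 3, 1 / 3], atol=1e-12)

    def test_column_mass_conserved(self, fixture7, diffusion7):
        rng = np.random.default_rng(1)
        raw = rng.uniform(size=(fixture7.network.n_genes, 4))
        s = m.column_normalize(_scores(raw, fixture7.network.genes,
                                       ["a", "b", "c", "d"], normalized=False))
        w = m.relevance_scores(diffusion7, s)
        np.testing.assert_allclose(w.matrix.sum(axis=0), np.ones(4), atol=1e-8)

    def test_gene_order_mismatch_rejected(self, mutual_pair):
        d = m.compute_diffusion(m.normalize_adjacency(mutual_pair), 0.5)
        s = _scores([[1], [0]], ("g2", "g1"), ["a"])
        with pytest.raises(ValueError, match="gene order"):
            m.relevance_scores(d, s)

    def test_unnormalized_input_rejected(self, mutual_pair):
        d = m.compute_diffusion(m.normalize_adjacency(mutual_pair), 0.5)
        with pytest.raises(ValueError, match="normalized"):
            m.relevance_scores(d, _scores([[1], [0]], mutual_pair.genes, ["a"], normalized=False))


class TestIntegrate:
    def test_min_demotes_single_omics_outlier(self):
        # the outlier narrative: huge mutation score, tiny expression score
        wm = _rel([[0.48]], ["OR2C3"], ["s"], "mutation")
        we = _rel([[3.24e-6]], ["OR2C3"], ["s"], "expression")
        w = m.integrate(wm, we, "min")
        assert w.matrix[0, 0] == pytest.approx(3.24e-6)
        assert w.source == "integrated" and w.strategy == "min"

    def test_identical_inputs_idempotent(self):
        wm = _rel([[0.2, 0.8]], ["g"], ["a", "b"], "mutation")
        we = _rel([[0.2, 0.8]], ["g"], ["a", "b"], "expression")
        for strat in ("min", "mean", "max"):
            np.testing.assert_array_equal(m.integrate(wm, we, strat).matrix, wm.matrix)

    def test_min_le_mean_le_max(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(size=(2, 6, 4))
        genes = [f"g{i}" for i in range(6)]
        wm = _rel(a, genes, list("abcd"), "mutation")
        we = _rel(b, genes, list("abcd"), "expression")
        w_min = m.integrate(wm, we, "min").matrix
        w_mean = m.integrate(wm, we, "mean").matrix
        w_max = m.integrate(wm, we, "max").matrix
        assert np.all(w_min <= w_mean + 1e-15) and np.all(w_mean <= w_max + 1e-15)
        assert np.all(w_min <= a) and np.all(w_min <= b)

    def test_sample_mismatch_lists_difference(self):
        wm = _rel([[1, 2]], ["g"], ["a", "b"], "mutation")
        we = _rel([[1, 2]], ["g"], ["a", "c"], "expression")
        with pytest.raises(ValueError, match="'b'.*'c'"):
            m.integrate(wm, we)


class TestRanks:
    def test_rank_one_is_largest(self):
        w = _rel([[0.5], [0.2], [0.3]], ["a", "b", "c"], ["s"])
        np.testing.assert_array_equal(m.per_sample_ranks(w)[:, 0], [1, 3, 2])

    def test_average_rank_ties(self):
        w = _rel([[0.4], [0.4], [0.1]], ["a", "b", "c"], ["s"])
        np.testing.assert_array_equal(m.per_sample_ranks(w)[:, 0], [1.5, 1.5, 3])

    def test_all_zero_column_total_tie(self):
        w = _rel(np.zeros((5, 1)), list("abcde"), ["s"])
        np.testing.assert_array_equal(m.per_sample_ranks(w)[:, 0], np.full(5, 3.0))

    def test_column_sums_invariant(self):
        rng = np.random.default_rng(8)
        n = 17
        w = _rel(rng.choice([0.0, 0.1, 0.5], size=(n, 6)), [f"g{i}" for i in range(n)],
                 list("abcdef"))
        ranks = m.per_sample_ranks(w)
        np.testing.assert_allclose(ranks.sum(axis=0), np.full(6, n * (n + 1) / 2))


class TestAggregateRanks:
    def test_hand_example(self):
        ranks = np.array([[1, 3], [2, 1], [3, 2]], dtype=float)
        r = m.aggregate_ranks(ranks, ["g1", "g2", "g3"], ["a", "b"])
        assert r.genes == ("g2", "g1", "g3")
        assert r.scores == (3.0, 4.0, 5.0)

    def test_consistent_samples_preserve_order(self):
        ranks = np.array([[2, 2], [1, 1], [3, 3]], dtype=float)
        r = m.aggregate_ranks(ranks, ["x", "y", "z"])
        assert r.genes == ("y", "x", "z")

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ranks = rng.permuted(np.tile(np.arange(1.0, 11.0), (4, 1)).T, axis=0)
        genes = [f"g{i}" for i in range(10)]
        r1 = m.aggregate_ranks(ranks, genes)
        r2 = m.aggregate_ranks(ranks[:, ::-1], genes)
        assert r1.genes == r2.genes and r1.scores == r2.scores

    def test_lexicographic_tie_break(self):
        ranks = np.array([[1.5], [1.5]], dtype=float)
        r = m.aggregate_ranks(ranks, ["zz", "aa"])
        assert r.genes == ("aa", "zz")


class TestFrequencyBaseline:
    def test_frequency_order(self):
        mat = np.zeros((2, 10))
        mat[0, :3] = 1
        mat[1, :1] = 1
        sm = _scores(mat, ["g1", "g2"], [f"s{i}" for i in range(10)], normalized=False)
        r = m.frequency_baseline(sm)
        assert r.genes == ("g1", "g2")
        assert r.scores == (0.3, 0.1)

    def test_all_zero_lexicographic(self):
        sm = _scores(np.zeros((3, 2)), ["c", "a", "b"], ["s1", "s2"], normalized=False)
        r = m.frequency_baseline(sm)
        assert r.genes == ("a", "b", "c") and set(r.scores) == {0.0}

    def test_matches_hand_count_on_fixture(self, fixture7):
        from minnetrank.weighting import WeightScheme, assign_variant_weights
        weighted = assign_variant_weights(list(fixture7.variants), WeightScheme())
        sm = m.build_mutation_scores(weighted, fixture7.network, list(fixture7.samples),
                                     cap_at_one=True)
        r = m.frequency_baseline(sm)
        mutated = {}
        for v in weighted:
            mutated.setdefault(v.gene, set()).add(v.sample)
        top = r.genes[0]
        assert r.scores[0] == pytest.approx(len(mutated[top]) / len(fixture7.samples))

    def test_normalized_input_rejected(self):
        sm = _scores([[1.0]], ["g"], ["s"], normalized=True)
        with pytest.raises(ValueError):
            m.frequency_baseline(sm)


class TestMinSourceProportions:
    def test_dominance(self):
        wm = _rel([[0.1, 0.2]], ["g"], ["a", "b"], "mutation")
        we = _rel([[0.5, 0.9]], ["g"], ["a", "b"], "expression")
        w = m.integrate(wm, we, "min")
        assert m.min_source_proportions(wm, we, w, ["g"]) == (1.0, 0.0)

    def test_exact_ties_count_in_both(self):
        wm = _rel([[0.3]], ["g"], ["a"], "mutation")
        we = _rel([[0.3]], ["g"], ["a"], "expression")
        w = m.integrate(wm, we, "min")
        assert m.min_source_proportions(wm, we, w, ["g"]) == (1.0, 1.0)

    def test_matches_brute_force_cell_count(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(8)]
        samples = list("abcde")
        a, b = rng.uniform(size=(2, 8, 5))
        wm = _rel(a, genes, samples, "mutation")
        we = _rel(b, genes, samples, "expression")
        w = m.integrate(wm, we, "min")
        top = genes[:4]
        pm, pe = m.min_source_proportions(wm, we, w, top)
        cells = [(i, j) for i in range(4) for j in range(5)]
        brute_m = sum(a[i, j] <= b[i, j] for i, j in cells) / len(cells)
        brute_e = sum(b[i, j] <= a[i, j] for i, j in cells) / len(cells)
        assert pm == pytest.approx(brute_m) and pe == pytest.approx(brute_e)

    def test_unknown_gene_rejected(self):
        wm = _rel([[0.1]], ["g"], ["a"], "mutation")
        we = _rel([[0.5]], ["g"], ["a"], "expression")
        w = m.integrate(wm, we, "min")
        with pytest.raises(ValueError):
            m.min_source_proportions(wm, we, w, ["nope"])

    def test_requires_min_strategy(self):
        wm = _rel([[0.1]], ["g"], ["a"], "mutation")
        we = _rel([[0.5]], ["g"], ["a"], "expression")
        w = m.integrate(wm, we, "mean")
        with pytest.raises(ValueError, match="min"):
            m.min_source_proportions(wm, we, w, ["g"])
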