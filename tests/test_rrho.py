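"""Signed ranking, hypergeometric overlap, RRHO maps, quadrants."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import sigerode as sg
from conftest import de_table


def exact_upper_tail(k: int, i: int, j: int, N: int) -> Fraction:
    """Exact P(X >= k), X ~ Hypergeometric(N, i, j), by rational summation."""
    total = Fraction(0)
    denom = math.comb(N, j)
    for x in range(k, min(i, j) + 1):
        total += Fraction(math.comb(i, x) * math.comb(N - i, j - x), denom)
    return total


class TestRankGenes:
    def test_rank_value_formula(self):
        t = de_table(["a", "b", "c"], [1.0, -1.0, 0.5], [0.01, 0.01, 1.0])
        ranked = sg.rank_genes(t)
        values = dict(zip(ranked.genes, ranked.rank_values))
        assert values["a"] == pytest.approx(2.0)
        assert values["b"] == pytest.approx(-2.0)
        assert values["c"] == 0.0

    def test_ordering_matches_brute_force_sort(self):
        rng = np.random.default_rng(11)
        n = 100
        lfc = np.round(rng.normal(0, 1, n), 2)  # rounding forces ties
        p = np.round(rng.uniform(0.001, 1, n), 2)
        t = de_table([f"g{i:03d}" for i in range(n)], lfc, p)
        ranked = sg.rank_genes(t)
        rows = [
            (-(-math.log10(pv) * np.sign(l)), -abs(l), g)
            for g, l, pv in zip(t["gene_id"], lfc, p)
        ]
        expected = [g for _, _, g in sorted(rows)]
        assert list(ranked.genes) == expected
        assert (np.diff(ranked.rank_values) <= 0).all()

    def test_rejects_nonpositive_p(self):
        with pytest.raises(ValueError, match="pvalue"):
            sg.rank_genes(de_table(["a"], [1.0], [0.0]))


class TestHypergeomOverlap:
    def test_zero_overlap_is_certain(self):
        assert sg.hypergeom_overlap_p(0, 5, 5, 10) == 1.0

    @pytest.mark.parametrize(
        "k,i,j,N",
        [(3, 5, 5, 10), (4, 5, 4, 20), (2, 6, 3, 12)],
    )
    def test_matches_exact_rational_tail(self, k, i, j, N):
        expected = float(exact_upper_tail(k, i, j, N))
        assert sg.hypergeom_overlap_p(k, i, j, N) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            sg.hypergeom_overlap_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            sg.hypergeom_overlap_p(1, 11, 5, 10)

    def test_underflow_rescued_to_finite_neglog(self):
        # overlap so extreme the survival function underflows double precision
        p = sg.hypergeom_overlap_p(1000, 1000, 1000, 12000)
        assert p > 0.0
        assert -np.log10(p) > 300


def _ranked_from_values(genes, values):
    order = np.argsort(-np.asarray(values), kind="stable")
    return sg.RankedList(np.asarray(genes)[order], np.asarray(values, dtype=float)[order])


class TestBuildRRHO:
    def test_self_overlap_diagonal(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(60)]
        vals = rng.normal(0, 2, 60)
        l1 = _ranked_from_values(genes, vals)
        m = sg.build_rrho(l1, l1, step=10)
        diag = np.diag(m.overlap)
        assert (diag == m.prefix_sizes).all()
        # maximum signal sits on the diagonal for a self-comparison
        i, j = np.unravel_index(np.argmax(m.neglog10_p), m.neglog10_p.shape)
        assert i == j

    def test_full_universe_cell_is_zero(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(40)]
        l1 = _ranked_from_values(genes, rng.normal(0, 1, 40))
        l2 = _ranked_from_values(genes, rng.normal(0, 1, 40))
        m = sg.build_rrho(l1, l2, step=10)
        assert m.overlap[-1, -1] == 40
        assert m.neglog10_p[-1, -1] == 0.0

    def test_interleaved_toy_matches_enumeration(self):
        # fixed interleaved lists: list1 = g00..g19 by value, list2 swaps
        # neighbouring pairs
        genes = [f"g{i:02d}" for i in range(20)]
        v1 = np.arange(20, 0, -1.0) - 10.5  # descending, half positive
        order2 = [i + 1 if i % 2 == 0 else i - 1 for i in range(20)]
        l1 = sg.RankedList(np.array(genes), v1)
        l2 = sg.RankedList(np.array(genes)[order2], v1.copy())
        m = sg.build_rrho(l1, l2, step=5)
        assert m.neglog10_p.shape == (4, 4)
        top1 = list(l1.genes)
        top2 = list(l2.genes)
        for a, i in enumerate(m.prefix_sizes):
            for b, j in enumerate(m.prefix_sizes):
                k = len(set(top1[:i]) & set(top2[:j]))
                assert m.overlap[a, b] == k
                expected = -math.log10(float(exact_upper_tail(k, i, j, 20))) if k else 0.0
                assert m.neglog10_p[a, b] == pytest.approx(expected, abs=1e-9)

    def test_partial_final_prefix_included(self):
        genes = [f"g{i:02d}" for i in range(23)]
        l1 = _ranked_from_values(genes, np.arange(23.0))
        m = sg.build_rrho(l1, l1, step=5)
        assert m.neglog10_p.shape == (5, 5)
        assert m.prefix_sizes[-1] == 23

    def test_monotone_overlap_in_both_axes(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:04d}" for i in range(500)]
        l1 = _ranked_from_values(genes, rng.normal(0, 1, 500))
        l2 = _ranked_from_values(genes, rng.normal(0, 1, 500))
        m = sg.build_rrho(l1, l2, step=50)
        assert (np.diff(m.overlap, axis=0) >= 0).all()
        assert (np.diff(m.overlap, axis=1) >= 0).all()
        assert (m.overlap <= np.minimum(m.prefix_sizes[:, None], m.prefix_sizes[None, :])).all()

    def test_label_invariance(self):
        rng = np.random.default_rng(10)
        genes = np.array([f"g{i:03d}" for i in range(120)])
        v1 = rng.normal(0, 1, 120)
        v2 = 0.6 * v1 + rng.normal(0, 0.8, 120)
        l1 = _ranked_from_values(genes, v1)
        l2 = _ranked_from_values(genes, v2)
        m = sg.build_rrho(l1, l2, step=20)
        renamed = {g: f"x{idx:04d}" for idx, g in enumerate(genes)}
        l1r = sg.RankedList(np.array([renamed[g] for g in l1.genes]), l1.rank_values)
        l2r = sg.RankedList(np.array([renamed[g] for g in l2.genes]), l2.rank_values)
        mr = sg.build_rrho(l1r, l2r, step=20)
        assert np.allclose(m.neglog10_p, mr.neglog10_p)

    def test_self_comparison_dominates_shuffles(self):
        rng = np.random.default_rng(12)
        genes = np.array([f"g{i:04d}" for i in range(1000)])
        l1 = _ranked_from_values(genes, rng.normal(0, 2, 1000))
        self_max = sg.build_rrho(l1, l1, step=50).max_signal
        for _ in range(50):
            shuffled = l1.shuffled(rng)
            assert sg.build_rrho(shuffled, l1, step=50).max_signal <= self_max

    def test_step_larger_than_universe_is_error(self):
        l1 = _ranked_from_values(["a", "b"], [1.0, -1.0])
        with pytest.raises(ValueError, match="step"):
            sg.build_rrho(l1, l1, step=5)

    def test_disjoint_universes_intersected(self):
        l1 = _ranked_from_values([f"g{i}" for i in range(10)], np.arange(10.0))
        l2 = _ranked_from_values([f"g{i}" for i in range(5, 15)], np.arange(10.0))
        m = sg.build_rrho(l1, l2, step=1)
        assert m.n_genes == 5

    def test_stratified_mode_concordant_corners(self):
        rng = np.random.default_rng(4)
        genes = np.array([f"g{i:03d}" for i in range(200)])
        vals = np.concatenate([rng.uniform(1, 3, 100), rng.uniform(-3, -1, 100)])
        l1 = _ranked_from_values(genes, vals)
        m = sg.build_rrho(l1, l1, step=20, mode="stratified")
        # self-comparison: strong signal in both the UU (small prefixes) and
        # DD (large prefixes / list tails) corners
        assert m.neglog10_p[0, 0] > 10
        assert m.neglog10_p[-2, -2] > 10


class TestQuadrants:
    def test_concordant_lists_fill_uu_dd(self):
        genes = np.array([f"g{i}" for i in range(10)])
        vals = np.array([5.0, 4, 3, 2, 1, -1, -2, -3, -4, -5])
        l1 = sg.RankedList(genes, vals)
        part = sg.extract_quadrants(l1, l1)
        assert part.ud == frozenset() and part.du == frozenset()
        assert part.uu | part.dd == set(genes)

    def test_negating_one_list_swaps_quadrants(self):
        rng = np.random.default_rng(6)
        genes = np.array([f"g{i:03d}" for i in range(100)])
        v1 = rng.normal(0, 1, 100)
        v2 = rng.normal(0, 1, 100)
        l1 = _ranked_from_values(genes, v1)
        l2 = _ranked_from_values(genes, v2)
        l2n = _ranked_from_values(genes, -v2)
        a = sg.extract_quadrants(l1, l2)
        b = sg.extract_quadrants(l1, l2n)
        assert a.uu == b.ud and a.dd == b.du and a.ud == b.uu and a.du == b.dd

    def test_matches_per_gene_sign_scan(self):
        rng = np.random.default_rng(7)
        genes = np.array([f"g{i:03d}" for i in range(500)])
        v1 = np.round(rng.normal(0, 1, 500), 1)
        v2 = np.round(rng.normal(0, 1, 500), 1)
        part = sg.extract_quadrants(
            _ranked_from_values(genes, v1), _ranked_from_values(genes, v2)
        )
        expected = {"UU": set(), "DD": set(), "UD": set(), "DU": set(), "zero": set()}
        for g, a, b in zip(genes, v1, v2):
            if a == 0 or b == 0:
                expected["zero"].add(g)
            elif a > 0 and b > 0:
                expected["UU"].add(g)
            elif a < 0 and b < 0:
                expected["DD"].add(g)
            elif a > 0:
                expected["UD"].add(g)
            else:
                expected["DU"].add(g)
        assert part.uu == expected["UU"] and part.dd == expected["DD"]
        assert part.ud == expected["UD"] and part.du == expected["DU"]
        assert part.unsigned == expected["zero"]


class TestDisplayTransforms:
    def _toy_map(self):
        genes = np.array([f"g{i:03d}" for i in range(100)])
        vals = np.arange(100, 0, -1.0) - 50.5
        l1 = sg.RankedList(genes, vals)
        return sg.build_rrho(l1, l1, step=10)

    def test_cap_clips_without_mutation(self):
        m = self._toy_map()
        m.neglog10_p[0, 0] = 450.0
        m.neglog10_p[0, 1] = 0.2
        m.neglog10_p[1, 1] = 150.0
        before = m.neglog10_p.copy()
        capped = sg.cap_for_display(m)
        assert capped[0, 0] == 300.0 and capped[0, 1] == 1.0 and capped[1, 1] == 150.0
        assert (m.neglog10_p == before).all()
        with pytest.raises(ValueError):
            sg.cap_for_display(m, max_val=1, min_val=10)

    def test_log_odds_signs_and_independence(self):
        m = self._toy_map()
        lor = sg.log_odds_map(m, cap=6)
        # k = min(i, j) on the diagonal -> strong positive association
        assert lor[0, 0] > 0
        # independence-level cell computed directly: N=100, i=j=10, k=1
        # gives odds ratio (1*81)/(9*9) = 1 -> log-odds 0
        direct = np.log((1 * 81) / (9 * 9))
        assert direct == pytest.approx(0.0, abs=0.25)
        assert (lor <= 6.0).all() and (lor >= -6.0).all()

    def test_zero_overlap_negative_log_odds(self):
        genes = np.array([f"g{i}" for i in range(20)])
        v = np.arange(20, 0, -1.0) - 10.5
        l1 = sg.RankedList(genes, v)
        l2 = sg.RankedList(genes[::-1], v.copy())  # reversed -> zero top overlap
        m = sg.build_rrho(l1, l2, step=5)
        lor = sg.log_odds_map(m)
        assert m.overlap[0, 0] == 0
        assert lor[0, 0] < 0
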