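import numpy as np
import pytest

from exactcells import (
    Collapsed2x2,
    ContingencyTable,
    collapse_cell,
    exact_cell_pvalue,
    exact_pvalue_matrix,
    exact_pvalues_all,
    hypergeom_prob,
    make_fixture,
    rejection_region,
)
from exactcells.exact_posthoc import exact_pvalue_lookup, _log_pmf_support

from golden import printed, MELANOMA_CELLS, ZEBRA_COLUMNS, exact_pvalue_oracle


class TestCollapse:
    def test_zebra_pleasure(self, zebra):
        y = collapse_cell(zebra, 0, 0)
        assert (y.x, y.a, y.b, y.d) == (139, 24, 68, 43)
        assert (y.m, y.n, y.total) == (163, 207, 274)

    def test_melanoma_h_head(self, melanoma):
        y = collapse_cell(melanoma, 0, 1)
        assert (y.x, y.a, y.b, y.d) == (22, 12, 46, 320)

    def test_2x2_is_fixed_point(self):
        t = ContingencyTable([[3, 1], [2, 4]])
        y = collapse_cell(t, 0, 0)
        assert (y.x, y.a, y.b, y.d) == (3, 1, 2, 4)

    def test_margins_of_reduction(self, melanoma):
        for i in range(4):
            for j in range(3):
                y = collapse_cell(melanoma, i, j)
                assert y.x + y.a == y.m == melanoma.row_totals[i]
                assert y.x + y.b == y.n == melanoma.col_totals[j]
                assert y.x + y.a + y.b + y.d == y.total == 400

    def test_invalid_collapsed_rejected(self):
        with pytest.raises(ValueError):
            Collapsed2x2(x=3, a=-1, b=1, d=1, m=2, n=4, total=4)


class TestHypergeomProb:
    def test_tiny_by_hand(self):
        # (2 choose 1)(2 choose 1)/(4 choose 2) = 2/3
        y = Collapsed2x2(x=1, a=1, b=1, d=1, m=2, n=2, total=4)
        assert hypergeom_prob(y) == pytest.approx(2 / 3, rel=1e-12)

    @pytest.mark.parametrize(
        "m,n,total", [(2, 2, 4), (34, 68, 400), (163, 207, 274), (50, 999, 2000)]
    )
    def test_normalizes_over_support(self, m, n, total):
        lo, logpmf = _log_pmf_support(m, n, total)
        assert np.exp(logpmf).sum() == pytest.approx(1.0, rel=1e-10)

    def test_mode_near_expectation(self):
        lo, logpmf = _log_pmf_support(34, 68, 400)
        assert lo == 0
        mode = int(np.argmax(logpmf))
        assert abs(mode - 34 * 68 / 400) <= 1  # e = 5.78


class TestExactPvalues:
    @pytest.mark.parametrize("key", sorted(MELANOMA_CELLS))
    def test_melanoma_golden(self, melanoma, key):
        i = melanoma.row_labels.index(key[0])
        j = melanoma.col_labels.index(key[1])
        v, tol = printed(MELANOMA_CELLS[key][-1])
        assert exact_cell_pvalue(melanoma, i, j).p_exact == pytest.approx(v, abs=tol)

    @pytest.mark.parametrize("activity", sorted(ZEBRA_COLUMNS))
    def test_zebra_golden_and_column_pairing(self, zebra, activity):
        j = zebra.col_labels.index(activity)
        v, tol = printed(ZEBRA_COLUMNS[activity][-1])
        p0 = exact_cell_pvalue(zebra, 0, j).p_exact
        p1 = exact_cell_pvalue(zebra, 1, j).p_exact
        assert p0 == pytest.approx(v, abs=tol)
        # in a 2-row table both cells of a column share the exact p-value
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_all_cells_matches_per_cell(self, melanoma):
        mat = exact_pvalue_matrix(melanoma)
        res = exact_pvalues_all(melanoma)
        for i in range(4):
            for j in range(3):
                single = exact_cell_pvalue(melanoma, i, j)
                assert mat[i, j] == single.p_exact == res[i, j].p_exact
                assert res[i, j].support_size == single.support_size

    def test_uniform_2x2_symmetric(self):
        t = ContingencyTable([[1, 1], [1, 1]])
        mat = exact_pvalue_matrix(t)
        assert np.allclose(mat, mat[0, 0])

    def test_degenerate_support_gives_one(self):
        # a column margin that absorbs the whole sample pins the support
        t = ContingencyTable([[5, 0], [7, 0]])  # n_1 = N = 12
        r = exact_cell_pvalue(t, 0, 0)
        assert r.support_size == 1
        assert r.p_exact == 1.0

    def test_observed_probability_bound(self, melanoma):
        # p_exact always includes the observed outcome's own probability
        for i in range(4):
            for j in range(3):
                y = collapse_cell(melanoma, i, j)
                r = exact_cell_pvalue(melanoma, i, j)
                assert r.p_exact >= hypergeom_prob(y) - 1e-13

    def test_monotone_in_deviation(self):
        # holding margins fixed, p is non-increasing as |x - e| grows
        for m, n, total in [(10, 14, 30), (34, 68, 400), (163, 30, 274)]:
            lo, p = exact_pvalue_lookup(m, n, total)
            x = np.arange(lo, lo + p.size)
            dev = np.abs(x * total - m * n)
            order = np.argsort(dev, kind="stable")
            assert (np.diff(p[order]) <= 1e-12).all()

    def test_oracle_agreement_small_tables(self, rng):
        for _ in range(40):
            total = int(rng.integers(4, 41))
            m = int(rng.integers(1, total))
            n = int(rng.integers(1, total))
            lo, hi = max(0, m + n - total), min(m, n)
            x = int(rng.integers(lo, hi + 1))
            lo_, p = exact_pvalue_lookup(m, n, total)
            want = float(exact_pvalue_oracle(m, n, total, x))
            assert p[x - lo_] == pytest.approx(want, abs=1e-12)

    def test_conditional_validity_exhaustive(self):
        # P(p <= alpha) <= alpha under the hypergeometric null, summed
        # exactly over the support for a grid of margins
        alphas = [0.01, 0.05, 0.1, 0.25, 0.5]
        for m, n, total in [(3, 5, 10), (10, 10, 20), (7, 19, 40), (25, 30, 60)]:
            lo, p = exact_pvalue_lookup(m, n, total)
            _, logpmf = _log_pmf_support(m, n, total)
            pmf = np.exp(logpmf)
            pmf /= pmf.sum()
            for a in alphas:
                assert pmf[p <= a].sum() <= a + 1e-12


class TestOrderingInvariance:
    """The three residual orderings induce one rejection region."""

    def test_regions_identical_on_references(self, zebra, melanoma):
        for table in (zebra, melanoma):
            R, C = table.shape
            for i in range(R):
                for j in range(C):
                    y = collapse_cell(table, i, j)
                    r_raw = rejection_region(y, "raw")
                    assert r_raw == rejection_region(y, "std")
                    assert r_raw == rejection_region(y, "adj")

    def test_region_matches_integer_deviation_rule(self, melanoma):
        for i in range(4):
            for j in range(3):
                y = collapse_cell(melanoma, i, j)
                lo, hi = y.support
                obs = abs(y.x * y.total - y.m * y.n)
                expected = {
                    x for x in range(lo, hi + 1)
                    if abs(x * y.total - y.m * y.n) >= obs
                }
                assert rejection_region(y, "raw") == expected
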