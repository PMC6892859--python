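"""The 2x2 enrichment core: table construction, fold, CI, Fisher, FDR.

The Fisher implementation is checked against two independent routes: an
exhaustive enumeration oracle in exact rational arithmetic, and
scipy.stats.fisher_exact.
"""

from fractions import Fraction
from math import comb

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from genoverlap.enrichment import (
    ContingencyTable,
    apply_haldane,
    bh_fdr,
    enrichment_result,
    fisher_two_sided,
    fold_enrichment,
    katz_ci,
    make_table,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals.

    Enumerates every table with the observed margins, computes each point
    probability as an exact Fraction, and sums those not exceeding the
    observed probability.  Independent of the log-space implementation.
    """
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    obs = Fraction(comb(row1, a) * comb(row2, c), denom)
    total = Fraction(0)
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        pk = Fraction(comb(row1, k) * comb(row2, col1 - k), denom)
        if pk <= obs:
            total += pk
    return float(total)


class TestMakeTable:
    def test_suicide_cag_cells(self):
        t = make_table(65, 590, 1375, 20479)
        assert t.cells == (65, 525, 1310, 18579)

    def test_zero_overlap_cells(self):
        t = make_table(0, 36, 724, 20479)
        assert t.cells == (0, 36, 724, 19719)

    def test_negative_derived_cell_is_fatal(self):
        with pytest.raises(ValueError, match="cell b"):
            make_table(10, 5, 100, 1000)

    def test_non_integer_inputs_rejected(self):
        with pytest.raises(TypeError):
            make_table(1.5, 10, 10, 100)

    def test_cells_partition_the_genome(self):
        t = make_table(7, 31, 3800, 20479)
        assert sum(t.cells) == 20479


class TestHaldane:
    def test_no_zero_cell_passes_through(self):
        t = make_table(65, 590, 1375, 20479)
        cells, applied = apply_haldane(t)
        assert cells == (65.0, 525.0, 1310.0, 18579.0)
        assert not applied

    @pytest.mark.parametrize(
        "n1, z, n2, expected",
        [
            (0, 36, 724, (0.5, 36.5, 724.5, 19719.5)),
            (0, 31, 724, (0.5, 31.5, 724.5, 19724.5)),
        ],
    )
    def test_zero_cell_adds_half_everywhere(self, n1, z, n2, expected):
        cells, applied = apply_haldane(make_table(n1, z, n2, 20479))
        assert cells == expected
        assert applied


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "n1, z, n2, expected",
        [
            (65, 590, 1375, 1.641),
            (122, 590, 1660, 2.551),
            (0, 36, 724, 0.382),
            (0, 31, 724, 0.442),
        ],
    )
    def test_published_values(self, n1, z, n2, expected):
        assert round(fold_enrichment(make_table(n1, z, n2, 20479)), 3) == expected

    def test_observed_equals_expected_gives_unity(self):
        assert fold_enrichment(make_table(10, 100, 100, 1000)) == pytest.approx(1.0)

    def test_closed_form_without_correction(self):
        t = make_table(20, 225, 1375, 20479)
        assert fold_enrichment(t) == pytest.approx(20 * 20479 / (225 * 1375))

    def test_strictly_increasing_in_overlap(self):
        folds = [fold_enrichment(make_table(n1, 100, 200, 5000)) for n1 in range(0, 60)]
        assert all(x < y for x, y in zip(folds, folds[1:]))

    def test_symmetry_of_list_and_reference_sizes(self):
        f1 = fold_enrichment(make_table(5, 50, 80, 2000))
        f2 = fold_enrichment(make_table(5, 80, 50, 2000))
        assert f1 == pytest.approx(f2)


class TestKatzCI:
    @pytest.mark.parametrize(
        "n1, z, n2, lo, hi",
        [
            (65, 590, 1375, 1.297, 2.075),
            (11, 36, 3800, 1.005, 2.697),
            (0, 31, 724, 0.028, 6.916),
        ],
    )
    def test_published_bounds(self, n1, z, n2, lo, hi):
        low, high = katz_ci(make_table(n1, z, n2, 20479))
        assert low == pytest.approx(lo, abs=2e-3)
        assert high == pytest.approx(hi, abs=2e-3)

    def test_interval_brackets_the_fold(self):
        t = make_table(17, 225, 1037, 20479)
        low, high = katz_ci(t)
        assert low <= fold_enrichment(t) <= high

    def test_width_shrinks_under_scaling(self):
        widths = []
        for scale in (1, 4, 16, 64):
            t = make_table(8 * scale, 100 * scale, 200 * scale, 5000 * scale)
            low, high = katz_ci(t)
            widths.append(high - low)
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))


class TestFisherTwoSided:
    def test_balanced_table_gives_one(self):
        t = ContingencyTable(n1=5, z=10, n2=10, G=20)  # cells (5,5,5,5)
        assert fisher_two_sided(t) == pytest.approx(1.0)

    def test_small_table_matches_enumeration_oracle(self):
        # margins (10, 10; 5, 15): six possible tables
        t = ContingencyTable(n1=3, z=10, n2=5, G=20)  # cells (3,7,2,8)
        assert fisher_two_sided(t) == pytest.approx(fisher_oracle(3, 7, 2, 8), rel=1e-12)

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_matches_oracle_on_tables_with_margins_up_to_60(self, a, b, c, d):
        assume(a + b + c + d > 0)
        t = ContingencyTable(n1=a, z=a + b, n2=a + c, G=a + b + c + d)
        assert fisher_two_sided(t) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-12)

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    def test_invariant_under_transposition(self, a, b, c, d):
        assume(a + b + c + d > 0)
        t = ContingencyTable(n1=a, z=a + b, n2=a + c, G=a + b + c + d)
        tt = ContingencyTable(n1=a, z=a + c, n2=a + b, G=a + b + c + d)
        assert fisher_two_sided(t) == pytest.approx(fisher_two_sided(tt), rel=1e-10)

    def test_matches_scipy_at_genome_scale(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        t = make_table(65, 590, 1375, 20479)
        expected = scipy_stats.fisher_exact([[65, 525], [1310, 18579]]).pvalue
        assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-9)


class TestBhFdr:
    def test_single_value_identity(self):
        assert bh_fdr([0.04]) == [0.04]

    def test_hand_executed_step_up(self):
        # q_i = min_{j>=i} p_j * m / j: all four collapse to 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_are_symmetric(self):
        assert bh_fdr([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_out_of_range_input_is_fatal(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_values_dominate_raw_and_stay_capped(self, p_values):
        q = bh_fdr(p_values)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p_values))
        assert all(qi <= 1.0 + 1e-12 for qi in q)
        # monotone non-decreasing when sorted by raw p
        order = sorted(range(len(p_values)), key=lambda i: p_values[i])
        ranked = [q[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(ranked, ranked[1:]))


class TestEnrichmentResult:
    def test_composes_all_statistics(self):
        r = enrichment_result(make_table(65, 590, 1375, 20479))
        assert round(r.fold, 3) == 1.641
        assert r.ci_low < r.fold < r.ci_high
        assert not r.haldane_applied
        assert f"{r.p_fisher:.3g}" == "7.83e-05"

    def test_flags_continuity_correction(self):
        r = enrichment_result(make_table(0, 31, 724, 20479))
        assert r.haldane_applied
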