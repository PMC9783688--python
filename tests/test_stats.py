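import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from orthonod import (
    ContingencyTable,
    OrthogroupCountMatrix,
    PanelError,
    SpeciesPanel,
    SpeciesRecord,
    TestConfig,
    bonferroni_adjust,
    fisher_exact_two_sided,
    normalize_counts,
    presence_table,
    run_differential_representation,
    sample_odds_ratio,
    t_test_independent,
)

from oracles import fisher_two_sided_exact


def random_table(rng) -> ContingencyTable:
    n = int(rng.integers(2, 31))
    a = int(rng.integers(0, n + 1))
    b = int(rng.integers(0, n - a + 1))
    c = int(rng.integers(0, n - a - b + 1))
    return ContingencyTable(a, b, c, n - a - b - c)


class TestSampleOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((30, 5, 6, 33), 33.0),
            ((11, 24, 38, 1), 11 / 912),
            ((0, 35, 23, 16), 0.0),
            ((3, 0, 2, 4), math.inf),
        ],
    )
    def test_zero_product_conventions_and_values(self, cells, expected):
        assert sample_odds_ratio(ContingencyTable(*cells)) == pytest.approx(expected)

    def test_both_products_zero_is_undefined(self):
        assert math.isnan(sample_odds_ratio(ContingencyTable(0, 3, 0, 4)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_swap_symmetries(self, seed):
        t = random_table(np.random.default_rng(seed))
        orig = sample_odds_ratio(t)
        # simultaneous row+column swap leaves the OR unchanged
        both = sample_odds_ratio(ContingencyTable(t.d, t.c, t.b, t.a))
        # swapping only the groups inverts it (0 <-> inf)
        grp = sample_odds_ratio(t.swapped_groups())
        if math.isnan(orig):
            assert math.isnan(both) and math.isnan(grp)
        else:
            assert both == pytest.approx(orig)
            if orig == 0.0:
                assert grp == math.inf
            elif orig == math.inf:
                assert grp == 0.0
            else:
                assert grp == pytest.approx(1.0 / orig)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_a(self, seed):
        t = random_table(np.random.default_rng(seed))
        bumped = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        lo, hi = sample_odds_ratio(t), sample_odds_ratio(bumped)
        if not (math.isnan(lo) or math.isnan(hi)):
            assert hi >= lo


class TestFisherExact:
    def test_symmetric_table_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_perfect_separation_five_vs_five(self):
        # margins (5,5;5,5): the two extreme tables each have probability 1/252
        p = fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_degenerate_margins_return_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exact_enumeration_and_scipy(self, seed):
        t = random_table(np.random.default_rng(seed))
        if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
            return
        mine = fisher_exact_two_sided(t)
        oracle = fisher_two_sided_exact(t.a, t.b, t.c, t.d)
        assert mine == pytest.approx(oracle, rel=1e-9)
        scipy_p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
        assert mine == pytest.approx(scipy_p, rel=1e-6)


class TestTTest:
    def test_identical_vectors_give_null_result(self):
        assert t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (
            pytest.approx(0.0),
            pytest.approx(1.0),
        )

    def test_pooled_closed_form(self):
        # means 2 vs 5, pooled variance 1, se = sqrt(2/3), df = 4
        t, p = t_test_independent([1, 2, 3], [4, 5, 6], "pooled")
        assert t == pytest.approx(-3 / math.sqrt(2 / 3))
        assert p == pytest.approx(2 * sps.t.sf(3 / math.sqrt(2 / 3), df=4))

    def test_sign_convention_positive_means_first_sample_larger(self):
        t, _ = t_test_independent([5, 6, 7], [1, 2, 3])
        assert t > 0

    def test_constant_equal_samples(self):
        assert t_test_independent([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_independent([1.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["pooled", "welch"]))
    def test_swapping_samples_negates_t_and_preserves_p(self, seed, variant):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 10))
        y = rng.normal(size=rng.integers(2, 10))
        t1, p1 = t_test_independent(x, y, variant)
        t2, p2 = t_test_independent(y, x, variant)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.001, 10, 0.01), (0.5, 10, 1.0)])
    def test_examples(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.integers(1, 10_000), st.floats(1e-6, 0.5))
    def test_adjusted_significance_equals_raw_at_alpha_over_m(self, p, m, alpha):
        adj = bonferroni_adjust(p, m)
        assert adj >= p
        assert adj <= 1.0
        if abs(p * m - alpha) > 1e-9 * alpha:  # off the float-rounding boundary
            assert (adj < alpha) == (p * m < alpha)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 100), st.integers(1, 100))
    def test_monotone_in_p_and_m(self, p1, p2, m1, m2):
        lo_p, hi_p = sorted([p1, p2])
        lo_m, hi_m = sorted([m1, m2])
        assert bonferroni_adjust(lo_p, lo_m) <= bonferroni_adjust(hi_p, lo_m)
        assert bonferroni_adjust(lo_p, lo_m) <= bonferroni_adjust(lo_p, hi_m)


def _toy_inputs():
    records = [
        SpeciesRecord(f"nod{i}", order_label="Fabales", nodulation_status="nodulating")
        for i in range(4)
    ] + [
        SpeciesRecord(f"non{i}", nodulation_status="non_nodulating") for i in range(4)
    ] + [SpeciesRecord("mys", nodulation_status="unknown")]
    panel = SpeciesPanel(records)
    cols = [r.species_id for r in records]
    df = pd.DataFrame(
        {
            "OG1": [2, 0, 1, 0, 0, 0, 0, 0, 5],
            "OG2": [1, 1, 1, 1, 1, 1, 1, 1, 1],
        },
        index=cols,
    ).T
    return OrthogroupCountMatrix(df, pd.Series(40, index=cols)), panel


class TestPresenceTable:
    def test_counts_present_and_absent_per_group(self):
        matrix, panel = _toy_inputs()
        t = presence_table(matrix, panel, "OG1", "Viridiplantae")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 0, 4)

    def test_unknown_status_species_never_counted(self):
        matrix, panel = _toy_inputs()
        # 'mys' has 5 copies of OG1 but belongs to no group
        t = presence_table(matrix, panel, "OG1", "Fabales")
        assert t.n == 8

    def test_presence_threshold_applies(self):
        matrix, panel = _toy_inputs()
        t = presence_table(
            matrix, panel, "OG1", "Viridiplantae", TestConfig(presence_threshold=2)
        )
        assert (t.a, t.b) == (1, 3)

    def test_all_unknown_panel_is_an_error(self):
        matrix, _ = _toy_inputs()
        panel = SpeciesPanel(
            [SpeciesRecord(s, nodulation_status="unknown") for s in matrix.species_ids]
        )
        with pytest.raises(PanelError, match="empty"):
            presence_table(matrix, panel, "OG1", "Viridiplantae")


class TestNormalizeCounts:
    def test_cellwise_ratio(self):
        matrix, _ = _toy_inputs()
        norm = normalize_counts(matrix)
        assert norm.loc["OG1", "nod0"] == pytest.approx(2 / 40)
        assert norm.loc["OG1", "nod1"] == 0.0
        assert ((norm >= 0) & (norm <= 1)).all().all()

    def test_column_sums_equal_assigned_fraction(self):
        matrix, _ = _toy_inputs()
        norm = normalize_counts(matrix)
        expected = matrix.counts.sum(axis=0) / matrix.species_totals
        pd.testing.assert_series_equal(norm.sum(axis=0), expected)
        assert (expected <= 1).all()


class TestRunDifferentialRepresentation:
    def test_identical_columns_yield_no_significant_results(self):
        cols = [f"nod{i}" for i in range(3)] + [f"non{i}" for i in range(3)]
        records = [
            SpeciesRecord(c, order_label="Fabales",
                          nodulation_status="nodulating" if c.startswith("nod")
                          else "non_nodulating")
            for c in cols
        ]
        panel = SpeciesPanel(records)
        df = pd.DataFrame(
            np.tile([[3], [1], [2]], (1, 6)), index=["OG1", "OG2", "OG3"], columns=cols
        )
        matrix = OrthogroupCountMatrix(df, pd.Series(50, index=cols))
        results = run_differential_representation(matrix, panel)
        assert results
        assert not any(r.significant_presence or r.significant_count for r in results)

    def test_extreme_planted_absence_is_recovered_as_under_represented(self):
        n1, n2 = 10, 10
        cols = [f"nod{i}" for i in range(n1)] + [f"non{i}" for i in range(n2)]
        records = [
            SpeciesRecord(c, order_label="Fabales",
                          nodulation_status="nodulating" if c.startswith("nod")
                          else "non_nodulating")
            for c in cols
        ]
        panel = SpeciesPanel(records)
        rows = {f"BG{i}": [1] * (n1 + n2) for i in range(8)}
        rows["LOST"] = [0] * n1 + [2] * n2
        df = pd.DataFrame(rows, index=cols).T
        matrix = OrthogroupCountMatrix(df, pd.Series(100, index=cols))
        # raw two-sided p for (0,10,10,0) is 2/C(20,10) = 1.08e-5; with m = 9
        # tests the adjusted p 9.7e-5 clears alpha = 0.001 (oracle-checked)
        assert fisher_two_sided_exact(0, 10, 10, 0) * 9 < 1e-3
        results = run_differential_representation(matrix, panel)
        hits = [r for r in results if r.significant_presence]
        assert {r.orthogroup_id for r in hits} == {"LOST"}
        assert all(r.direction == "under_represented" for r in hits)

    def test_direction_agrees_with_odds_ratio_on_balanced_groups(self, default_run):
        *_, results = default_run
        for r in results:
            if r.significant_presence and not math.isnan(r.odds_ratio):
                if r.odds_ratio < 1:
                    assert r.direction == "under_represented"

    def test_adjusted_p_dominates_raw(self, default_run):
        *_, results = default_run
        for r in results[:200]:
            assert r.fisher_p_adj >= r.fisher_p_raw - 1e-15
            assert r.t_p_adj >= r.t_p_raw - 1e-15
            assert r.fisher_p_adj <= 1.0 and r.t_p_adj <= 1.0

    def test_presence_significant_set_within_union_of_tracks(self, default_run):
        *_, results = default_run
        pres = {r.orthogroup_id for r in results if r.significant_presence}
        either = {
            r.orthogroup_id
            for r in results
            if r.significant_presence or r.significant_count
        }
        assert pres <= either
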