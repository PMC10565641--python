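import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from degscan.stats import (TwoByTwo, bh_fdr, fisher_exact_2x2, hypergeom_point,
                           hypergeom_upper_tail, odds_ratio, ora,
                           proportion_percent)


# ----------------------------------------------------------------------
# hypergeometric upper tail
# ----------------------------------------------------------------------

def test_hypergeom_exact_rational_value():
    # C(5,3)C(15,1) + C(5,4)C(15,0) over C(20,4) = 155/4845
    assert hypergeom_upper_tail(3, 5, 4, 20) == pytest.approx(155 / 4845, rel=1e-12)


def test_hypergeom_trivial_tails():
    assert hypergeom_upper_tail(0, 5, 4, 20) == 1.0
    assert hypergeom_upper_tail(5, 5, 5, 5) == 1.0  # certainty: all draws succeed


def test_hypergeom_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        hypergeom_upper_tail(6, 5, 4, 20)
    with pytest.raises(ValueError):
        hypergeom_upper_tail(1, 25, 4, 20)


@pytest.mark.parametrize("seed", range(5))
def test_hypergeom_agrees_with_scipy_survival_function(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        N = int(rng.integers(2, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        ours = hypergeom_upper_tail(k, K, n, N)
        ref = scipy.stats.hypergeom.sf(k - 1, N, K, n)
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_hypergeom_log_space_path_for_large_population():
    # N > 10,000 exercises the log-gamma branch
    ours = hypergeom_upper_tail(40, 500, 1000, 20_000)
    ref = scipy.stats.hypergeom.sf(39, 20_000, 500, 1000)
    assert ours == pytest.approx(ref, rel=1e-9)


def test_hypergeom_monte_carlo_calibration():
    rng = np.random.default_rng(42)
    for _ in range(5):
        N = int(rng.integers(20, 200))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(0, min(K, n) + 1))
        draws = rng.hypergeometric(K, N - K, n, size=100_000)
        est = (draws >= k).mean()
        p = hypergeom_upper_tail(k, K, n, N)
        se = math.sqrt(max(p * (1 - p), 1e-12) / 100_000)
        assert abs(est - p) <= 3 * se + 1e-9


def test_hypergeom_point_sums_to_tail():
    total = sum(hypergeom_point(j, 5, 4, 20) for j in range(3, 5))
    assert total == pytest.approx(hypergeom_upper_tail(3, 5, 4, 20), rel=1e-12)


# ----------------------------------------------------------------------
# Benjamini-Hochberg
# ----------------------------------------------------------------------

def test_bh_hand_computed_step_up():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_equal_and_single_p():
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert bh_fdr([0.07]) == pytest.approx([0.07])
    assert bh_fdr([]) == []


def test_bh_out_of_range_rejected():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@pytest.mark.parametrize("seed", range(5))
def test_bh_matches_statsmodels(seed):
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(seed)
    p = rng.random(30)
    ours = bh_fdr(list(p))
    ref = statsmodels.multipletests(p, method="fdr_bh")[1]
    assert ours == pytest.approx(list(ref), rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_monotone_in_p_rank(p_values):
    q = bh_fdr(p_values)
    order = sorted(range(len(p_values)), key=lambda i: p_values[i])
    sorted_q = [q[i] for i in order]
    assert all(a <= b + 1e-12 for a, b in zip(sorted_q, sorted_q[1:]))
    assert all(0 <= x <= 1 for x in q)


# ----------------------------------------------------------------------
# overrepresentation
# ----------------------------------------------------------------------

def _toy_universe():
    return [f"G{i}" for i in range(20)]


def test_ora_worked_example():
    universe = _toy_universe()
    sets = {"S1": universe[:5]}
    candidates = universe[2:6]  # overlap = genes 2,3,4 -> k=3
    (row,) = ora(candidates, sets, universe)
    assert (row.k, row.K, row.n, row.N) == (3, 5, 4, 20)
    assert row.p_value == pytest.approx(155 / 4845, rel=1e-12)
    assert row.fold_enrichment == pytest.approx(3.0)
    assert row.q_value == row.p_value  # single set


def test_ora_disjoint_set_p_is_one():
    universe = _toy_universe()
    (row,) = ora(universe[:4], {"S": universe[10:15]}, universe)
    assert row.k == 0 and row.p_value == 1.0


def test_ora_candidates_outside_universe_dropped(caplog):
    import logging

    universe = _toy_universe()
    with caplog.at_level(logging.WARNING, logger="degscan.stats"):
        (row,) = ora(universe[:3] + ["ALIEN"], {"S": universe[:5]}, universe)
    assert row.n == 3
    assert "outside the universe" in caplog.text


def test_ora_set_members_intersected_with_universe():
    universe = _toy_universe()
    (row,) = ora(universe[:4], {"S": universe[:5] + ["ALIEN1", "ALIEN2"]}, universe)
    assert row.K == 5


def test_ora_ordering_invariance():
    rng = np.random.default_rng(7)
    universe = _toy_universe()
    sets = {"A": universe[:5], "B": universe[5:12]}
    cand = universe[2:6]
    base = ora(cand, sets, universe)
    shuffled = ora(
        list(rng.permutation(cand)), sets, list(rng.permutation(universe))
    )
    assert [(r.set_name, r.p_value) for r in base] == [
        (r.set_name, r.p_value) for r in shuffled
    ]


def test_ora_sorted_by_p_then_name():
    universe = _toy_universe()
    sets = {"B": universe[10:15], "A": universe[15:20], "HIT": universe[:5]}
    rows = ora(universe[:4], sets, universe)
    assert [r.set_name for r in rows] == ["HIT", "A", "B"]


def test_ora_empty_universe_rejected():
    with pytest.raises(ValueError):
        ora(["A"], {"S": ["A"]}, [])


# ----------------------------------------------------------------------
# 2x2 tables
# ----------------------------------------------------------------------

def test_fisher_symmetric_table_is_one():
    assert fisher_exact_2x2(TwoByTwo(1, 1, 1, 1)) == 1.0


def test_fisher_reference_table_matches_scipy():
    ours = fisher_exact_2x2(TwoByTwo(8, 3, 1, 9))
    ref = scipy.stats.fisher_exact([[8, 3], [1, 9]])[1]
    assert ours == pytest.approx(ref, rel=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_fisher_matches_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if a + b + c + d == 0:
            continue
        ours = fisher_exact_2x2(TwoByTwo(a, b, c, d))
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_invariant_under_row_and_column_swap():
    t = TwoByTwo(8, 3, 1, 9)
    swapped = TwoByTwo(9, 1, 3, 8)  # both rows and columns reversed
    assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped), rel=1e-12)


def test_odds_ratio_values():
    assert odds_ratio(TwoByTwo(10, 5, 2, 8)) == pytest.approx(8.0)
    assert odds_ratio(TwoByTwo(5, 5, 5, 5)) == pytest.approx(1.0)


def test_odds_ratio_haldane_correction():
    assert odds_ratio(TwoByTwo(3, 0, 2, 4), haldane=True) == pytest.approx(12.6)


def test_odds_ratio_zero_denominator_flagged():
    with pytest.raises(ZeroDivisionError):
        odds_ratio(TwoByTwo(3, 0, 2, 4))


def test_two_by_two_validation():
    with pytest.raises(ValueError):
        TwoByTwo(-1, 0, 0, 1)
    with pytest.raises(ValueError):
        TwoByTwo(0, 0, 0, 0)


# ----------------------------------------------------------------------
# proportions
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "count, total, expected",
    [(146, 184, 79.3), (20, 33, 60.6), (8, 11, 72.7), (0, 7, 0.0)],
)
def test_proportion_percent_reported_values(count, total, expected):
    assert proportion_percent(count, total, 1) == expected


def test_proportion_rounds_half_up():
    # 1.25% would round to 1.2 under banker's rounding
    assert proportion_percent(5, 400, 1) == 1.3
    assert proportion_percent(1, 8, 0) == 13.0


def test_proportion_argument_validation():
    with pytest.raises(ValueError):
        proportion_percent(5, 0)
    with pytest.raises(ValueError):
        proportion_percent(5, 4)
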