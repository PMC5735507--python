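"""Summary statistics and significance tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import wellpat as wp
from wellpat.errors import DegenerateVarianceError, UndefinedStatisticError


def _assignment(locations, in_sampled=None, well_ids=None):
    n = len(locations)
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(n),
            "well_id": np.zeros(n, dtype=int) if well_ids is None else well_ids,
            "distance_um": np.zeros(n),
            "location": locations,
            "in_sampled_set": np.ones(n, dtype=bool) if in_sampled is None else in_sampled,
        }
    )


# ---------------------------------------------------------------- efficiency


def test_localization_efficiency_arithmetic():
    asg = _assignment(["interior"] * 9 + ["exterior"])
    assert wp.localization_efficiency(asg) == pytest.approx(90.0)
    assert wp.localization_efficiency(_assignment(["interior"] * 5)) == 100.0


def test_localization_efficiency_excludes_out_of_sample_rows():
    asg = _assignment(
        ["interior", "interior", "exterior", "interior"],
        in_sampled=[True, True, True, False],
    )
    assert wp.localization_efficiency(asg) == pytest.approx(100 * 2 / 3)


def test_localization_efficiency_undefined_for_no_nuclei():
    with pytest.raises(UndefinedStatisticError):
        wp.localization_efficiency(_assignment([]))


# ----------------------------------------------------------------- viability


def test_viability_arithmetic_and_complement():
    alive = _assignment(["interior"] * 100)
    dead = _assignment(["interior"] * 4)
    v = wp.viability(alive, dead)
    assert v == pytest.approx(96.0)
    dead_pct = 100.0 - v
    assert v + dead_pct == 100.0
    assert wp.viability(alive, _assignment([])) == 100.0


def test_viability_restriction_to_interior():
    alive = _assignment(["interior"] * 10 + ["exterior"] * 10)
    dead = _assignment(["interior"] * 1 + ["exterior"] * 9)
    assert wp.viability(alive, dead, restrict_to_interior=True) == pytest.approx(90.0)
    assert wp.viability(alive, dead, restrict_to_interior=False) == pytest.approx(50.0)


def test_viability_undefined_for_zero_total():
    with pytest.raises(UndefinedStatisticError):
        wp.viability(_assignment([]), _assignment([]))


# ----------------------------------------------------------------- occupancy


def test_occupancy_all_empty_wells():
    counts, single = wp.occupancy_distribution(_assignment([]), np.arange(400))
    assert counts == {0: 400, 1: 0, 2: 0, 3: 0, 4: 0}
    assert single == 0.0


def test_occupancy_binning_and_single_cell_percentage():
    # wells: 0 -> 1 cell, 1 -> 2 cells, 2 -> 5 cells (open 4+ bin), 3 -> empty
    locs = ["interior"] * 8
    wells = [0, 1, 1, 2, 2, 2, 2, 2]
    asg = _assignment(locs, well_ids=wells)
    counts, single = wp.occupancy_distribution(asg, np.arange(4))
    assert counts == {0: 1, 1: 1, 2: 1, 3: 0, 4: 1}
    assert sum(counts.values()) == 4
    assert single == pytest.approx(25.0)


def test_occupancy_counts_interior_only():
    asg = _assignment(["interior", "exterior"], well_ids=[0, 0])
    counts, _ = wp.occupancy_distribution(asg, np.arange(2))
    assert counts == {0: 1, 1: 1, 2: 0, 3: 0, 4: 0}


def test_occupancy_percentages_sum_to_100():
    summary = wp.PatterningSummary(
        condition="x",
        n_wells_sampled=4,
        n_cells_total=8,
        n_cells_interior=8,
        localization_efficiency_pct=100.0,
        n_dead=0,
        viability_pct=100.0,
        occupancy_counts={0: 1, 1: 1, 2: 1, 3: 0, 4: 1},
    )
    assert sum(summary.occupancy_percentages().values()) == pytest.approx(100.0)


# ------------------------------------------------------------- fold increase


def test_fold_increase_examples():
    assert wp.fold_increase([92, 92, 92, 92], [23, 23, 23, 23]) == pytest.approx(4.0)
    assert wp.fold_increase([81, 77, 85], [81, 77, 85]) == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(c=st.floats(0.01, 100.0))
def test_fold_increase_scale_invariant(c):
    a = np.array([90.0, 80.0, 70.0, 60.0])
    b = np.array([30.0, 20.0, 35.0, 15.0])
    assert wp.fold_increase(c * a, c * b) == pytest.approx(wp.fold_increase(a, b))


def test_fold_increase_zero_control_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        wp.fold_increase([90.0, 90.0], [0.0, 30.0])


# ----------------------------------------------------------------- t-test


def test_students_t_null_identity():
    r = wp.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_students_t_separation():
    r = wp.students_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert r.p_value < 0.001


def test_students_t_matches_direct_formula_and_scipy():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1.3, 7)
    r = wp.students_t(a, b)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t_manual = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert r.statistic == pytest.approx(t_manual, rel=1e-12)
    t_sp, p_sp = sps.ttest_ind(a, b, equal_var=True)
    assert r.statistic == pytest.approx(t_sp, rel=1e-12)
    assert r.p_value == pytest.approx(p_sp, rel=1e-12)


def test_students_t_degenerate_variance():
    with pytest.raises(DegenerateVarianceError):
        wp.students_t([2.0, 2.0, 2.0], [2.0, 2.0])
    with pytest.raises(UndefinedStatisticError):
        wp.students_t([1.0], [2.0, 3.0])


# ------------------------------------------------------------- Mann-Whitney


def test_mann_whitney_exact_small_case():
    r = wp.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(2.0 / 6.0)


def test_mann_whitney_identical_multisets():
    a = [1.0, 2.0, 3.0, 4.0]
    r = wp.mann_whitney_u(a, a)
    assert r.statistic == pytest.approx(len(a) ** 2 / 2.0)
    assert r.p_value == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_exact_agrees_with_independent_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(5):
        a = rng.normal(size=5)
        b = rng.normal(size=5) + rng.uniform(-1, 1)
        r = wp.mann_whitney_u(a, b)
        # enumeration oracle, written independently of the implementation
        n1, n2 = len(a), len(b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        u_obs = min(
            ranks[:n1].sum() - n1 * (n1 + 1) / 2,
            ranks[n1:].sum() - n2 * (n2 + 1) / 2,
        )
        hits = total = 0
        for combo in combinations(range(1, n1 + n2 + 1), n1):
            u1 = sum(combo) - n1 * (n1 + 1) / 2
            total += 1
            hits += min(u1, n1 * n2 - u1) <= u_obs + 1e-12
        assert r.p_value == pytest.approx(hits / total, abs=1e-12)


def test_mann_whitney_matches_scipy_exact():
    rng = np.random.default_rng(19)
    a, b = rng.normal(size=6), rng.normal(size=6) + 0.8
    r = wp.mann_whitney_u(a, b)
    sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert r.p_value == pytest.approx(sp.pvalue, rel=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    seed=st.integers(0, 5000),
    n1=st.integers(1, 8),
    n2=st.integers(1, 8),
)
def test_mann_whitney_p_in_unit_interval_and_u_bounds(seed, n1, n2):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n1)
    b = rng.normal(size=n2)
    r = wp.mann_whitney_u(a, b)
    assert 0.0 <= r.p_value <= 1.0
    assert 0.0 <= r.statistic <= n1 * n2


def test_mann_whitney_exact_vs_approximation_within_tolerance():
    # overlap regime: n1 = n2 = 6 is exact; the continuity-corrected
    # normal approximation tracks it to ~0.015 in the worst case
    rng = np.random.default_rng(29)
    diffs = []
    for _ in range(50):
        a = rng.normal(size=6)
        b = rng.normal(size=6) + rng.uniform(0, 1.5)
        r = wp.mann_whitney_u(a, b)
        mu = 18.0
        var = 6 * 6 * 13 / 12.0
        approx = min(1.0, 2.0 * sps.norm.cdf((r.statistic - mu + 0.5) / math.sqrt(var)))
        diffs.append(abs(r.p_value - approx))
    assert max(diffs) < 0.02
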