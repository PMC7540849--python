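"""Smoothing-spline trait extraction: oracles and invariants.

The independent smoother oracle builds the natural cubic interpolation
basis with scipy's CubicSpline (unit-vector interpolants), assembles the
curvature penalty from exact integrals of the piecewise-linear second
derivatives, and solves the df equation by bisection — a construction
disjoint from the banded second-difference formulation under test.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline

from pasturepheno.set_smoothing import (
    PsaSeries,
    aggregate_psa,
    aggregate_psa_table,
    extract_traits,
    natural_spline_penalty,
    smooth_psa,
    smooth_table,
    solve_lambda_for_df,
    smoother_matrix,
    traits_table,
    validate_proxy,
)


# ---------------------------------------------------------------- oracle

def oracle_penalty(x):
    n = len(x)
    M = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        M[:, j] = CubicSpline(x, e, bc_type="natural")(x, 2)
    h = np.diff(x)
    Om = np.zeros((n, n))
    for i in range(n - 1):
        a0, a1 = M[i, :], M[i + 1, :]
        Om += h[i] / 6.0 * (
            2 * np.outer(a0, a0) + np.outer(a0, a1) + np.outer(a1, a0) + 2 * np.outer(a1, a1)
        )
    return Om


def oracle_smooth(x, y, df, tol=1e-10):
    Om = oracle_penalty(x)
    n = len(x)

    def trace(lam):
        return np.trace(np.linalg.inv(np.eye(n) + lam * Om))

    lo, hi = 1e-12, 1e12
    while hi / lo > 1 + 1e-14:
        mid = np.sqrt(lo * hi)
        if trace(mid) > df:
            lo = mid
        else:
            hi = mid
        if abs(trace(mid) - df) < tol:
            break
    lam = np.sqrt(lo * hi)
    return np.linalg.solve(np.eye(n) + lam * Om, y)


# ---------------------------------------------------------------- smoother

def test_penalty_matrix_matches_basis_construction():
    x = np.array([0.0, 1.0, 2.5, 3.0, 4.7, 6.0])
    assert np.allclose(natural_spline_penalty(x), oracle_penalty(x), atol=1e-9)


def test_smoothed_noisy_logistic_matches_dense_oracle():
    rng = np.random.default_rng(42)
    x = np.arange(28, 71, dtype=float)
    truth = 500.0 / (1.0 + np.exp(-0.15 * (x - 45.0)))
    y = truth * np.exp(rng.normal(0, 0.12, x.size))
    s = smooth_psa(PsaSeries("hp", x, y), df=5.0)
    expected = oracle_smooth(x, y, 5.0)
    assert np.max(np.abs(s.smoothed - expected) / np.abs(expected)) < 1e-6


def test_constant_series_is_a_fixed_point():
    x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
    for df in (2.0, 3.0, 4.9):
        s = smooth_psa(PsaSeries("c", x, np.full(5, 100.0)), df=df)
        assert np.allclose(s.smoothed, 100.0, atol=1e-8)


def test_df2_limit_is_least_squares_line():
    x = np.arange(10, 20, dtype=float)
    y = 10.0 * x
    s = smooth_psa(PsaSeries("lin", x, y), df=2.0)
    assert np.allclose(s.smoothed, y, atol=1e-8)
    # noisy series: df=2 must equal the OLS line
    rng = np.random.default_rng(1)
    y2 = 10.0 * x + rng.normal(0, 5, x.size)
    s2 = smooth_psa(PsaSeries("lin2", x, y2), df=2.0)
    coef = np.polyfit(x, y2, 1)
    assert np.allclose(s2.smoothed, np.polyval(coef, x), atol=1e-8)


def test_trace_equation_solved_to_tolerance():
    x = np.arange(28, 71, dtype=float)
    for df in (2.5, 3.0, 5.0, 10.0, 25.0, 42.0):
        lam = solve_lambda_for_df(x, df)
        assert abs(np.trace(smoother_matrix(x, lam)) - df) < 1e-6


def test_trace_is_decreasing_in_lambda():
    x = np.arange(0, 20, dtype=float)
    lams = 10.0 ** np.arange(-6, 7)
    traces = [np.trace(smoother_matrix(x, l)) for l in lams]
    assert all(a > b for a, b in zip(traces, traces[1:]))
    assert traces[0] <= len(x) + 1e-9
    assert traces[-1] >= 2.0 - 1e-9


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    a=st.floats(0.5, 3.0),
    b=st.floats(0.0, 50.0),
    seed=st.integers(0, 100),
)
def test_smoother_is_linear_and_shift_equivariant(a, b, seed):
    rng = np.random.default_rng(seed)
    x = np.arange(0, 15, dtype=float)
    y = rng.uniform(10, 100, x.size)
    s1 = smooth_psa(PsaSeries("p", x, y), df=5.0).smoothed
    s2 = smooth_psa(PsaSeries("p", x, a * y + b), df=5.0).smoothed
    assert np.allclose(s2, a * s1 + b, rtol=1e-9, atol=1e-7)


def test_residual_sum_of_squares_decreases_with_df():
    rng = np.random.default_rng(7)
    x = np.arange(28, 71, dtype=float)
    y = 80 + 300 / (1 + np.exp(-0.2 * (x - 50))) + rng.normal(0, 15, x.size)
    rss = []
    for df in (3.0, 5.0, 8.0, 15.0, 30.0):
        s = smooth_psa(PsaSeries("p", x, y), df=df)
        rss.append(float(np.sum((y - s.smoothed) ** 2)))
    assert all(a >= b - 1e-8 for a, b in zip(rss, rss[1:]))


def test_too_few_days_and_bad_df_rejected():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        smooth_psa(PsaSeries("p", x, np.ones(3)), df=2.5)
    x5 = np.arange(5.0)
    with pytest.raises(ValueError):
        smooth_psa(PsaSeries("p", x5, np.ones(5)), df=1.5)
    with pytest.raises(ValueError):
        smooth_psa(PsaSeries("p", x5, np.ones(5)), df=6.0)


# ---------------------------------------------------------------- aggregation

def test_view_aggregation_sums_three_views():
    assert aggregate_psa({"top": 10, "side1": 20, "side2": 30}) == 60
    with pytest.raises(ValueError):
        aggregate_psa({"top": 10, "side1": 20})


def test_day_with_missing_view_is_flagged_and_excluded():
    rows = []
    for d in (28, 29, 30, 31, 32):
        for v in ("top", "side1", "side2"):
            if d == 30 and v == "side2":
                continue
            rows.append(("hp1", d, v, 10.0))
    psa = pd.DataFrame(rows, columns=["half_pot_id", "DAP", "view", "kpixels"])
    agg, flagged = aggregate_psa_table(psa)
    assert 30 not in agg["DAP"].values
    assert len(agg) == 4
    assert flagged.iloc[0].tolist() == ["hp1", 30]


def test_duplicate_view_rows_are_averaged():
    rows = [("h", 28, "top", 10.0), ("h", 28, "top", 20.0),
            ("h", 28, "side1", 5.0), ("h", 28, "side2", 5.0)]
    psa = pd.DataFrame(rows, columns=["half_pot_id", "DAP", "view", "kpixels"])
    agg, _ = aggregate_psa_table(psa)
    assert agg["psa"].iloc[0] == pytest.approx(25.0)


# ---------------------------------------------------------------- traits

def _series_with_smoothed(days, values):
    s = PsaSeries("t", np.asarray(days, float), np.abs(np.asarray(values, float)))
    s.smoothed = np.asarray(values, float)
    s.df_used = 5.0
    return s


def test_rgr_conventions():
    days = [35, 40, 50, 60, 70]
    s = _series_with_smoothed(days, [500, 500, 200, 400, 400])
    tr = extract_traits(s, days=tuple(days), per_day=True)
    assert tr.rgr[(35, 40)] == pytest.approx(0.0)
    assert tr.rgr[(50, 60)] == pytest.approx(np.log(2) / 10, rel=1e-12)
    tr2 = extract_traits(s, days=tuple(days), per_day=False)
    assert tr2.rgr[(50, 60)] == pytest.approx(np.log(2), rel=1e-12)
    assert tr.ag == pytest.approx(400.0)


def test_exponential_growth_has_constant_per_day_rgr():
    days = np.array([35.0, 40.0, 50.0, 60.0, 70.0])
    s = _series_with_smoothed(days, 100 * np.exp(0.1 * days))
    tr = extract_traits(s, days=tuple(int(d) for d in days), per_day=True)
    for v in tr.rgr.values():
        assert v == pytest.approx(0.1, rel=1e-9)


def test_rgr_is_invariant_to_psa_rescaling():
    days = np.array([35.0, 40.0, 50.0, 60.0, 70.0])
    vals = np.array([120.0, 180.0, 330.0, 480.0, 540.0])
    t1 = extract_traits(_series_with_smoothed(days, vals), per_day=True)
    t2 = extract_traits(_series_with_smoothed(days, 3.7 * vals), per_day=True)
    for k in t1.rgr:
        assert t1.rgr[k] == pytest.approx(t2.rgr[k], rel=1e-12)


def test_nonpositive_endpoint_flags_interval_undefined():
    days = [35, 40, 50, 60, 70]
    s = _series_with_smoothed(days, [0.0, 100, 200, 300, 400])
    tr = extract_traits(s, days=tuple(days))
    assert (35, 40) in tr.undefined_intervals
    assert np.isnan(tr.rgr[(35, 40)])
    assert np.isfinite(tr.rgr[(40, 50)])


def test_extraction_outside_range_rejected():
    days = np.array([40.0, 50.0, 60.0, 70.0])
    s = _series_with_smoothed(days, [1, 2, 3, 4])
    with pytest.raises(ValueError):
        extract_traits(s, days=(35, 40, 70))


# ---------------------------------------------------------------- proxy

def test_perfectly_linear_proxy_has_r2_one(design10, sim10):
    from pasturepheno.set_smoothing import smooth_table

    agg, _ = aggregate_psa_table(sim10.psa)
    traits = traits_table(smooth_table(agg))
    harvest = traits[["half_pot_id", "AG"]].copy()
    harvest["AGB"] = 0.01 * harvest["AG"]
    fit = validate_proxy(traits, harvest[["half_pot_id", "AGB"]], design10.table, "grass")
    assert fit.r2 == pytest.approx(1.0)
    assert fit.slope == pytest.approx(0.01)


def test_three_point_toy_r2():
    traits = pd.DataFrame({"half_pot_id": ["a", "b", "c"], "AG": [1.0, 2.0, 3.0]})
    harvest = pd.DataFrame({"half_pot_id": ["a", "b", "c"], "AGB": [1.0, 2.0, 4.0]})
    design = pd.DataFrame(
        {"half_pot_id": ["a", "b", "c"], "pot_id": ["p1", "p1", "p2"],
         "species": ["grass"] * 3}
    )
    fit = validate_proxy(traits, harvest, design, "grass")
    assert fit.r2 == pytest.approx(27 / 28, rel=1e-9)
    assert fit.n == 3


def test_proxy_requires_three_pairs():
    traits = pd.DataFrame({"half_pot_id": ["a", "b"], "AG": [1.0, 2.0]})
    harvest = pd.DataFrame({"half_pot_id": ["a", "b"], "AGB": [1.0, 2.0]})
    design = pd.DataFrame(
        {"half_pot_id": ["a", "b"], "pot_id": ["p", "p"], "species": ["grass", "grass"]}
    )
    with pytest.raises(ValueError):
        validate_proxy(traits, harvest, design, "grass")


def test_smoothing_is_independent_across_half_pots():
    rng = np.random.default_rng(3)
    x = np.arange(28, 71, dtype=float)
    rows = []
    for hp in ("a", "b"):
        y = rng.uniform(50, 400, x.size)
        for d, v in zip(x, y):
            rows.append((hp, int(d), v))
    agg = pd.DataFrame(rows, columns=["half_pot_id", "DAP", "psa"])
    both = smooth_table(agg)
    solo = smooth_table(agg[agg["half_pot_id"] == "a"])
    assert np.allclose(both["a"].smoothed, solo["a"].smoothed)
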