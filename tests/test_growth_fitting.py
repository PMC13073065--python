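"""Logistic growth model, per-spot fitting, and array QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qhtcp.growth import (
    FLAG_INSUFFICIENT,
    FLAG_NON_GROWER,
    LogisticParams,
    fit_growth_curve,
    fit_screen,
    logistic_eval,
    qc_arrays,
)
from qhtcp.plate_io import SpotTimeSeries

T = np.arange(0.0, 120.1, 3.5)


def test_logistic_eval_analytic_points():
    p = LogisticParams(K=100, r=0.1, L=50)
    assert logistic_eval(p, 50.0) == pytest.approx(50.0)          # G(L) = K/2
    assert logistic_eval(p, 1e6) == pytest.approx(100.0)          # asymptote
    assert logistic_eval(p, 60.0) == pytest.approx(100 / (1 + np.exp(-1.0)), abs=1e-9)


@given(
    st.floats(10, 300), st.floats(0.02, 1.0), st.floats(0, 100),
    st.floats(0, 200), st.floats(0, 200),
)
def test_logistic_eval_monotone_and_bounded(K, r, L, t1, t2):
    p = LogisticParams(K=K, r=r, L=L)
    lo, hi = sorted((t1, t2))
    # upper bound is non-strict only at float saturation of exp(-r(t-L))
    assert 0 < logistic_eval(p, lo) <= logistic_eval(p, hi) <= K


def test_max_slope_at_L_equals_rK_over_4():
    """The logistic derivative peaks at t = L with value r*K/4."""
    p = LogisticParams(K=150, r=0.2, L=40)
    t = np.linspace(0, 120, 200001)
    g = logistic_eval(p, t)
    slope = np.diff(g) / np.diff(t)
    i = np.argmax(slope)
    assert slope[i] == pytest.approx(p.r * p.K / 4, rel=1e-3)
    assert t[i] == pytest.approx(p.L, abs=0.05)


def test_noiseless_recovery_exact():
    truth = LogisticParams(K=120, r=0.08, L=40)
    res = fit_growth_curve((T, logistic_eval(truth, T)))
    assert res.ok
    for name in ("K", "r", "L"):
        assert getattr(res.params, name) == pytest.approx(getattr(truth, name), rel=1e-6)


def test_noisy_recovery_within_tolerance():
    truth = LogisticParams(K=120, r=0.08, L=40)
    rng = np.random.default_rng(123)
    y = np.maximum(logistic_eval(truth, T) + rng.normal(0, 0.02 * truth.K, T.size), 0)
    res = fit_growth_curve((T, y))
    assert res.ok
    assert res.params.K == pytest.approx(truth.K, rel=0.02)
    assert res.params.L == pytest.approx(truth.L, rel=0.05)


def test_flat_series_is_non_grower():
    res = fit_growth_curve((T, np.full(T.size, 7.0)))
    assert res.flags == {FLAG_NON_GROWER} and res.params is None


def test_too_few_points_flagged():
    res = fit_growth_curve((T[:4], logistic_eval(LogisticParams(100, 0.1, 40), T[:4])))
    assert res.flags == {FLAG_INSUFFICIENT} and not res.converged


def test_scale_equivariance():
    y = logistic_eval(LogisticParams(90, 0.12, 55), T)
    a = fit_growth_curve((T, y)).params
    b = fit_growth_curve((T, 3.7 * y)).params
    assert b.K / a.K == pytest.approx(3.7, rel=1e-6)
    assert b.r == pytest.approx(a.r, rel=1e-6)
    assert b.L == pytest.approx(a.L, rel=1e-6, abs=1e-6)


def test_time_shift_equivariance():
    y = logistic_eval(LogisticParams(90, 0.12, 55), T)
    a = fit_growth_curve((T, y)).params
    b = fit_growth_curve((T + 9.5, y)).params
    assert b.L - a.L == pytest.approx(9.5, rel=1e-6)
    assert b.K == pytest.approx(a.K, rel=1e-6)
    assert b.r == pytest.approx(a.r, rel=1e-6)


def _spot(plate, row, col, y, cond=0.0, strain="G1"):
    return SpotTimeSeries(plate, row, col, strain, cond, T, y)


def test_fit_screen_cardinality_flags_and_order_invariance():
    truth = LogisticParams(K=120, r=0.1, L=40)
    y = logistic_eval(truth, T)
    spots = [_spot("p", 1, c, y, strain=f"G{c}") for c in range(1, 11)]
    # ten flat spots planted
    spots += [_spot("p", 2, c, np.full(T.size, 3.0), strain=f"F{c}") for c in range(1, 11)]
    table = fit_screen(spots)
    assert len(table) == 20
    assert (table["flags"] == FLAG_NON_GROWER).sum() == 10
    reversed_table = fit_screen(spots[::-1])
    pd.testing.assert_frame_equal(table, reversed_table)


def _fit_table(fail_positions, plate="p", cond=0.0):
    rows = []
    for r in range(1, 17):
        for c in range(1, 25):
            failed = (r, c) in fail_positions
            rows.append(
                {
                    "strain": f"G{r}_{c}", "plate": plate, "row": r, "col": c,
                    "condition_ugml": cond,
                    "K": np.nan if failed else 100.0, "r": 0.1, "L": 40.0,
                    "rss": 1.0, "converged": not failed,
                    "flags": "poor_fit" if failed else "",
                }
            )
    return pd.DataFrame(rows)


def test_qc_scattered_failures_pass():
    fails = {(1, 1), (9, 17)}
    (report,) = qc_arrays(_fit_table(fails))
    assert report.passed and not report.spatial_flag
    assert report.fraction_failed == pytest.approx(2 / 384)


def test_qc_spatial_block_fails():
    fails = {(r, c) for r in range(5, 9) for c in range(10, 14)}  # 4x4 block of 16
    (report,) = qc_arrays(_fit_table(fails))
    assert report.spatial_flag and not report.passed


def test_qc_fraction_threshold():
    # 50 failures spread out: fraction 0.13 > 0.10
    fails = {(r, c) for r in range(1, 17, 2) for c in range(1, 25, 4)}
    assert len(fails) == 48
    fails |= {(2, 2), (2, 20)}
    (report,) = qc_arrays(_fit_table(fails))
    assert report.fraction_failed == pytest.approx(50 / 384)
    assert not report.passed and not report.spatial_flag
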