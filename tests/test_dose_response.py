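"""4PL dose-response fitting, growth metrics, and ZIP synergy surfaces."""

import numpy as np
import pandas as pd
import pytest

from qhtcp.dose import (
    FlatResponseError,
    FourPLParams,
    _HillInc,
    fit_4pl,
    growth_metrics,
    percent_inhibition,
    read_dose_matrix,
    window_summary,
    write_dose_matrix,
    zip_surface,
)
from qhtcp.simulate import simulate_dose_matrix

LADDER = np.array([0, 0.625, 1.25, 2.5, 5, 10, 20, 40, 80.0])


def test_4pl_noiseless_recovery():
    truth = FourPLParams(bottom=0, top=1, hill=1, ec50=5)
    fit = fit_4pl(LADDER, truth(LADDER))
    for name in ("bottom", "top", "hill", "ec50"):
        assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-6, abs=1e-6)
    assert fit.ic50 == pytest.approx(5.0, rel=1e-6)


@pytest.mark.parametrize("hill", [0.7, 1.0, 2.5])
def test_4pl_half_response_at_ec50(hill):
    truth = FourPLParams(bottom=0, top=1, hill=hill, ec50=4.0)
    fit = fit_4pl(LADDER, truth(LADDER))
    assert fit(fit.ec50) == pytest.approx(0.5, abs=1e-6)


def test_4pl_flat_response_rejected():
    with pytest.raises(FlatResponseError):
        fit_4pl(LADDER, np.full(LADDER.size, 0.8))


def test_4pl_dose_scale_equivariance():
    truth = FourPLParams(bottom=0.1, top=1.0, hill=1.6, ec50=5)
    a = fit_4pl(LADDER, truth(LADDER))
    b = fit_4pl(LADDER * 13.0, truth(LADDER))
    assert b.ec50 / a.ec50 == pytest.approx(13.0, rel=1e-6)
    assert b.hill == pytest.approx(a.hill, rel=1e-6)
    assert b.top == pytest.approx(a.top, rel=1e-6)
    assert b.bottom == pytest.approx(a.bottom, abs=1e-6)


def test_4pl_noisy_ec50_recovery():
    """5% replicate noise: ec50 back within 10% (seeded replicates)."""
    truth = FourPLParams(bottom=0, top=1, hill=1.3, ec50=5)
    rng = np.random.default_rng(42)
    errs = []
    for _ in range(25):
        x = np.tile(LADDER, 3)
        y = truth(x) + rng.normal(0, 0.05, x.size)
        errs.append(abs(fit_4pl(x, y).ec50 - 5) / 5)
    assert np.median(errs) < 0.10


def test_growth_metrics_logistic_limits():
    t = np.arange(0, 36.01, 0.5)  # 30-min cadence
    K, r, L = 1.2, 0.5, 12.0
    ab = K / (1 + np.exp(-r * (t - L)))
    gm = growth_metrics(t, ab)
    assert gm.lag == pytest.approx(L, rel=0.01)
    assert gm.max_rate == pytest.approx(r * K / 4 / 60 * 1000, rel=0.02)


def test_growth_metrics_flat_and_shift():
    t = np.arange(0, 36.01, 0.5)
    flat = growth_metrics(t, np.full(t.size, 0.1))
    assert flat.max_rate == 0.0 and flat.undefined
    K, r, L = 1.0, 0.4, 10.0
    ab = K / (1 + np.exp(-r * (t - L)))
    a = growth_metrics(t, ab)
    b = growth_metrics(t + 4.0, ab)
    assert b.lag - a.lag == pytest.approx(4.0, abs=1e-9)
    assert b.max_rate == pytest.approx(a.max_rate)


def test_percent_inhibition():
    assert percent_inhibition(0.5, [0.5, 0.5]) == pytest.approx(0.0)
    assert percent_inhibition(0.0, 0.5) == pytest.approx(100.0)
    assert percent_inhibition(0.25, 0.5) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        percent_inhibition(0.1, 0.0)


DOSES_A = 10 * 2.0 ** np.arange(-2, 4)
DOSES_B = 1 * 2.0 ** np.arange(-2, 4)


@pytest.mark.parametrize("hill_a", [0.5, 1, 2, 4])
@pytest.mark.parametrize("hill_b", [0.5, 2])
def test_zip_bliss_consistent_matrix_is_null(hill_a, hill_b):
    """No interaction planted: delta below one percentage point everywhere."""
    pa = _HillInc(0, 0.9, hill_a, 10.0)
    pb = _HillInc(0, 0.8, hill_b, 1.0)
    matrix = simulate_dose_matrix(pa, pb, DOSES_A, DOSES_B)
    surface = zip_surface(matrix)
    assert np.abs(surface.delta.to_numpy()).max() < 1.0
    assert abs(surface.summary) < 0.5


def test_zip_zero_margins_constant_combination():
    """Inactive monotherapies: delta equals the planted combination effect."""
    doses = 2.0 ** np.arange(0, 6)
    zero = _HillInc(0, 0.0, 1, 1.0)
    c = 20.0
    matrix = simulate_dose_matrix(zero, zero, doses, doses,
                                  delta_surface=np.full((6, 6), c))
    surface = zip_surface(matrix)
    np.testing.assert_allclose(surface.delta.to_numpy(), c, atol=1.0)


def test_zip_summary_shift_linearity():
    pa = _HillInc(0, 0.9, 1.5, 10.0)
    pb = _HillInc(0, 0.8, 1.2, 1.0)
    base = zip_surface(simulate_dose_matrix(pa, pb, DOSES_A, DOSES_B))
    shifted = zip_surface(
        simulate_dose_matrix(pa, pb, DOSES_A, DOSES_B,
                             delta_surface=np.full((6, 6), 7.0))
    )
    assert shifted.summary - base.summary == pytest.approx(7.0, abs=1.0)


def test_window_summary_planted_block_ties_and_degenerate():
    idx = pd.Index([1.0, 2, 4, 8, 16], name="dose_a")
    cols = pd.Index([1.0, 2, 4, 8, 16], name="dose_b")
    d = np.zeros((5, 5))
    d[1:4, 2:5] = 20.0
    from qhtcp.dose import SynergySurface

    surface = SynergySurface(
        delta=pd.DataFrame(d, index=idx, columns=cols),
        expected=None, observed=None, summary=float(d.mean()),
    )
    best = window_summary(surface)
    assert (best["row_start"], best["col_start"]) == (1, 2)
    assert best["mean_delta"] == pytest.approx(20.0)

    flat = SynergySurface(
        delta=pd.DataFrame(np.ones((5, 5)), index=idx, columns=cols),
        expected=None, observed=None, summary=1.0,
    )
    tie = window_summary(flat)
    assert (tie["row_start"], tie["col_start"]) == (0, 0)   # tie -> lowest doses

    cell = window_summary(surface, window=(1, 1))
    assert cell["mean_delta"] == pytest.approx(20.0)

    with pytest.raises(ValueError):
        window_summary(surface, window=(6, 6))


def test_zip_requires_zero_margins():
    df = pd.DataFrame(np.zeros((3, 3)), index=[1.0, 2, 4], columns=[1.0, 2, 4])
    with pytest.raises(ValueError, match="0-dose"):
        zip_surface(df)


def test_dose_matrix_roundtrip(tmp_path):
    matrix = simulate_dose_matrix(
        _HillInc(0, 0.9, 1.5, 10.0), _HillInc(0, 0.8, 1.2, 1.0),
        DOSES_A, DOSES_B, noise_sd=1.0, seed=5,
    )
    path = tmp_path / "m.tsv"
    write_dose_matrix(matrix, path)
    back = read_dose_matrix(path)
    np.testing.assert_allclose(back.to_numpy(), matrix.to_numpy())
    (tmp_path / "bad.tsv").write_text("x\ta\tb\nrow1\t1\t2\n")
    with pytest.raises(ValueError, match="malformed"):
        read_dose_matrix(tmp_path / "bad.tsv")
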