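"""Liquid-assay analytics: 4PL dose-response, growth metrics, ZIP synergy.

Endpoint absorbance versus a serial drug dilution is fit with the
four-parameter logistic (4PL) model

    y(x) = bottom + (top - bottom) / (1 + (x / ec50)^hill)

on log10 dose; the 0-dose wells anchor the untreated response but do not
enter the logistic fit (log dose is undefined at 0). IC50 is reported as
the concentration at which the fitted response falls to 50% of the fitted
untreated response.

Drug-combination matrices of % inhibition are scored with the zero
interaction potency (ZIP) model: monotherapy margins are fit with
inhibition-constrained 4PL curves, the zero-interaction expectation at a
combination is y1 + y2 - y1*y2 (Bliss-type independence of the two fitted
single-drug effects), the observed potency-shifted response comes from
refitting each row and column with the baseline pinned to the conditioning
drug's monotherapy effect, and delta = observed - expected in percentage
points. The summary score is the mean delta over all combination cells;
3x3 dose-window means localize regions of maximal synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class FlatResponseError(ValueError):
    """Response does not vary enough to define a dose-response curve."""


class SurfaceError(ValueError):
    """A ZIP margin or conditional fit failed."""


@dataclass(frozen=True)
class FourPLParams:
    """4PL parameters; top > bottom, ec50 > 0, hill > 0 for inhibition."""

    bottom: float
    top: float
    hill: float
    ec50: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (x / self.ec50) ** self.hill, 0.0)
        out = self.bottom + (self.top - self.bottom) / (1.0 + ratio)
        return out if out.ndim else float(out)

    @property
    def ic50(self) -> float:
        """Concentration where the fitted response = 50% of the fitted
        untreated response (top). Equals ec50 when bottom = 0."""
        target = self.top / 2.0
        if not self.bottom < target < self.top:
            return np.nan
        ratio = (self.top - self.bottom) / (target - self.bottom) - 1.0
        return float(self.ec50 * ratio ** (1.0 / self.hill))


def fit_4pl(
    concentrations: np.ndarray, responses: np.ndarray, min_rel_range: float = 0.10
) -> FourPLParams:
    """Least-squares 4PL fit of endpoint responses over a dose ladder.

    Requires >= 4 distinct concentrations including 0 (or a span wide
    enough to anchor both plateaus); replicates are passed as repeated
    (concentration, response) pairs. Raises :class:`FlatResponseError`
    when responses vary by less than ``min_rel_range`` of their magnitude.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must align")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations for a 4PL fit")
    span = y.max() - y.min()
    if span <= min_rel_range * max(abs(y).max(), 1e-12):
        raise FlatResponseError("response varies by less than the flatness threshold")

    pos = x > 0
    xp, yp = x[pos], y[pos]
    y0_mean = float(y[~pos].mean()) if (~pos).any() else float(yp[np.argmin(xp)])
    lx = np.log10(xp)

    def model(p, lx):
        b, t, h, le = p
        return b + (t - b) / (1.0 + 10.0 ** (h * (lx - le)))

    def resid(p):
        return model(p, lx) - yp

    mid = (y.max() + y.min()) / 2.0
    le0 = float(lx[np.argmin(np.abs(yp - mid))])
    x0 = np.array([y.min(), max(y0_mean, y.min() + span), 1.0, le0])
    lb = np.array([y.min() - span, y.min(), 0.05, lx.min() - 3.0])
    ub = np.array([y.max(), y.max() + span, 10.0, lx.max() + 3.0])
    x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    if sol.status < 0 or not np.all(np.isfinite(sol.x)):
        raise SurfaceError("4PL fit did not converge")
    b, t, h, le = sol.x
    if t <= b:
        raise SurfaceError("degenerate 4PL fit: top <= bottom")
    return FourPLParams(bottom=float(b), top=float(t), hill=float(h), ec50=float(10.0**le))


@dataclass(frozen=True)
class GrowthMetrics:
    """Lag (h, time to maximum slope) and max rate (absorbance x1000/min)."""

    lag: float
    max_rate: float
    undefined: bool = False


def growth_metrics(
    times_h: np.ndarray, absorbance: np.ndarray, smoothing_window: int = 3
) -> GrowthMetrics:
    """Lag time and maximum growth rate of a liquid growth curve.

    The curve is smoothed with a centered moving average before the slope
    is taken (finite differences); max_rate is the largest slope rescaled
    to absorbance x 1000 per minute and lag is the time at which it
    occurs. A curve with no positive slope yields max_rate 0 and an
    undefined lag.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if t.size < 10:
        raise ValueError("need >= 10 points for growth metrics")
    w = max(1, int(smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: t.size]
    slope = np.gradient(y, t)  # per hour
    i = int(np.argmax(slope))
    if slope[i] <= 0:
        return GrowthMetrics(lag=np.nan, max_rate=0.0, undefined=True)
    return GrowthMetrics(lag=float(t[i]), max_rate=float(slope[i] / 60.0 * 1000.0))


def percent_inhibition(
    treated: np.ndarray | float, control: np.ndarray | float
) -> np.ndarray | float:
    """100 * (1 - treated / mean(control)); control mean must be positive."""
    ctrl = float(np.mean(np.asarray(control, dtype=float)))
    if ctrl <= 0:
        raise ValueError("degenerate control: mean must be > 0")
    out = 100.0 * (1.0 - np.asarray(treated, dtype=float) / ctrl)
    return out if out.ndim else float(out)


# --- ZIP -------------------------------------------------------------------

@dataclass(frozen=True)
class _HillInc:
    """Increasing Hill curve on fractional inhibition: b at 0 dose, t at inf."""

    bottom: float
    top: float
    hill: float
    ec50: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (self.ec50 / x) ** self.hill, np.inf)
        out = self.bottom + (self.top - self.bottom) / (1.0 + ratio)
        return out if out.ndim else float(out)


def _fit_hill_inc(x: np.ndarray, y: np.ndarray, bottom: float = 0.0,
                  what: str = "margin") -> _HillInc:
    """Fit top/hill/ec50 of an increasing Hill curve with fixed baseline.

    Inhibition fits are bounded to [bottom, 1]; dose on log10 scale.
    """
    lx = np.log10(x)

    def model(p):
        t, h, le = p
        return bottom + (t - bottom) / (1.0 + 10.0 ** (-h * (lx - le)))

    def resid(p):
        return model(p) - y

    t0 = float(np.clip(y.max(), bottom + 1e-3, 1.0))
    mid = (bottom + t0) / 2.0
    le0 = float(lx[np.argmin(np.abs(y - mid))])
    x0 = np.array([t0, 1.0, le0])
    lb = np.array([bottom, 0.05, lx.min() - 4.0])
    ub = np.array([1.0, 10.0, lx.max() + 4.0])
    x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=2000)
    # status 0 (iteration cap) happens on near-flat conditionals where the
    # hill/ec50 pair is unidentifiable; the fitted values are still valid
    if sol.status < 0 or not np.all(np.isfinite(sol.x)):
        raise SurfaceError(f"ZIP {what} fit did not converge")
    t, h, le = sol.x
    return _HillInc(bottom=float(bottom), top=float(t), hill=float(h), ec50=float(10.0**le))


@dataclass
class SynergySurface:
    """ZIP delta landscape aligned to the combination cells of a DoseMatrix."""

    delta: pd.DataFrame          # rows: drug A doses > 0, cols: drug B doses > 0
    expected: pd.DataFrame
    observed: pd.DataFrame
    summary: float               # mean delta over all combination cells

    def window_means(self, window: tuple[int, int] = (3, 3)) -> pd.DataFrame:
        wr, wc = window
        d = self.delta.to_numpy()
        nr, nc = d.shape
        if wr > nr or wc > nc:
            raise ValueError(f"window {window} larger than surface {d.shape}")
        rows = []
        for i in range(nr - wr + 1):
            for j in range(nc - wc + 1):
                rows.append(
                    {
                        "row_start": i,
                        "col_start": j,
                        "row_doses": tuple(self.delta.index[i : i + wr]),
                        "col_doses": tuple(self.delta.columns[j : j + wc]),
                        "mean_delta": float(d[i : i + wr, j : j + wc].mean()),
                    }
                )
        return pd.DataFrame(rows)


def _check_matrix(matrix: pd.DataFrame) -> None:
    rows = np.asarray(matrix.index, dtype=float)
    cols = np.asarray(matrix.columns, dtype=float)
    if 0.0 not in rows or 0.0 not in cols:
        raise ValueError("dose matrix must include the 0-dose row and column")
    if np.any(np.diff(rows) <= 0) or np.any(np.diff(cols) <= 0):
        raise ValueError("dose ladders must be strictly increasing")


def zip_surface(matrix: pd.DataFrame) -> SynergySurface:
    """ZIP delta landscape of a % inhibition dose-combination matrix.

    ``matrix`` is indexed by drug A doses (rows) and drug B doses
    (columns), both including 0, with entries in % inhibition. See the
    module docstring for the model. Delta is defined only at combination
    cells (both doses > 0).
    """
    matrix = matrix.copy()
    matrix.index = matrix.index.astype(float)
    matrix.columns = matrix.columns.astype(float)
    _check_matrix(matrix)
    frac = matrix / 100.0
    a_doses = np.array([d for d in frac.index if d > 0])
    b_doses = np.array([d for d in frac.columns if d > 0])

    try:
        fit_a = _fit_hill_inc(a_doses, frac.loc[a_doses, 0.0].to_numpy(), 0.0, "drug A margin")
    except SurfaceError:
        raise SurfaceError("monotherapy fit failed for drug A margin") from None
    try:
        fit_b = _fit_hill_inc(b_doses, frac.loc[0.0, b_doses].to_numpy(), 0.0, "drug B margin")
    except SurfaceError:
        raise SurfaceError("monotherapy fit failed for drug B margin") from None

    ya = fit_a(a_doses)
    yb = fit_b(b_doses)
    expected = np.add.outer(ya, yb) - np.outer(ya, yb)

    # conditional refits: rows condition on drug B, columns on drug A
    obs_row = np.empty((a_doses.size, b_doses.size))
    for j, b in enumerate(b_doses):
        base = float(np.clip(yb[j], 0.0, 0.999))
        fit = _fit_hill_inc(a_doses, frac.loc[a_doses, b].to_numpy(), base, f"row at B={b}")
        obs_row[:, j] = fit(a_doses)
    obs_col = np.empty_like(obs_row)
    for i, a in enumerate(a_doses):
        base = float(np.clip(ya[i], 0.0, 0.999))
        fit = _fit_hill_inc(b_doses, frac.loc[a, b_doses].to_numpy(), base, f"column at A={a}")
        obs_col[i, :] = fit(b_doses)
    observed = (obs_row + obs_col) / 2.0

    delta = 100.0 * (observed - expected)
    idx = pd.Index(a_doses, name="dose_a")
    cols = pd.Index(b_doses, name="dose_b")
    return SynergySurface(
        delta=pd.DataFrame(delta, index=idx, columns=cols),
        expected=pd.DataFrame(100.0 * expected, index=idx, columns=cols),
        observed=pd.DataFrame(100.0 * observed, index=idx, columns=cols),
        summary=float(delta.mean()),
    )


def window_summary(
    surface: SynergySurface, window: tuple[int, int] = (3, 3)
) -> dict:
    """Maximal-mean contiguous dose window; ties pick the lowest indices."""
    means = surface.window_means(window)
    best = means.sort_values(
        ["mean_delta", "row_start", "col_start"], ascending=[False, True, True],
        kind="mergesort",
    ).iloc[0]
    return {
        "row_start": int(best["row_start"]),
        "col_start": int(best["col_start"]),
        "row_doses": best["row_doses"],
        "col_doses": best["col_doses"],
        "mean_delta": float(best["mean_delta"]),
    }


def read_dose_matrix(path: str) -> pd.DataFrame:
    """Read a dose matrix TSV whose first row/column carry the dose ladders."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        df.index = df.index.astype(float)
        df.columns = df.columns.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed dose matrix {path}: non-numeric dose labels") from exc
    return df.sort_index().sort_index(axis=1)


def write_dose_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t")
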