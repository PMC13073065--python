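"""Logistic growth-curve fitting and array-level quality control.

Each spot culture's intensity time series is fit to the logistic growth
equation

    G(t) = K / (1 + exp(-r * (t - L)))

yielding the cell proliferation parameters (CPPs): carrying capacity ``K``
(intensity units), maximum specific growth rate ``r`` (per hour), and the
time ``L`` (hours) at which K/2 is reached. The analytic maximum slope of
the curve is r*K/4, attained at t = L.

``r`` is fitted and reported but never used for scoring downstream: at the
imaging cadence of a spot-array scanner the early exponential phase is
barely sampled, making ``L`` a much more precise kinetic phenotype than
``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plate_io import SpotTimeSeries

FLAG_NON_GROWER = "non_grower"
FLAG_POOR_FIT = "poor_fit"
FLAG_INSUFFICIENT = "insufficient_data"

MIN_POINTS = 5


@dataclass(frozen=True)
class LogisticParams:
    """Fitted CPPs. K > 0 (intensity units), r > 0 (1/h), L >= 0 (h)."""

    K: float
    r: float
    L: float

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.r > 0 and self.L >= 0):
            raise ValueError(f"invalid logistic parameters K={self.K}, r={self.r}, L={self.L}")


def logistic_eval(params: LogisticParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate G(t) = K / (1 + exp(-r (t - L))); G(L) = K/2, G(inf) = K."""
    t = np.asarray(t, dtype=float)
    out = params.K / (1.0 + np.exp(-params.r * (t - params.L)))
    return out if out.ndim else float(out)


@dataclass
class FitSettings:
    """Fit configuration.

    ``rel_range_threshold`` declares a spot non-growing when its dynamic
    range is below this fraction of the plate's median dynamic range (the
    relative rule adapts to imaging gain); ``min_dynamic_range`` overrides
    with an absolute floor when set.
    """

    min_points: int = MIN_POINTS
    rel_range_threshold: float = 0.10
    min_dynamic_range: float | None = None
    subtract_baseline: bool = True
    max_nfev: int = 200
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass
class FitResult:
    """Per-spot fit outcome; ``params`` present iff converged and growing."""

    params: LogisticParams | None
    rss: float
    converged: bool
    flags: frozenset[str] = field(default_factory=frozenset)
    n_obs: int = 0
    baseline: float = 0.0

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


def _residual_and_jac(t: np.ndarray, y: np.ndarray):
    def resid(p):
        K, r, L, b = p
        s = 1.0 / (1.0 + np.exp(-r * (t - L)))
        return b + K * s - y

    def jac(p):
        K, r, L, b = p
        s = 1.0 / (1.0 + np.exp(-r * (t - L)))
        ds = s * (1.0 - s)
        return np.column_stack((s, K * ds * (t - L), -K * ds * r, np.ones_like(t)))

    return resid, jac


def fit_growth_curve(
    series: SpotTimeSeries | tuple[np.ndarray, np.ndarray],
    settings: FitSettings | None = None,
    min_dynamic_range: float | None = None,
) -> FitResult:
    """Nonlinear least-squares logistic fit of one spot's time series.

    Background pixel intensity is handled with an additive baseline
    parameter, initialized at the series minimum and reported in
    ``FitResult.baseline``; K is the growth amplitude on the
    background-subtracted scale. (Subtracting the minimum *before*
    fitting would destroy the logistic form whenever G(0) is not
    negligible and bias K.) Initialization: K0 = dynamic range, L0 = time
    nearest the half-range crossing, r0 = 4 * (max finite-difference
    slope) / K0. Bounds keep the optimizer physical: K in (0, 2*max],
    r in (0, 5/h], L in [0, 2*t_max], baseline in [0, max].
    """
    settings = settings or FitSettings()
    if isinstance(series, SpotTimeSeries):
        t, y = series.times, series.intensities
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    n = t.size
    if n < settings.min_points:
        return FitResult(None, np.nan, False, frozenset({FLAG_INSUFFICIENT}), n)

    b0 = float(y.min()) if settings.subtract_baseline else 0.0
    rng = float(y.max() - y.min())

    floor = min_dynamic_range if min_dynamic_range is not None else settings.min_dynamic_range
    if rng <= max(floor if floor is not None else 0.0, 1e-9):
        return FitResult(None, np.nan, False, frozenset({FLAG_NON_GROWER}), n, b0)

    K0 = rng
    half_idx = int(np.argmin(np.abs(y - b0 - rng / 2.0)))
    L0 = float(np.clip(t[half_idx], 0.0, 2.0 * t[-1]))
    slopes = np.diff(y) / np.diff(t)
    smax = float(slopes.max()) if slopes.size else 0.0
    r0 = float(np.clip(4.0 * max(smax, 1e-9) / K0, 1e-3, 5.0))

    resid, jac = _residual_and_jac(t, y)
    b_ub = float(y.max()) if settings.subtract_baseline else 1e-9
    lb = np.array([1e-9, 1e-6, 0.0, 0.0])
    ub = np.array([2.0 * float(y.max()), 5.0, 2.0 * t[-1], max(b_ub, 1e-9)])
    x0 = np.clip(np.array([K0, r0, L0, b0]), lb + 1e-12, ub - 1e-12)
    try:
        sol = least_squares(
            resid, x0, jac=jac, bounds=(lb, ub), method="trf",
            xtol=settings.xtol, ftol=settings.ftol, gtol=1e-12,
            max_nfev=settings.max_nfev,
        )
    except Exception:
        return FitResult(None, np.nan, False, frozenset({FLAG_POOR_FIT}), n, b0)
    if sol.status <= 0:
        return FitResult(None, float(np.sum(sol.fun**2)), False,
                         frozenset({FLAG_POOR_FIT}), n, b0)
    K, r, L, b = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    return FitResult(LogisticParams(K=K, r=r, L=L), rss, True, frozenset(), n, b)


def fit_screen(
    series: Iterable[SpotTimeSeries],
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """Fit every spot of a screen; one row per (plate, position, condition).

    Non-growing spots are detected against the plate's median dynamic range
    (``rel_range_threshold``). Per-spot failures become flags; the screen
    never aborts. Deterministic given identical inputs and settings, and
    invariant to input row order.
    """
    settings = settings or FitSettings()
    series = sorted(series, key=lambda s: (s.plate_id, s.condition, s.row, s.col))
    by_plate: dict[tuple[str, float], list[SpotTimeSeries]] = {}
    for s in series:
        by_plate.setdefault((s.plate_id, s.condition), []).append(s)

    rows = []
    for (plate, cond), spots in sorted(by_plate.items()):
        ranges = [float(s.intensities.max() - s.intensities.min()) for s in spots]
        med_range = float(np.median(ranges)) if ranges else 0.0
        floor = settings.rel_range_threshold * med_range
        for s in spots:
            res = fit_growth_curve(s, settings, min_dynamic_range=floor)
            p = res.params
            rows.append(
                {
                    "strain": s.strain_id,
                    "plate": s.plate_id,
                    "row": s.row,
                    "col": s.col,
                    "condition_ugml": s.condition,
                    "K": p.K if p else np.nan,
                    "r": p.r if p else np.nan,
                    "L": p.L if p else np.nan,
                    "rss": res.rss,
                    "converged": res.converged,
                    "flags": ";".join(sorted(res.flags)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ArrayQCReport:
    """QC verdict for one (plate, condition) array.

    ``passed`` iff the failed-spot fraction is within threshold AND no
    contiguous 4x4 block concentrates failures (spatially clustered
    failures indicate imaging/pinning artifacts).
    """

    plate_id: str
    condition: float
    fraction_failed: float
    spatial_flag: bool
    passed: bool


def _spatial_cluster(fail_grid: np.ndarray, block: int, min_failures: int) -> bool:
    """True if any contiguous block x block window holds >= min_failures failures."""
    if fail_grid.shape[0] < block or fail_grid.shape[1] < block:
        return False
    c = fail_grid.cumsum(0).cumsum(1)
    c = np.pad(c, ((1, 0), (1, 0)))
    sums = (
        c[block:, block:] - c[:-block, block:] - c[block:, :-block] + c[:-block, :-block]
    )
    return bool(sums.max() >= min_failures)


def qc_arrays(
    fit_table: pd.DataFrame,
    max_fraction_failed: float = 0.10,
    block: int = 4,
    block_failures: int = 8,
) -> list[ArrayQCReport]:
    """Flag problematic arrays; failed arrays are excluded downstream.

    A spot counts as failed when its fit carries any flag or did not
    converge. Empty positions (no data) do not count toward the fraction
    but missing-but-expected positions are the design validator's job.
    """
    reports = []
    for (plate, cond), grp in fit_table.groupby(["plate", "condition_ugml"], sort=True):
        failed = (grp["flags"].fillna("").astype(str) != "") | (~grp["converged"])
        frac = float(failed.mean()) if len(grp) else 1.0
        grid = np.zeros((16, 24), dtype=int)
        for r, c, f in zip(grp["row"], grp["col"], failed):
            if f:
                grid[int(r) - 1, int(c) - 1] = 1
        spatial = _spatial_cluster(grid, block, block_failures)
        reports.append(
            ArrayQCReport(
                plate_id=str(plate),
                condition=float(cond),
                fraction_failed=frac,
                spatial_flag=spatial,
                passed=(frac <= max_fraction_failed) and not spatial,
            )
        )
    return reports


def qc_frame(reports: Sequence[ArrayQCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate": r.plate_id,
                "condition_ugml": r.condition,
                "fraction_failed": r.fraction_failed,
                "spatial_flag": r.spatial_flag,
                "passed": r.passed,
            }
            for r in reports
        ]
    )
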