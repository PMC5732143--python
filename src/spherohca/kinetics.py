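"""Time-series analyses: assembly detection, dye-uptake kinetics and the
volume-per-seeded-cell regression.

Spheroid assembly is scored on the Shape P2A roundness series: loose
aggregates are irregular (high P2A), compact spheroids are round, so the
time at which P2A attains its minimum marks assembly.  Dye uptake follows a
saturating mono-exponential; its plateau is the dose-responsive readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    feature: str = ""
    well: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


class AssemblyResult(NamedTuple):
    time: float
    index: int
    unassembled: bool  # minimum at the final timepoint: still flattening
    ambiguous: bool  # ties (flat stretch at the minimum)


@dataclass
class UptakeFit:
    plateau: float
    rate_k: float  # 1/hour
    rss: float

    @property
    def t95(self) -> float:
        """Time to 95% of plateau: ln(20)/k."""
        return float(np.log(20.0) / self.rate_k) if self.rate_k > 0 else np.inf


class SlopeFit(NamedTuple):
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    stderr: float


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty(len(values), dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.mean(values[lo:hi])
    return out


def detect_assembly_time(
    p2a_series: TimeSeries, smoothing_window: int = 3
) -> AssemblyResult:
    """Time of the minimum of the (smoothed) roundness series.

    Ties break toward the earliest time.  A minimum at the final timepoint
    is flagged ``unassembled`` (roundness still improving when observation
    stopped).
    """
    if len(p2a_series.times) < 3:
        raise InsufficientDataError("need at least 3 timepoints")
    smooth = moving_average(p2a_series.values, smoothing_window)
    idx = int(np.argmin(smooth))
    ties = np.isclose(smooth, smooth[idx]).sum() > 1
    return AssemblyResult(
        time=float(p2a_series.times[idx]),
        index=idx,
        unassembled=idx == len(smooth) - 1,
        ambiguous=bool(ties),
    )


def _uptake_model(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def fit_uptake(series: TimeSeries) -> UptakeFit:
    """Least-squares fit of I(t) = plateau * (1 - exp(-k t))."""
    t, y = series.times, series.values
    if len(t) < 4:
        raise InsufficientDataError("need at least 4 timepoints")
    ymax = float(np.max(y))
    if ymax <= 0:
        return UptakeFit(plateau=0.0, rate_k=0.0, rss=float(np.sum(y**2)))
    # initial rate from the first nonzero rise
    k0 = 1.0 / max(t[int(np.argmax(y >= 0.63 * ymax))], t[1])
    try:
        popt, _ = curve_fit(
            _uptake_model,
            t,
            y,
            p0=[ymax, k0],
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError("uptake fit failed to converge", {"p0": [ymax, k0]}) from exc
    resid = y - _uptake_model(t, *popt)
    return UptakeFit(plateau=float(popt[0]), rate_k=float(popt[1]),
                     rss=float(np.sum(resid**2)))


def volume_per_cell_slope(points, alpha: float = 0.05) -> SlopeFit:
    """OLS slope of estimated spheroid volume (pL) on seeded cell number.

    ``points`` is an iterable of (seeded_cells, sphere_volume_pl) pairs;
    the slope is the occupied volume per seeded cell.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InsufficientDataError("need at least 3 (cells, volume) points")
    cells, vols = pts[:, 0], pts[:, 1]
    if len(np.unique(cells)) < 2:
        raise InsufficientDataError(
            "need at least 2 distinct seeding densities (rank-deficient design)"
        )
    X = sm.add_constant(cells)
    fit = sm.OLS(vols, X).fit()
    ci = fit.conf_int(alpha)
    return SlopeFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        stderr=float(fit.bse[1]),
    )


def aggregate_replicates(df, by, value_col="value"):
    """Per-condition mean +/- SD over replicate spheroids (long-format df)."""
    g = df.groupby(list(by))[value_col]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "value_mean", "std": "value_sd",
                               "count": "n"})
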