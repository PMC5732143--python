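"""Concentration–response modelling with mono- and biphasic Hill curves.

The modelling surface follows the Model/Results convention: build a
:class:`DoseResponseModel` from replicate data normalized to the vehicle
control, call :meth:`~DoseResponseModel.fit`, and read estimates,
uncertainties and diagnostics off the returned
:class:`DoseResponseResults` (``summary()`` prints the fit table).

Two mean functions are supported, both monotone between a zero-dose
asymptote ``left`` and a saturating asymptote ``right``:

* monophasic four-parameter logistic (4PL)::

      y(c) = left + (right - left) / (1 + (ec50 / c)^h)

* biphasic double-Hill mixture sharing the asymptotes and splitting the
  span with a mixing fraction ``f`` in (0, 1)::

      y(c) = left + (right - left) * [ f * S(c; ec50_1, h1)
                                     + (1 - f) * S(c; ec50_2, h2) ]

  with ``S(c; e, h) = c^h / (c^h + e^h)`` and ``ec50_1 < ec50_2`` enforced.
  Shared asymptotes stabilize the 8-to-9-point fits typical of one plate.

Fits run on log10 concentration with multi-start least squares; the vehicle
(zero) condition anchors the normalization but is excluded from the fit.
EC50s landing outside the tested range are reported censored (">top" /
"<bottom"), mirroring how saturating curves are tabulated.  Model choice
between the two fits uses the small-sample-corrected information criterion
(AICc), with ties resolved toward the monophasic model, and a biphasic fit
whose phases are separated by less than 0.5 log10 units falls back to the
monophasic one (they are not identifiable at plate-scale replication).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .exceptions import (
    FitError,
    InsufficientDataError,
    NormalizationError,
    ValidationError,
)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: minimum log10 separation below which two phases are not identifiable
MIN_PHASE_SEPARATION = 0.5


def stars_for(p: float) -> str:
    for level, label in STAR_LEVELS:
        if p < level:
            return label
    return ""


@dataclass
class DoseResponseCurve:
    """Replicate responses per concentration, normalized to vehicle mean = 1."""

    parameter: str
    concentrations: np.ndarray  # ascending, includes 0 (vehicle)
    responses: dict  # concentration -> 1-D array of replicate values
    direction: str = "auto"  # 'increase' | 'decrease' | 'auto'

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if 0.0 not in self.responses:
            raise ValidationError("vehicle (0) condition required")
        if self.direction == "auto":
            self.direction = self._infer_direction()

    def _infer_direction(self) -> str:
        means = [np.mean(self.responses[c]) for c in self.concentrations]
        return "increase" if means[-1] >= means[0] else "decrease"

    @property
    def nonzero_concentrations(self) -> np.ndarray:
        return self.concentrations[self.concentrations > 0]

    def flatten(self, include_vehicle: bool = False):
        cs, ys = [], []
        for c in self.concentrations:
            if c == 0 and not include_vehicle:
                continue
            for y in np.atleast_1d(self.responses[c]):
                cs.append(c)
                ys.append(y)
        return np.asarray(cs), np.asarray(ys)


def normalize_to_control(
    raw: pd.DataFrame,
    parameter: str = "",
    conc_col: str = "concentration",
    value_col: str = "value",
    direction: str = "auto",
) -> DoseResponseCurve:
    """Divide every replicate value by the vehicle-control mean.

    ``raw`` is long-format with one row per replicate; the vehicle is the
    zero-concentration group and must have a positive mean.
    """
    if conc_col not in raw or value_col not in raw:
        raise ValidationError(f"columns {conc_col!r}, {value_col!r} required")
    vehicle = raw.loc[raw[conc_col] == 0, value_col].to_numpy(dtype=float)
    if vehicle.size == 0:
        raise NormalizationError("no vehicle (concentration 0) replicates")
    vmean = vehicle.mean()
    if vmean <= 0:
        raise NormalizationError(f"vehicle mean {vmean} is not positive")
    responses = {
        float(c): g[value_col].to_numpy(dtype=float) / vmean
        for c, g in raw.groupby(conc_col)
    }
    concentrations = np.sort(raw[conc_col].unique())
    return DoseResponseCurve(
        parameter=parameter,
        concentrations=concentrations,
        responses=responses,
        direction=direction,
    )


@dataclass
class EC50Estimate:
    value: float
    label: str = ""
    censored: str = "none"  # 'none' | 'above_max' | 'below_min'
    ci: tuple[float, float] | None = None

    def __str__(self):
        if self.censored == "above_max":
            return f">{self.value:g}"
        if self.censored == "below_min":
            return f"<{self.value:g}"
        return f"{self.value:g}"


def _hill_s(logc: np.ndarray, loge: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (h * (loge - logc)))


def _mono_predict(theta, logc):
    left, right, loge, h = theta
    return left + (right - left) * _hill_s(logc, loge, h)


def _bi_predict(theta, logc):
    left, right, loge1, dloge, h1, h2, f = theta
    s1 = _hill_s(logc, loge1, h1)
    s2 = _hill_s(logc, loge1 + dloge, h2)
    return left + (right - left) * (f * s1 + (1 - f) * s2)


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class DoseResponseResults:
    """Estimates, uncertainties and diagnostics of one dose–response fit."""

    model: str  # 'monophasic_4PL' | 'biphasic_double_hill'
    parameter: str
    params: dict
    ec50s: list
    rss: float
    n_obs: int
    aicc: float
    converged: bool
    no_effect: bool = False
    fell_back: bool = False
    cov: np.ndarray | None = None
    curve: DoseResponseCurve | None = None
    _theta: np.ndarray | None = None

    @property
    def ec50(self) -> EC50Estimate:
        """Lowest-concentration EC50 (the '-1' increment)."""
        return self.ec50s[0]

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        logc = np.log10(np.where(c > 0, c, np.nan))
        fn = _mono_predict if self.model == "monophasic_4PL" else _bi_predict
        y = fn(self._theta, logc)
        return np.where(c > 0, y, self.params["left"])

    def summary(self) -> str:
        lines = [
            f"Dose-response fit: {self.parameter or '(unnamed)'}",
            f"  model        {self.model}"
            + ("  [fallback from biphasic]" if self.fell_back else ""),
            f"  n_obs        {self.n_obs}",
            f"  RSS          {self.rss:.5g}",
            f"  AICc         {self.aicc:.4g}",
            f"  converged    {self.converged}" + ("  (no effect)" if self.no_effect else ""),
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:<12} {v:.5g}")
        for e in self.ec50s:
            ci = f"  CI [{e.ci[0]:.4g}, {e.ci[1]:.4g}]" if e.ci else ""
            lines.append(f"  EC50 {e.label or '-'}: {e}{ci}")
        return "\n".join(lines)


class DoseResponseModel:
    """Mono-/biphasic Hill model over one normalized dose–response curve."""

    def __init__(self, curve: DoseResponseCurve):
        self.curve = curve

    @classmethod
    def from_dataframe(cls, raw: pd.DataFrame, parameter: str = "", **kw):
        return cls(normalize_to_control(raw, parameter=parameter, **kw))

    # -- fitting ---------------------------------------------------------

    def fit(
        self, kind: str = "auto", n_starts: int = 8, seed: int = 0
    ) -> DoseResponseResults:
        """Fit the requested model; ``kind='auto'`` fits both and selects
        by AICc (ties toward monophasic)."""
        if kind == "monophasic":
            return self._fit_mono(n_starts, seed)
        if kind == "biphasic":
            return self._fit_bi(n_starts, seed)
        if kind == "auto":
            mono = self._fit_mono(n_starts, seed)
            try:
                bi = self._fit_bi(n_starts, seed)
            except (FitError, InsufficientDataError):
                return mono
            return select_model(mono, bi)
        raise ValidationError(f"unknown model kind {kind!r}")

    def _data(self, min_conc_count: int):
        cs, ys = self.curve.flatten()
        if len(np.unique(cs)) < min_conc_count:
            raise InsufficientDataError(
                f"need >= {min_conc_count} distinct nonzero concentrations"
            )
        return np.log10(cs), ys

    def _censor(self, loge, ci_log=None) -> EC50Estimate:
        cmin = float(self.curve.nonzero_concentrations.min())
        cmax = float(self.curve.nonzero_concentrations.max())
        ec50 = 10.0**loge
        ci = (
            tuple(10.0 ** np.clip(np.asarray(ci_log), -300, 300))
            if ci_log is not None
            else None
        )
        if ec50 > cmax:
            return EC50Estimate(value=cmax, censored="above_max", ci=ci)
        if ec50 < cmin:
            return EC50Estimate(value=cmin, censored="below_min", ci=ci)
        return EC50Estimate(value=float(ec50), ci=ci)

    def _fit_mono(self, n_starts: int, seed: int) -> DoseResponseResults:
        logc, y = self._data(4)
        lo, hi = logc.min(), logc.max()
        span = y.max() - y.min()
        bounds = (
            [y.min() - 2 * span - 0.1, y.min() - 2 * span - 0.1, lo - 2.0, 0.2],
            [y.max() + 2 * span + 0.1, y.max() + 2 * span + 0.1, hi + 2.0, 6.0],
        )
        rng = np.random.default_rng(seed)
        y0 = float(np.mean(self.curve.responses[0.0]))
        yend = float(np.mean(y[logc >= hi - 0.01]))
        starts = [[y0, yend, 0.5 * (lo + hi), 1.0]]
        for _ in range(n_starts - 1):
            starts.append(
                [y0, yend, rng.uniform(lo, hi), 10 ** rng.uniform(-0.3, 0.5)]
            )
        theta, rss, cov = _best_fit(_mono_predict, starts, bounds, logc, y)
        left, right, loge, h = theta
        se_loge = np.sqrt(cov[2, 2]) if cov is not None else np.nan
        ci_log = (
            (loge - 1.96 * se_loge, loge + 1.96 * se_loge)
            if np.isfinite(se_loge)
            else None
        )
        est = self._censor(loge, ci_log)
        est.label = _label(self.curve.parameter, 1)
        rmse = np.sqrt(rss / len(y))
        # effect size judged over the tested range, not the asymptotes: an
        # EC50 extrapolated outside the data can inflate |right - left|
        span_tested = abs(
            _mono_predict(theta, np.array([hi]))[0]
            - _mono_predict(theta, np.array([lo]))[0]
        )
        no_effect = span_tested < 2.0 * rmse
        if no_effect:
            est.censored = "above_max"
            est.value = float(self.curve.nonzero_concentrations.max())
        return DoseResponseResults(
            model="monophasic_4PL",
            parameter=self.curve.parameter,
            params={"left": left, "right": right, "log10_ec50": loge, "hill": h},
            ec50s=[est],
            rss=rss,
            n_obs=len(y),
            aicc=_aicc(rss, len(y), 4),
            converged=True,
            no_effect=no_effect,
            cov=cov,
            curve=self.curve,
            _theta=np.asarray(theta),
        )

    def _fit_bi(self, n_starts: int, seed: int) -> DoseResponseResults:
        logc, y = self._data(6)
        lo, hi = logc.min(), logc.max()
        span = y.max() - y.min()
        bounds = (
            [y.min() - 2 * span - 0.1, y.min() - 2 * span - 0.1,
             lo - 2.0, 0.0, 0.2, 0.2, 0.02],
            [y.max() + 2 * span + 0.1, y.max() + 2 * span + 0.1,
             hi + 2.0, (hi - lo) + 3.0, 6.0, 6.0, 0.98],
        )
        rng = np.random.default_rng(seed + 1)
        y0 = float(np.mean(self.curve.responses[0.0]))
        yend = float(np.mean(y[logc >= hi - 0.01]))
        third = (hi - lo) / 3.0
        starts = [[y0, yend, lo + third, third * 2, 1.0, 1.0, 0.5]]
        for _ in range(n_starts - 1):
            e1 = rng.uniform(lo, hi - 0.5)
            starts.append(
                [y0, yend, e1, rng.uniform(0.5, hi - e1 + 1.0),
                 10 ** rng.uniform(-0.2, 0.4), 10 ** rng.uniform(-0.2, 0.4),
                 rng.uniform(0.2, 0.8)]
            )
        theta, rss, cov = _best_fit(_bi_predict, starts, bounds, logc, y)
        left, right, loge1, dloge, h1, h2, f = theta
        if dloge < MIN_PHASE_SEPARATION:
            mono = self._fit_mono(n_starts, seed)
            mono.fell_back = True
            return mono
        ses = (
            np.sqrt(np.clip(np.diag(cov), 0.0, None))
            if cov is not None
            else np.full(7, np.nan)
        )
        est1 = self._censor(
            loge1,
            (loge1 - 1.96 * ses[2], loge1 + 1.96 * ses[2])
            if np.isfinite(ses[2]) else None,
        )
        est1.label = _label(self.curve.parameter, 1)
        loge2 = loge1 + dloge
        est2 = self._censor(loge2)
        est2.label = _label(self.curve.parameter, 2)
        return DoseResponseResults(
            model="biphasic_double_hill",
            parameter=self.curve.parameter,
            params={
                "left": left, "right": right,
                "log10_ec50_1": loge1, "log10_ec50_2": loge2,
                "hill_1": h1, "hill_2": h2, "fraction_1": f,
            },
            ec50s=[est1, est2],
            rss=rss,
            n_obs=len(y),
            aicc=_aicc(rss, len(y), 7),
            converged=True,
            cov=cov,
            curve=self.curve,
            _theta=np.asarray(theta),
        )

    # -- inference -------------------------------------------------------

    def test_vs_control(self) -> "SignificanceTable":
        return test_vs_control(self.curve)


def _label(parameter: str, increment: int) -> str:
    return f"{parameter}-{increment}" if parameter else f"-{increment}"


def _best_fit(predict, starts, bounds, logc, y):
    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(
                lambda th: predict(th, logc) - y, p0, bounds=bounds,
                method="trf", max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1] - 1e-12:
            best = (res, rss)
    if best is None:
        raise FitError("all fit starts failed", {"n_starts": len(starts)})
    res, rss = best
    n, p = len(y), len(res.x)
    cov = None
    if n > p:
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / (n - p)
        except np.linalg.LinAlgError:
            cov = None
    return res.x, rss, cov


def fit_monophasic(curve: DoseResponseCurve, n_starts: int = 8, seed: int = 0):
    return DoseResponseModel(curve).fit("monophasic", n_starts, seed)


def fit_biphasic(curve: DoseResponseCurve, n_starts: int = 8, seed: int = 0):
    return DoseResponseModel(curve).fit("biphasic", n_starts, seed)


def select_model(
    mono: DoseResponseResults, bi: DoseResponseResults
) -> DoseResponseResults:
    """AICc model choice; ties (and biphasic fallbacks) go monophasic."""
    if bi.model == "monophasic_4PL":  # separation guard already fell back
        return mono
    return bi if bi.aicc < mono.aicc else mono


@dataclass
class SignificanceTable:
    """Per-concentration Welch tests against the vehicle control."""

    table: pd.DataFrame  # concentration, n, mean, p_value, stars

    def stars(self, concentration: float) -> str:
        row = self.table[self.table.concentration == concentration]
        return row.stars.iloc[0] if len(row) else ""


def test_vs_control(curve: DoseResponseCurve, test: str = "welch") -> SignificanceTable:
    """Two-sample test of each concentration against vehicle.

    Welch's t by default; 'mannwhitney' for the rank alternative.  Single
    replicates give an NA p-value.  No multiplicity correction is applied
    (per-concentration stars); use `holm=True` via :func:`holm_adjust`.
    """
    vehicle = np.atleast_1d(curve.responses[0.0])
    rows = []
    for c in curve.concentrations:
        if c == 0:
            continue
        vals = np.atleast_1d(curve.responses[float(c)])
        if len(vals) < 2 or len(vehicle) < 2:
            p = np.nan
        elif test == "welch":
            p = stats.ttest_ind(vals, vehicle, equal_var=False).pvalue
        elif test == "mannwhitney":
            p = stats.mannwhitneyu(vals, vehicle).pvalue
        else:
            raise ValidationError(f"unknown test {test!r}")
        rows.append(
            {"concentration": float(c), "n": len(vals),
             "mean": float(np.mean(vals)),
             "p_value": float(p) if np.isfinite(p) else np.nan,
             "stars": stars_for(p) if np.isfinite(p) else ""}
        )
    return SignificanceTable(pd.DataFrame(rows))


def holm_adjust(sig: SignificanceTable) -> SignificanceTable:
    """Holm step-down adjustment of the per-concentration p-values."""
    from statsmodels.stats.multitest import multipletests

    df = sig.table.copy()
    ok = df.p_value.notna()
    if ok.any():
        adj = multipletests(df.loc[ok, "p_value"], method="holm")[1]
        df.loc[ok, "p_value"] = adj
        df.loc[ok, "stars"] = [stars_for(p) for p in adj]
    return SignificanceTable(df)


def simulate_curve(
    ec50s,
    hills=1.0,
    fraction: float = 0.5,
    left: float = 1.0,
    right: float = 0.25,
    concentrations=None,
    n_replicates: int = 6,
    noise_sd: float = 0.1,
    seed: int = 0,
    parameter: str = "Area",
) -> DoseResponseCurve:
    """Simulate a normalized replicate dose–response table from the
    (mono- or bi-phasic) Hill truth, with additive Gaussian noise.

    One EC50 gives 4PL data; two give the shared-asymptote double-Hill
    mixture with mixing fraction ``fraction`` on the lower-EC50 phase.
    """
    ec50s = np.atleast_1d(np.asarray(ec50s, dtype=float))
    hills = np.broadcast_to(np.atleast_1d(np.asarray(hills, float)), ec50s.shape)
    if concentrations is None:
        concentrations = np.logspace(0, 3, 9)
    concentrations = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)

    def mean_at(c):
        if c == 0:
            return left
        if len(ec50s) == 1:
            s = c ** hills[0] / (c ** hills[0] + ec50s[0] ** hills[0])
        else:
            s1 = c ** hills[0] / (c ** hills[0] + ec50s[0] ** hills[0])
            s2 = c ** hills[1] / (c ** hills[1] + ec50s[1] ** hills[1])
            s = fraction * s1 + (1 - fraction) * s2
        return left + (right - left) * s

    all_c = np.concatenate([[0.0], concentrations])
    responses = {
        float(c): mean_at(c) + rng.normal(0.0, noise_sd, n_replicates)
        for c in all_c
    }
    return DoseResponseCurve(
        parameter=parameter,
        concentrations=np.sort(all_c),
        responses=responses,
        direction="decrease" if right < left else "increase",
    )
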