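"""Bivariate scaling estimation in log-log space.

Standardized major axis (Model II) and ordinary least squares fits of
allometric power laws, slope/elevation hypothesis tests, quadratic curvature
checks, continuous piecewise (segmented) fits, and AIC model comparison.

All logarithms are base 10, the convention for allometric normalization
constants (``d0 = 10**intercept``). SMA is the estimator of choice for power
laws because it minimizes residual variation in both axes; its slope has the
closed form sign(r) * s_y / s_x, which the test suite uses as an independent
oracle on raw moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TRANSFORMS",
    "FitResult",
    "ModelComparison",
    "PiecewiseFit",
    "QuadraticResult",
    "DegenerateFitError",
    "sma_fit",
    "ols_fit",
    "sma_slope_test",
    "sma_slope_difference_test",
    "sma_elevation_test",
    "quadratic_curvature",
    "piecewise_fit",
    "model_compare",
    "tb2_decay_fit",
    "format_p",
]

#: smallest p-value printed at machine precision
P_FLOOR = 2.22e-16

TRANSFORMS = ("log10-log10", "log10-linear", "linear-log10", "none")


class DegenerateFitError(ValueError):
    """Raised when a fit is undefined (zero variance, collinearity, n too small)."""


def format_p(p: float) -> str:
    """Render a p-value, flooring at the machine-representable 2.22e-16."""
    return f"< {P_FLOOR:.3g}" if p < P_FLOOR else f"{p:.3g}"


@dataclass(frozen=True)
class FitResult:
    """A fitted bivariate scaling relationship on a transformed scale.

    ``slope`` is the scaling exponent (alpha or beta for log10-log10 power
    laws); ``intercept`` the log10 normalization, so d0 = 10**intercept.
    Sample moments (x_mean, y_mean, sx, sy, r) are retained so downstream
    hypothesis tests need no access to the raw data.
    """

    method: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r2: float
    p: float
    n: int
    x_var: str = "x"
    y_var: str = "y"
    transform: str = "log10-log10"
    x_mean: float = field(default=np.nan, repr=False)
    y_mean: float = field(default=np.nan, repr=False)
    sx: float = field(default=np.nan, repr=False)
    sy: float = field(default=np.nan, repr=False)
    r: float = field(default=np.nan, repr=False)

    @property
    def slope_se(self) -> float:
        """Large-sample standard error of the slope."""
        return abs(self.slope) * np.sqrt(max(1.0 - self.r2, 0.0) / (self.n - 2))

    def to_dict(self) -> dict:
        return {
            "method": self.method, "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci_low": self.slope_ci[0], "slope_ci_high": self.slope_ci[1],
            "r2": self.r2, "p": self.p, "p_text": format_p(self.p),
            "n": self.n, "x_var": self.x_var, "y_var": self.y_var,
            "transform": self.transform,
        }


def _transform(x, y, transform):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    xt, yt = transform.split("-") if transform != "none" else ("linear", "linear")
    if xt == "log10":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive x")
        x = np.log10(x)
    if yt == "log10":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive y")
        y = np.log10(y)
    return x, y


def _moments(x, y):
    n = x.size
    if n < 3:
        raise DegenerateFitError("need n >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or not np.isfinite(sx):
        raise DegenerateFitError("zero variance in x")
    r = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])
    return n, float(x.mean()), float(y.mean()), float(sx), float(sy), r


def _corr_p(r, n):
    """Two-sided p for zero correlation (Pearson t-test)."""
    r = np.clip(r, -1.0, 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def sma_fit(x, y, transform="log10-log10", x_var="x", y_var="y") -> FitResult:
    """Standardized major axis fit on the transformed scale.

    slope = sign(r) * s_y/s_x, intercept = ybar - slope * xbar. The 95% CI is
    the standard SMA interval: with B = F(0.95; 1, n-2) * (1 - r^2) / (n - 2),
    CI = slope * (sqrt(B + 1) +/- sqrt(B)). p comes from the Pearson
    correlation test.
    """
    xt, yt = _transform(x, y, transform)
    n, xm, ym, sx, sy, r = _moments(xt, yt)
    # a constant y can leave sy at roundoff level (~1e-16) rather than an
    # exact zero; treat variance at machine-noise scale as degenerate too
    if sy <= 1e-13 * max(abs(ym), 1.0):
        raise DegenerateFitError("zero variance in y")
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = ym - slope * xm
    B = stats.f.ppf(0.95, 1, n - 2) * (1 - r**2) / (n - 2)
    ci = (slope * (np.sqrt(B + 1) - np.sqrt(B) * sign * np.sign(slope)),
          slope * (np.sqrt(B + 1) + np.sqrt(B) * sign * np.sign(slope)))
    # for positive slope the interval is slope*(sqrt(B+1)-sqrt(B)) .. *(+);
    # for negative slope multiplication flips the order, so sort:
    ci = (min(ci), max(ci))
    return FitResult("SMA", float(slope), float(intercept), ci,
                     r**2, _corr_p(r, n), n, x_var, y_var, transform,
                     xm, ym, sx, sy, r)


def ols_fit(x, y, transform="log10-log10", x_var="x", y_var="y") -> FitResult:
    """Ordinary least squares fit on the transformed scale.

    Under added y-noise the OLS slope attenuates toward r * (s_y/s_x), i.e.
    it is never steeper in magnitude than the SMA slope on the same data.
    """
    xt, yt = _transform(x, y, transform)
    n, xm, ym, sx, sy, r = _moments(xt, yt)
    slope = r * sy / sx
    intercept = ym - slope * xm
    se = (sy / sx) * np.sqrt(max(1 - r**2, 0.0) / (n - 2))
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (slope - tcrit * se, slope + tcrit * se)
    return FitResult("OLS", float(slope), float(intercept), ci,
                     r**2, _corr_p(r, n), n, x_var, y_var, transform,
                     xm, ym, sx, sy, r)


def sma_slope_test(fit: FitResult, b0: float) -> float:
    """Two-sided p for H0: SMA slope == b0.

    Exploits the SMA identity: the slope equals b0 iff the residual and major
    axes, (y - b0*x) and (y + b0*x), are uncorrelated; p is the Pearson test
    on that derived correlation.
    """
    if not np.isfinite(b0) or b0 == 0:
        raise ValueError("b0 must be finite and non-zero")
    sx, sy, r, n = fit.sx, fit.sy, fit.r, fit.n
    cov = sy**2 - b0**2 * sx**2
    v1 = sy**2 - 2 * b0 * r * sx * sy + b0**2 * sx**2
    v2 = sy**2 + 2 * b0 * r * sx * sy + b0**2 * sx**2
    if v1 <= 0 or v2 <= 0:
        return 0.0
    return _corr_p(cov / np.sqrt(v1 * v2), n)


def _check_compatible(fit_a: FitResult, fit_b: FitResult):
    if fit_a.transform != fit_b.transform:
        raise ValueError("fits use incompatible transforms")


def sma_slope_difference_test(fit_a: FitResult, fit_b: FitResult) -> float:
    """Wald test for equality of two independent SMA slopes (symmetric)."""
    _check_compatible(fit_a, fit_b)
    z = (fit_a.slope - fit_b.slope) / np.hypot(fit_a.slope_se, fit_b.slope_se)
    return float(2 * stats.norm.sf(abs(z)))


def sma_elevation_test(fit_a: FitResult, fit_b: FitResult) -> float:
    """Wald test for equality of intercepts under a common SMA slope."""
    _check_compatible(fit_a, fit_b)
    wa, wb = 1 / fit_a.slope_se**2, 1 / fit_b.slope_se**2
    b_common = (wa * fit_a.slope + wb * fit_b.slope) / (wa + wb)
    va, vb = [
        f.sy**2 * max(1 - f.r**2, 0.0) / f.n + f.x_mean**2 / (wa + wb)
        for f in (fit_a, fit_b)
    ]
    aa = fit_a.y_mean - b_common * fit_a.x_mean
    ab = fit_b.y_mean - b_common * fit_b.x_mean
    z = (aa - ab) / np.sqrt(va + vb)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class QuadraticResult:
    coef: float            # coefficient on x^2; > 0 means upward curvature
    ci: tuple[float, float]
    p: float
    coeffs: tuple[float, float, float]  # (intercept, linear, quadratic)


def quadratic_curvature(x, y) -> QuadraticResult:
    """OLS fit of y on {1, x, x^2} for already-transformed (log-log) data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise DegenerateFitError("need n >= 4 for a quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateFitError("collinear design (x has < 3 distinct values)")
    import statsmodels.api as sm
    res = sm.OLS(y, X).fit()
    lo, hi = res.conf_int()[2]
    return QuadraticResult(float(res.params[2]), (float(lo), float(hi)),
                           float(res.pvalues[2]), tuple(map(float, res.params)))


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float
    left_slope: float
    right_slope: float
    intercept: float       # value of the fitted curve at the breakpoint
    rss: float
    rss_line: float        # single-line RSS for comparison
    meaningful: bool       # RSS improvement over one line above tolerance

    def predict(self, x):
        x = np.asarray(x, float)
        return (self.intercept
                + np.where(x < self.breakpoint, self.left_slope,
                           self.right_slope) * (x - self.breakpoint))


def piecewise_fit(x, y, n_breakpoints: int = 1, n_grid: int = 200,
                  rel_tol: float = 1e-3) -> PiecewiseFit:
    """Continuous two-segment least squares with a grid-searched breakpoint.

    Candidate breakpoints are interior x-quantiles (1%-99%, ``n_grid``
    points); the RSS-minimizing candidate wins, with deterministic ties
    broken toward the smaller breakpoint. A break is flagged meaningful only
    when it improves on the single-line RSS by more than ``rel_tol``
    relatively (guarded against exactly-linear data where both RSS vanish).
    """
    if n_breakpoints != 1:
        raise NotImplementedError("only one breakpoint is supported")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 10:
        raise DegenerateFitError("need n >= 10 for a piecewise fit")
    qs = np.quantile(x, np.linspace(0.01, 0.99, n_grid))
    ux = np.unique(x)
    cands = [c for c in np.unique(qs)
             if (ux < c).sum() >= 5 and (ux > c).sum() >= 5]
    if not cands:
        raise DegenerateFitError("too few distinct x values on each side")

    ones = np.ones_like(x)
    # single-line baseline
    coef_l, res_l, *_ = np.linalg.lstsq(np.column_stack([ones, x]), y, rcond=None)
    rss_line = float(((y - (coef_l[0] + coef_l[1] * x))**2).sum())

    best = None
    for c in cands:  # ascending, strict < keeps the smaller tie-winner
        X = np.column_stack([ones, x - c, np.maximum(x - c, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef)**2).sum())
        if best is None or rss < best[0] * (1 - 1e-12):
            best = (rss, c, coef)
    rss, c, coef = best
    a, b_left, b_extra = coef
    tss = float(((y - y.mean())**2).sum())
    meaningful = (rss_line - rss) > rel_tol * max(rss_line, 1e-12 * max(tss, 1.0))
    return PiecewiseFit(float(c), float(b_left), float(b_left + b_extra),
                        float(a), rss, rss_line, bool(meaningful))


@dataclass(frozen=True)
class ModelComparison:
    """Per-candidate AIC table on a common log10-response scale.

    ``winner`` applies the parsimony convention: among candidates within
    ``parsimony_delta`` AIC units of the minimum, the one with fewest
    parameters wins. ``aic_winner`` is the raw AIC argmin.
    """

    table: list[dict]
    winner: str
    aic_winner: str


_CANDIDATE_ORDER = ["power", "exponential", "logarithmic", "quadratic", "piecewise"]


def _fit_logarithmic(x, ylog):
    """y = a + b*ln(x), fitted on the log10-y response scale."""
    from scipy.optimize import curve_fit
    lnx = np.log(x)
    # initialize from OLS on the raw response
    b0, a0 = np.polyfit(lnx, 10.0**ylog, 1)

    def f(xv, a, b):
        return np.log10(np.clip(a + b * np.log(xv), 1e-300, None))

    popt, _ = curve_fit(f, x, ylog, p0=[max(a0, 1e-6), b0], maxfev=5000)
    pred = f(x, *popt)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("logarithmic candidate produced non-finite predictions")
    return float(((ylog - pred)**2).sum())


def model_compare(x, y, parsimony_delta: float = 2.0) -> ModelComparison:
    """Compare power, exponential, logarithmic, quadratic, and piecewise fits.

    All candidates are fitted with log10(y) as the response so the RSS-based
    AIC = n*ln(RSS/n) + 2k is comparable across them; k counts mean-function
    parameters, with the piecewise breakpoint counted as a parameter.
    Candidates that fail to fit are reported as unavailable, never fatal.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("model_compare requires strictly positive x and y")
    n = x.size
    ylog = np.log10(y)
    xlog = np.log10(x)

    def lin_rss(design):
        coef, *_ = np.linalg.lstsq(design, ylog, rcond=None)
        return float(((ylog - design @ coef)**2).sum())

    ones = np.ones_like(x)
    rows = []
    for label, k, fitter in [
        ("power", 2, lambda: lin_rss(np.column_stack([ones, xlog]))),
        ("exponential", 2, lambda: lin_rss(np.column_stack([ones, x]))),
        ("logarithmic", 2, lambda: _fit_logarithmic(x, ylog)),
        ("quadratic", 3, lambda: lin_rss(np.column_stack([ones, xlog, xlog**2]))),
        ("piecewise", 4, lambda: piecewise_fit(xlog, ylog).rss),
    ]:
        try:
            rss = fitter()
            aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
            rows.append({"model": label, "k": k, "rss": rss, "aic": float(aic)})
        except Exception as exc:  # candidate unavailable, not fatal
            rows.append({"model": label, "k": k, "rss": None, "aic": None,
                         "error": str(exc)})

    avail = [r for r in rows if r["aic"] is not None]
    if not avail:
        raise DegenerateFitError("no candidate model could be fitted")
    aic_min = min(r["aic"] for r in avail)
    for r in rows:
        r["delta_aic"] = None if r["aic"] is None else r["aic"] - aic_min
    aic_winner = min(avail, key=lambda r: (r["aic"],
                                           _CANDIDATE_ORDER.index(r["model"])))
    close = [r for r in avail if r["delta_aic"] <= parsimony_delta]
    winner = min(close, key=lambda r: (r["k"], r["aic"],
                                       _CANDIDATE_ORDER.index(r["model"])))
    return ModelComparison(rows, winner["model"], aic_winner["model"])


def tb2_decay_fit(tb2, L_rel) -> FitResult:
    """SMA fit of log10((t/b)^2) on relative path position L/H.

    An exponential decay (t/b)^2 = c * exp(-k * L/H) appears as a straight
    line of slope -k/ln(10) on this scale, so the fitted slope times -ln(10)
    recovers the decay rate.
    """
    tb2 = np.asarray(tb2, float)
    L_rel = np.asarray(L_rel, float)
    if np.any(tb2 <= 0):
        raise ValueError("tb2 must be strictly positive")
    if np.any((L_rel <= 0) | (L_rel > 1)):
        raise ValueError("L_rel must lie in (0, 1]")
    return sma_fit(L_rel, tb2, transform="linear-log10",
                   x_var="L_rel", y_var="tb2")
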