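"""Bin-balanced subsampling and bootstrapping before model fitting.

Conduit tables are severely unbalanced: thick organs contribute orders of
magnitude more measured conduits than leaves or fine roots, which biases
pooled regressions toward the heavily sampled path positions. The remedy
implemented here divides the predictor (path length L or organ diameter D)
into equally spaced logarithmic bins and then either

* subsamples every bin, without replacement, down to the smallest occupied
  bin count (n_min), or
* bootstraps every bin up to the largest occupied bin count (n_max) by
  keeping all raw records and adding n_max - n_bin records drawn with
  replacement,

repeating the procedure over many seeded iterations and aggregating the
per-iteration fits, with a running-mean stability diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scaling

__all__ = [
    "BinningPlan",
    "BinningInfeasibleError",
    "FitSpec",
    "ResampleOutcome",
    "plan_bins",
    "assign_bins",
    "subsample_balance",
    "bootstrap_balance",
    "iterate_fit",
]


class BinningInfeasibleError(ValueError):
    """No bin count >= 2 satisfies the per-bin minimum."""


@dataclass(frozen=True)
class BinningPlan:
    """Equally spaced log10 bins over one predictor variable.

    ``n_bins`` is the largest bin count (up to ``max_bins``) whose every
    *occupied* bin holds at least ``min_count`` records; interior bins that
    happen to be empty are treated as absent, not zero-count, and listed in
    ``empty_bins``. n_min/n_max are extrema over occupied bins.
    """

    variable: str
    edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    min_count: int
    empty_bins: tuple[int, ...] = ()

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_min(self) -> int:
        return int(self.counts[self.occupied].min())

    @property
    def n_max(self) -> int:
        return int(self.counts[self.occupied].max())


def _bin_index(logv: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin assignment: edge values go to the right bin, except the final
    edge (the last bin is closed on the right)."""
    idx = np.searchsorted(edges, logv, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def plan_bins(values, min_count: int = 100, max_bins: int = 30,
              variable: str = "L") -> BinningPlan:
    """Find the finest equally-log-spaced binning meeting the per-bin minimum.

    Searches n_bins downward from ``max_bins`` and returns the first (i.e.
    largest) bin count for which every occupied bin holds >= ``min_count``
    values and at least two bins are occupied.
    """
    v = np.asarray(values, float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("binning variable must be finite and strictly positive")
    logv = np.log10(v)
    lo, hi = logv.min(), logv.max()
    if lo == hi:
        raise BinningInfeasibleError("all values identical: a single occupied bin")
    for n_bins in range(max_bins, 1, -1):
        edges = np.linspace(lo, hi, n_bins + 1)
        counts = np.bincount(_bin_index(logv, edges), minlength=n_bins)
        occ = counts > 0
        if occ.sum() >= 2 and counts[occ].min() >= min_count:
            return BinningPlan(variable, edges, counts, min_count,
                               tuple(np.flatnonzero(~occ)))
    raise BinningInfeasibleError(
        f"no binning with >= 2 bins keeps every occupied bin at n >= {min_count}")


def assign_bins(values, plan: BinningPlan) -> np.ndarray:
    """Bin index for each value under an existing plan."""
    return _bin_index(np.log10(np.asarray(values, float)), plan.edges)


def _balanced_indices(bin_groups: list[np.ndarray], mode: str,
                      plan: BinningPlan, rng: np.random.Generator) -> np.ndarray:
    """Row positions of one balanced replicate. ``bin_groups`` holds the raw
    row positions of each occupied bin, in bin order."""
    if mode == "subsample":
        n_min = plan.n_min
        parts = [rng.choice(g, size=n_min, replace=False) for g in bin_groups]
    elif mode == "bootstrap":
        n_max = plan.n_max
        parts = []
        for g in bin_groups:
            extra = n_max - g.size
            if extra:
                parts.append(np.concatenate([g, rng.choice(g, size=extra,
                                                           replace=True)]))
            else:
                parts.append(g)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.concatenate(parts)


def _bin_groups(df: pd.DataFrame, plan: BinningPlan, column: str):
    idx = assign_bins(df[column].to_numpy(), plan)
    return [np.flatnonzero(idx == b)
            for b in np.flatnonzero(plan.occupied)]


def subsample_balance(records: pd.DataFrame, plan: BinningPlan, seed,
                      column: str | None = None) -> pd.DataFrame:
    """Exactly n_min records per occupied bin, sampled without replacement."""
    column = column or _default_column(plan)
    rng = np.random.default_rng(seed)
    pos = _balanced_indices(_bin_groups(records, plan, column),
                            "subsample", plan, rng)
    return records.iloc[pos].reset_index(drop=True)


def bootstrap_balance(records: pd.DataFrame, plan: BinningPlan, seed,
                      column: str | None = None) -> pd.DataFrame:
    """Every occupied bin grown to exactly n_max records: all raw records of
    the bin plus n_max - n_bin drawn with replacement from the same bin."""
    column = column or _default_column(plan)
    rng = np.random.default_rng(seed)
    pos = _balanced_indices(_bin_groups(records, plan, column),
                            "bootstrap", plan, rng)
    return records.iloc[pos].reset_index(drop=True)


def _default_column(plan: BinningPlan) -> str:
    return {"L": "L_m", "D": "D_mm"}.get(plan.variable, plan.variable)


@dataclass(frozen=True)
class FitSpec:
    """Which bivariate relationship to fit on each balanced replicate."""

    x: str
    y: str = "d_um"
    transform: str = "log10-log10"
    method: str = "SMA"

    def fit(self, x, y) -> scaling.FitResult:
        fn = scaling.sma_fit if self.method.upper() == "SMA" else scaling.ols_fit
        return fn(x, y, self.transform, x_var=self.x, y_var=self.y)


@dataclass(frozen=True)
class ResampleOutcome:
    """Distribution of fit results across balanced resampling iterations.

    ``aggregate_slope`` is the mean of per-iteration slopes and
    ``aggregate_ci`` the 2.5/97.5 percentiles of those slopes. Per-iteration
    parametric CIs are also stored; under bootstrap augmentation they reflect
    the inflated n_max-per-bin sample size and are anti-conservative, so the
    percentile view is the headline one.
    """

    mode: str
    slopes: np.ndarray = field(repr=False)
    intercepts: np.ndarray = field(repr=False)
    parametric_cis: np.ndarray = field(repr=False)  # (n_iter, 2)
    stability_trace: np.ndarray = field(repr=False)
    converged: bool
    stability_tol: float
    plan: BinningPlan
    fit_spec: FitSpec

    @property
    def n_iterations(self) -> int:
        return self.slopes.size

    @property
    def aggregate_slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def aggregate_intercept(self) -> float:
        return float(self.intercepts.mean())

    @property
    def aggregate_ci(self) -> tuple[float, float]:
        return (float(np.percentile(self.slopes, 2.5)),
                float(np.percentile(self.slopes, 97.5)))

    def to_dict(self, include_iterations: bool = False) -> dict:
        out = {
            "mode": self.mode,
            "aggregate_slope": self.aggregate_slope,
            "aggregate_intercept": self.aggregate_intercept,
            "aggregate_ci": list(self.aggregate_ci),
            "mean_parametric_ci": list(map(float, self.parametric_cis.mean(axis=0))),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "stability_tol": self.stability_tol,
            "n_bins": self.plan.n_bins,
            "bin_counts": [int(c) for c in self.plan.counts],
            "n_min": self.plan.n_min,
            "n_max": self.plan.n_max,
            "fit": {"x": self.fit_spec.x, "y": self.fit_spec.y,
                    "transform": self.fit_spec.transform,
                    "method": self.fit_spec.method},
        }
        if include_iterations:
            out["slopes"] = [float(s) for s in self.slopes]
        return out


def iterate_fit(records: pd.DataFrame, binning_variable: str, mode: str,
                fit_spec: FitSpec, n_iterations: int, seed,
                stability_tol: float = 1e-3, min_count: int = 100,
                max_bins: int = 30, plan: BinningPlan | None = None
                ) -> ResampleOutcome:
    """Repeat balance-then-fit for ``n_iterations`` seeded iterations.

    The binning plan is computed once on the raw records. Convergence is
    declared when the running mean of the slope moves by less than
    ``stability_tol`` over the last half of the iterations. Any iteration
    whose fit fails aborts with the iteration index.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    column = {"L": "L_m", "D": "D_mm"}.get(binning_variable, binning_variable)
    if plan is None:
        plan = plan_bins(records[column].to_numpy(), min_count=min_count,
                         max_bins=max_bins, variable=binning_variable)
    groups = _bin_groups(records, plan, column)
    xall = records[fit_spec.x].to_numpy(float)
    yall = records[fit_spec.y].to_numpy(float)

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    streams = ss.spawn(n_iterations)
    slopes = np.empty(n_iterations)
    intercepts = np.empty(n_iterations)
    cis = np.empty((n_iterations, 2))
    for i in range(n_iterations):
        rng = np.random.default_rng(streams[i])
        pos = _balanced_indices(groups, mode, plan, rng)
        try:
            fit = fit_spec.fit(xall[pos], yall[pos])
        except Exception as exc:
            raise RuntimeError(f"fit failed at iteration {i}: {exc}") from exc
        slopes[i] = fit.slope
        intercepts[i] = fit.intercept
        cis[i] = fit.slope_ci

    trace = np.cumsum(slopes) / np.arange(1, n_iterations + 1)
    tail = trace[n_iterations // 2:]
    converged = bool(tail.max() - tail.min() < stability_tol)
    return ResampleOutcome(mode, slopes, intercepts, cis, trace, converged,
                           stability_tol, plan, fit_spec)
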