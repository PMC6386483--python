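"""Distribution analysis across samples, groups and time points.

Per-time-point boxplot statistics with Tukey-fence outlier detection, plus
two straight-line trend fits over time:

* robust linear: iteratively reweighted least squares with Huber weights
  (tuning constant 1.345 times the robust scale MAD/0.6745), insensitive
  to gross outliers;
* chi-square: weighted least squares minimizing
  chi^2 = sum((y_i - a - b t_i) / sigma_i)^2, solved in closed form from
  the weighted normal equations.  When per-point uncertainties are not
  supplied, sigma_i is the replicate standard deviation at t_i (falling
  back to 1.0 for singleton or zero-spread time points).

Quartiles use linear interpolation of order statistics; this convention is
stated explicitly because it affects which values are called outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .project_io import PeakTable, SampleMetadata, define_groups

__all__ = [
    "BoxplotStats",
    "FitResult",
    "boxplot_stats",
    "robust_linear_fit",
    "chi_square_fit",
    "distribution_panel",
    "DistributionPanel",
]


@dataclass
class BoxplotStats:
    """Five-number summary with Tukey fences for one set of values."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]
    n: int
    fence_coef: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def fence_low(self) -> float:
        return self.q1 - self.fence_coef * self.iqr

    @property
    def fence_high(self) -> float:
        return self.q3 + self.fence_coef * self.iqr


def boxplot_stats(values: Sequence[float], fence_coef: float = 1.5) -> BoxplotStats:
    """Quartiles, whiskers at the most extreme in-fence data, and outliers.

    Fences sit at Q1 - coef*IQR and Q3 + coef*IQR (Tukey's coef = 1.5 by
    default); values strictly outside the fences are outliers; whiskers
    are the most extreme values inside the fences.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - fence_coef * iqr, q3 + fence_coef * iqr
    inside = arr[(arr >= lo) & (arr <= hi)]
    outliers = arr[(arr < lo) | (arr > hi)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
        n=int(arr.size),
        fence_coef=fence_coef,
    )


@dataclass
class FitResult:
    """A straight-line fit y = intercept + slope * t."""

    method: str
    slope: float
    intercept: float
    residuals: np.ndarray
    objective: float
    iterations: int = 0

    def predict(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def _wls_line(t: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares line via the normal equations."""
    sw = w.sum()
    st = (w * t).sum()
    sy = (w * y).sum()
    stt = (w * t * t).sum()
    sty = (w * t * y).sum()
    denom = sw * stt - st * st
    if denom == 0:
        raise ValueError("all time values identical: slope unidentifiable")
    slope = (sw * sty - st * sy) / denom
    intercept = (sy - slope * st) / sw
    return float(slope), float(intercept)


def robust_linear_fit(
    t: Sequence[float],
    y: Sequence[float],
    max_iter: int = 100,
    tol: float = 1e-10,
    tuning: float = 1.345,
    weight_fn: str = "huber",
) -> FitResult:
    """Huber IRLS straight-line fit, robust to gross outliers.

    Starts from ordinary least squares; at each iteration the robust scale
    is MAD/0.6745 of the residuals and points with |residual| beyond
    ``tuning * scale`` are down-weighted (Huber: w = c/|r|; bisquare
    alternative available via ``weight_fn="bisquare"``).  On outlier-free
    data all weights stay 1 and the result equals ordinary least squares.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal length")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time values")
    if weight_fn not in ("huber", "bisquare"):
        raise ValueError(f"unknown weight function {weight_fn!r}")

    w = np.ones_like(y)
    slope, intercept = _wls_line(t, y, w)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        resid = y - intercept - slope * t
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            break  # perfect fit (or degenerate residuals): weights all 1
        c = tuning * scale
        a = np.abs(resid)
        if weight_fn == "huber":
            w = np.where(a <= c, 1.0, c / np.where(a == 0, 1.0, a))
        else:  # Tukey bisquare
            u = resid / (4.685 * scale)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            if w.sum() == 0:
                w = np.ones_like(y)
        new_slope, new_intercept = _wls_line(t, y, w)
        if abs(new_slope - slope) < tol and abs(new_intercept - intercept) < tol:
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    resid = y - intercept - slope * t
    return FitResult(
        method="robust_linear",
        slope=slope,
        intercept=intercept,
        residuals=resid,
        objective=float((w * resid**2).sum()),
        iterations=iterations,
    )


def chi_square_fit(
    t: Sequence[float],
    y: Sequence[float],
    sigma: Sequence[float] | None = None,
) -> FitResult:
    """Closed-form weighted least-squares line minimizing chi-square.

    ``sigma`` holds per-point uncertainties (> 0).  When omitted, each
    point's sigma is the standard deviation of the replicates sharing its
    time value, with 1.0 substituted for singleton or zero-spread time
    points.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal length")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time values")
    if sigma is None:
        sig = np.ones_like(y)
        for tv in np.unique(t):
            mask = t == tv
            if mask.sum() > 1:
                sd = float(y[mask].std(ddof=1))
                if sd > 0:
                    sig[mask] = sd
    else:
        sig = np.asarray(sigma, dtype=float)
        if sig.shape != y.shape:
            raise ValueError("sigma must match y in length")
        if np.any(sig <= 0):
            raise ValueError("all sigma values must be positive")
    w = 1.0 / sig**2
    slope, intercept = _wls_line(t, y, w)
    resid = y - intercept - slope * t
    return FitResult(
        method="chi_square",
        slope=slope,
        intercept=intercept,
        residuals=resid,
        objective=float(((resid / sig) ** 2).sum()),
    )


@dataclass
class DistributionPanel:
    """Per-group boxplot stats over time, trend fit, and sample scatter."""

    molecule: str
    groups: dict[str, dict[float, BoxplotStats]]  # group -> time -> stats
    fits: dict[str, FitResult]
    scatter: dict[str, list[tuple[str, float, float]]]  # (sample, time, value)
    times: list[float]


def distribution_panel(
    table: PeakTable,
    metadata: SampleMetadata,
    molecule: str,
    groups: tuple[str, str] | None = None,
    grouping_features: Sequence[str] = ("group",),
    include_samples: Sequence[str] | None = None,
    include_times: Sequence[float] | None = None,
    fit: str = "robust_linear",
    fence_coef: float = 1.5,
) -> DistributionPanel:
    """Side-by-side distribution view of one molecule.

    With a ``groups`` pair, two parallel result sets share one time axis
    (the split comparison view); with ``groups=None`` a single panel over
    all samples is produced.  ``include_samples`` / ``include_times``
    dynamically deselect samples and time points; a group whose selection
    becomes empty at a time point simply omits that time point.
    """
    profile = table.profile(molecule)
    all_groups = define_groups(metadata, list(grouping_features))
    if groups is None:
        panel_groups = {"all": list(metadata.sample_ids)}
    else:
        for label in groups:
            if label not in all_groups:
                raise KeyError(f"unknown group label {label!r}")
        panel_groups = {label: all_groups[label] for label in groups}

    sample_ok = set(include_samples) if include_samples is not None else None
    time_ok = set(float(t) for t in include_times) if include_times is not None else None

    value_of = dict(zip(table.sample_ids, profile))
    stats_by_group: dict[str, dict[float, BoxplotStats]] = {}
    fits: dict[str, FitResult] = {}
    scatter: dict[str, list[tuple[str, float, float]]] = {}
    times_seen: set[float] = set()
    for label, samples in panel_groups.items():
        kept = [
            s
            for s in samples
            if (sample_ok is None or s in sample_ok)
            and (time_ok is None or metadata.time_of(s) in time_ok)
        ]
        if not kept:
            raise ValueError(f"selection leaves no samples in group {label!r}")
        pts = [(s, metadata.time_of(s), float(value_of[s])) for s in kept]
        scatter[label] = pts
        by_time: dict[float, list[float]] = {}
        for _, tv, v in pts:
            by_time.setdefault(tv, []).append(v)
        stats_by_group[label] = {
            tv: boxplot_stats(vals, fence_coef) for tv, vals in sorted(by_time.items())
        }
        times_seen.update(by_time)
        tvec = np.array([p[1] for p in pts])
        yvec = np.array([p[2] for p in pts])
        if len(np.unique(tvec)) >= 2:
            fits[label] = (
                robust_linear_fit(tvec, yvec) if fit == "robust_linear" else chi_square_fit(tvec, yvec)
            )
    return DistributionPanel(
        molecule=molecule,
        groups=stats_by_group,
        fits=fits,
        scatter=scatter,
        times=sorted(times_seen),
    )
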