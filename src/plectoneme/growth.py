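"""Growth kinetics and plasmid stability.

Specific growth rate is estimated from the exponential phase of a growth
curve as the least-squares slope of log2(cell density) versus time, in
divisions per hour -- during balanced exponential growth Y(t) = Y0 * 2^(mu t),
so the log2-linear slope is the division rate.  (A literal linear slope
dY/dt is available behind a flag, but its units are density per hour, not
divisions per hour.)  The exponential window can be supplied or found
automatically as the longest contiguous run of points whose log2-linear fit
reaches a target R^2.

Plasmid retention over serial passages is the ratio of colony-forming
units on selective versus non-selective plates at each sampled generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "RetentionSeries",
    "ExponentialWindowNotFound",
    "specific_growth_rate",
    "exponential_window",
    "plasmid_retention",
]


class ExponentialWindowNotFound(ValueError):
    """No contiguous run of points reaches the requested fit quality."""


@dataclass(frozen=True)
class GrowthCurve:
    """One strain's growth curve: strictly increasing times, positive densities."""

    times_h: tuple[float, ...]
    densities: tuple[float, ...]
    strain: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.densities, dtype=float)
        if len(t) != len(y):
            raise ValueError("times and densities must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y <= 0):
            raise ValueError("densities must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times_h, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.densities, dtype=float)


@dataclass(frozen=True)
class GrowthFit:
    """Specific growth rate with fit diagnostics."""

    mu: float  # divisions per hour (log2 slope) or density/h in literal mode
    stderr: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    literal_dY_dt: bool = False


def _window_mask(t: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(t, dtype=bool)
    lo, hi = window
    if hi < lo:
        raise ValueError("window must be (start, end) with end >= start")
    return (t >= lo) & (t <= hi)


def specific_growth_rate(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    literal_dY_dt: bool = False,
) -> GrowthFit:
    """Least-squares growth rate over ``window`` (inclusive; default: all points).

    Default: slope of log2(density) vs time -> divisions per hour.  With
    ``literal_dY_dt`` the raw density is regressed instead (slope in
    density units per hour).  Requires >= 3 points in the window.
    """
    mask = _window_mask(curve.t, window)
    t = curve.t[mask]
    y = curve.y[mask]
    if len(t) < 3:
        raise ValueError(f"window contains {len(t)} points; need >= 3")
    response = y if literal_dY_dt else np.log2(y)
    fit = stats.linregress(t, response)
    return GrowthFit(
        mu=float(fit.slope),
        stderr=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        n_points=len(t),
        window=(float(t[0]), float(t[-1])),
        literal_dY_dt=literal_dY_dt,
    )


def _run_r_squared(t: np.ndarray, log2y: np.ndarray) -> float:
    fit = stats.linregress(t, log2y)
    if np.isnan(fit.rvalue):  # constant response: no exponential signal
        return 0.0
    return float(fit.rvalue**2)


def exponential_window(
    curve: GrowthCurve, r2_min: float = 0.99, min_points: int = 3
) -> tuple[float, float]:
    """Longest contiguous point run whose log2-linear fit reaches ``r2_min``.

    Ties are broken toward the earlier run.  Raises
    :class:`ExponentialWindowNotFound` when no run of >= ``min_points``
    qualifies.  A lag/exponential/plateau curve yields (about) the planted
    exponential segment; a pure exponential yields the full range.
    """
    t, y = curve.t, curve.y
    n = len(t)
    if n < 4:
        raise ValueError("need at least 4 points to search for a window")
    log2y = np.log2(y)
    best: tuple[int, int] | None = None  # (length, -start) implicit via order
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            seg = slice(start, start + length)
            if _run_r_squared(t[seg], log2y[seg]) >= r2_min:
                best = (start, start + length - 1)
                break
        if best is not None:
            break
    if best is None:
        raise ExponentialWindowNotFound(
            f"no contiguous run of >= {min_points} points reaches R^2 >= {r2_min}"
        )
    return (float(t[best[0]]), float(t[best[1]]))


@dataclass(frozen=True)
class RetentionSeries:
    """CFU counts under selective and non-selective plating per generation."""

    generations: tuple[float, ...]
    cfu_selective: tuple[int, ...]
    cfu_nonselective: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.generations)
            == len(self.cfu_selective)
            == len(self.cfu_nonselective)
        ):
            raise ValueError("all vectors must have equal length")
        if any(c < 0 for c in self.cfu_selective):
            raise ValueError("selective CFU counts must be >= 0")
        if any(c <= 0 for c in self.cfu_nonselective):
            raise ValueError("non-selective CFU counts must be > 0")


def plasmid_retention(series: RetentionSeries) -> np.ndarray:
    """Per-timepoint plasmid retention = selective / non-selective CFU.

    Ratios above 1 are plating noise (the selective plate cannot truly
    out-count the non-selective one) and are clamped to 1 with a warning.
    """
    sel = np.asarray(series.cfu_selective, dtype=float)
    non = np.asarray(series.cfu_nonselective, dtype=float)
    ratio = sel / non
    over = ratio > 1.0
    if over.any():
        warnings.warn(
            f"{int(over.sum())} retention value(s) > 1 clamped (plating noise)",
            stacklevel=2,
        )
    return np.clip(ratio, 0.0, 1.0)
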