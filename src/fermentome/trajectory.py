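"""Growth-curve features of taxon relative-abundance trajectories.

During cocoa fermentation the marker taxa (e.g. Lactobacillaceae and
Acetobacteraceae among bacteria, *Saccharomyces* and *Torulaspora* among
fungi) rise and fall in relative abundance.  Each taxon trajectory is
summarized by seven model-free growth features: first local maximum,
initial density, area under the curve, maximum density, time to maximum
density, midpoint (first time the interpolated curve reaches half the
maximum density), and the inflection point (time of the maximum
forward-difference slope).  Which taxa are summarized is decided by a
threshold on community-dissimilarity (PERMANOVA) coefficients, consumed
here as an input table: bacteria with coefficient >= 10 and fungi with
coefficient >= 5 are retained by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTrajectory",
    "GrowthFeatures",
    "MarkerSelection",
    "SmoothConfig",
    "GROWTH_FEATURE_NAMES",
    "DEFAULT_MARKER_THRESHOLDS",
    "select_markers",
    "moving_average",
    "extract_growth_features",
]

GROWTH_FEATURE_NAMES = (
    "first_local_max",
    "initial_density",
    "auc",
    "max_density",
    "time_to_max_density",
    "midpoint",
    "inflection_point",
)

DEFAULT_MARKER_THRESHOLDS = {"bacteria": 10.0, "fungi": 5.0}


@dataclass(frozen=True)
class AbundanceTrajectory:
    """One taxon's relative abundance over fermentation time."""

    taxon: str
    kingdom: str
    times: np.ndarray
    abundances: np.ndarray
    replicate: str = "r1"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "abundances", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and abundances must match in shape")
        if t.size < 3:
            raise ValueError("trajectory needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise ValueError("abundances must lie in [0, 1]")
        if self.kingdom not in ("bacteria", "fungi"):
            raise ValueError(f"unknown kingdom {self.kingdom!r}")


@dataclass(frozen=True)
class GrowthFeatures:
    first_local_max: float
    initial_density: float
    auc: float
    max_density: float
    time_to_max_density: float
    midpoint: float
    inflection_point: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GROWTH_FEATURE_NAMES}


@dataclass(frozen=True)
class MarkerSelection:
    """Per-kingdom threshold filter over taxon coefficients."""

    coefficients: pd.DataFrame  # columns: taxon, kingdom, coefficient
    thresholds: dict
    selected: frozenset


@dataclass(frozen=True)
class SmoothConfig:
    """Centered moving-average smoothing; window 1 disables it."""

    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")


def select_markers(
    coefficients: pd.DataFrame, thresholds: dict | None = None
) -> MarkerSelection:
    """Select marker taxa whose coefficient meets its kingdom threshold.

    The comparison is inclusive (>=); defaults are 10 for bacteria and 5
    for fungi.
    """
    thr = dict(DEFAULT_MARKER_THRESHOLDS if thresholds is None else thresholds)
    required = {"taxon", "kingdom", "coefficient"}
    if not required.issubset(coefficients.columns):
        raise ValueError(f"coefficient table must have columns {sorted(required)}")
    unknown = set(coefficients["kingdom"].unique()) - set(thr)
    if unknown:
        raise ValueError(f"no threshold for kingdom(s) {sorted(unknown)}")
    if not np.all(np.isfinite(coefficients["coefficient"].to_numpy(dtype=float))):
        raise ValueError("coefficients must be finite")
    mask = coefficients.apply(
        lambda row: row["coefficient"] >= thr[row["kingdom"]], axis=1
    )
    selected = frozenset(coefficients.loc[mask, "taxon"]) if len(coefficients) else frozenset()
    return MarkerSelection(coefficients=coefficients, thresholds=thr, selected=selected)


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrunk at the edges."""
    if window == 1:
        return np.asarray(y, dtype=float).copy()
    half = window // 2
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def extract_growth_features(
    traj: AbundanceTrajectory, smooth: SmoothConfig | None = None
) -> GrowthFeatures:
    """Compute the seven growth features of one trajectory.

    Endpoints count as local extrema (one-sided comparison) because
    trajectories truncated at fermentation start or end routinely peak
    at a boundary.  All argmax/argmin ties resolve to the earliest time.
    """
    cfg = smooth or SmoothConfig()
    t = traj.times
    y = moving_average(traj.abundances, cfg.window)
    n = y.size

    def is_local_max(i: int) -> bool:
        left = i == 0 or y[i - 1] <= y[i]
        right = i == n - 1 or y[i] >= y[i + 1]
        return left and right

    def is_local_min(i: int) -> bool:
        left = i == 0 or y[i - 1] >= y[i]
        right = i == n - 1 or y[i] <= y[i + 1]
        return left and right

    first_local_max = next(float(y[i]) for i in range(n) if is_local_max(i))
    initial_density = next(float(y[i]) for i in range(n) if is_local_min(i))

    auc = float(np.trapezoid(y, t))
    i_max = int(np.argmax(y))  # argmax returns the earliest maximizer
    max_density = float(y[i_max])
    time_to_max = float(t[i_max])

    # earliest time the piecewise-linear interpolant reaches max/2
    half = max_density / 2.0
    if y[0] >= half:
        midpoint = float(t[0])
    else:
        midpoint = np.nan
        for i in range(1, n):
            if y[i] >= half:
                # linear interpolation within segment [i-1, i]
                f = (half - y[i - 1]) / (y[i] - y[i - 1])
                midpoint = float(t[i - 1] + f * (t[i] - t[i - 1]))
                break

    slopes = np.diff(y) / np.diff(t)
    i_slope = int(np.argmax(slopes))
    inflection = float(t[i_slope])

    return GrowthFeatures(
        first_local_max=first_local_max,
        initial_density=initial_density,
        auc=auc,
        max_density=max_density,
        time_to_max_density=time_to_max,
        midpoint=midpoint,
        inflection_point=inflection,
    )
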