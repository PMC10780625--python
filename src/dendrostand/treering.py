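"""Ring-width series management: descriptive statistics, cross-dating
screening, pith-offset and coring-height age estimation, age classes,
biometric screening, diameter reconstruction and the age-structure
histogram.

Units follow dendrochronological convention: ring widths in mm at a
measurement resolution of 0.01 mm, diameters in cm, heights and crown
radii in m, ages in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "TreeRecord",
    "AgeModel",
    "mean_sensitivity",
    "first_order_autocorrelation",
    "correlation_with_master",
    "estimate_pith_offset",
    "fit_age_correction",
    "assign_age_class",
    "biometric_screen",
    "cumulative_dib",
    "age_structure",
    "coefficient_of_variation",
    "cv_percent",
]


@dataclass
class RingSeries:
    """One increment core: calendar-dated ring widths (mm).

    ``pith_offset_rings`` is the estimated number of rings missing between
    the innermost measured ring and the stem pith (0 when the pith was
    reached); the cambial age of ring ``i`` (0-based) is therefore
    ``pith_offset_rings + i + 1``.
    """

    tree_id: str
    core_id: str
    first_year: int
    widths: np.ndarray
    pith_reached: bool = False
    pith_offset_rings: int = 0
    coring_height: float = 1.3

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or len(self.widths) < 1:
            raise ValueError("widths must be a nonempty 1-d array")
        if np.any(self.widths <= 0):
            raise ValueError("ring widths must be strictly positive")
        if self.pith_offset_rings < 0:
            raise ValueError("pith offset must be nonnegative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def mean_ring_width(self) -> float:
        """MRW: mean width over the entire series length (mm)."""
        return float(np.mean(self.widths))

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.core_id)


@dataclass
class TreeRecord:
    """Per-tree biometric record."""

    id: str
    dbh: float  # cm
    h: float  # m
    cw: float  # m^2, crown projection area
    cr: float  # m, mean of the four cardinal crown radii
    age: float | None = None  # corrected age, years
    age_class: str | None = None


@dataclass
class AgeModel:
    """OLS line of (ground-vs-DBH ring-count difference) on age at DBH.

    Predictions are the number of years to add to a ring count at coring
    height, rounded to the nearest nonnegative integer.
    """

    intercept: float
    slope: float
    n: int

    def predict(self, age_at_dbh) -> np.ndarray:
        raw = self.intercept + self.slope * np.asarray(age_at_dbh, dtype=float)
        return np.maximum(np.rint(raw), 0.0).astype(int)


def _positive_1d(x, name: str, min_len: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < min_len:
        raise ValueError(f"{name} must be 1-d with at least {min_len} values")
    return arr


def mean_sensitivity(series) -> float:
    """Douglass mean sensitivity: mean of 2|x(t+1)-x(t)| / (x(t+1)+x(t)).

    A high-frequency variability statistic on widths or indices; always in
    [0, 2] for positive input, 0 for a constant series.
    """
    x = _positive_1d(series, "series", 2)
    if np.any(x <= 0):
        raise ValueError("mean sensitivity requires strictly positive values")
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    return float(np.mean(num / den))


def first_order_autocorrelation(series) -> float:
    """Pearson correlation between consecutive values (lag-1)."""
    x = _positive_1d(np.asarray(series, float), "series", 3)
    a, b = x[:-1], x[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("autocorrelation undefined for a zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_with_master(
    series: pd.Series,
    master: pd.Series,
    min_overlap: int = 20,
    r_threshold: float = 0.40,
) -> tuple[float, str]:
    """Cross-dating screen: Pearson r over the year overlap with the master.

    Returns ``(r, flag)`` where flag is ``"keep"`` (r >= threshold),
    ``"discard"`` (r below threshold) or ``"undatable"`` (overlap shorter
    than ``min_overlap``; r is NaN).
    """
    joined = pd.concat([series, master], axis=1, join="inner").dropna()
    if len(joined) < min_overlap:
        return float("nan"), "undatable"
    r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
    return r, ("keep" if r >= r_threshold else "discard")


def estimate_pith_offset(chord: float, sagitta: float, inner_widths, k: int = 5) -> int:
    """Missing-ring count from innermost-ring arc geometry (pith locator).

    The innermost visible ring arc with chord length ``chord`` and sagitta
    (arc height) ``sagitta`` lies on a circle of radius
    ``r = chord**2 / (8 * sagitta) + sagitta / 2`` about the pith; the
    number of missing rings is that radius divided by the mean width of the
    ``k`` innermost measured rings, rounded to the nearest integer.  All
    lengths share one unit (mm).
    """
    if chord == 0:
        return 0
    if sagitta <= 0:
        raise ValueError("sagitta must be positive")
    if chord < 0:
        raise ValueError("chord must be nonnegative")
    inner = _positive_1d(inner_widths, "inner_widths", 1)
    if np.any(inner <= 0):
        raise ValueError("inner ring widths must be positive")
    r_missing = chord**2 / (8.0 * sagitta) + sagitta / 2.0
    mean_w = float(np.mean(inner[: max(1, k)]))
    return int(round(r_missing / mean_w))


def missing_radius(chord: float, sagitta: float) -> float:
    """Radius of the circle through an arc of given chord and sagitta."""
    if sagitta <= 0:
        raise ValueError("sagitta must be positive")
    return chord**2 / (8.0 * sagitta) + sagitta / 2.0


def fit_age_correction(pairs) -> AgeModel:
    """OLS of ring-count difference (ground vs DBH) on age at DBH.

    ``pairs`` is a sequence of (age_at_dbh, ring_diff) or a DataFrame with
    those two columns.  Needs >= 3 pairs and a non-degenerate age spread.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) < 3:
        raise ValueError("need at least 3 (age, difference) pairs")
    ages, diffs = arr[:, 0], arr[:, 1]
    if np.ptp(ages) == 0:
        raise ValueError("degenerate design: all ages equal")
    slope, intercept = np.polyfit(ages, diffs, 1)
    return AgeModel(intercept=float(intercept), slope=float(slope), n=len(arr))


def assign_age_class(age: float, adult: bool = True) -> str | None:
    """Chronological class from corrected age.

    Adults: Y (<= 40 yr), M (41-80 yr), O (> 80 yr).  Non-adults (below
    the DBH threshold) count as established regeneration ``"ER"`` only when
    at least 3 years old; younger plantlets return ``None``.
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    if not adult:
        return "ER" if age >= 3 else None
    if age <= 40:
        return "Y"
    if age <= 80:
        return "M"
    return "O"


def biometric_screen(
    trees: pd.DataFrame,
    ring_counts: Mapping[str, int],
    bin_width: int = 10,
    min_params: int = 2,
    min_rings: int = 20,
) -> pd.DataFrame:
    """Stunted-growth screen for the climate analysis.

    Within each ``bin_width``-year age bin, a tree passes a biometric
    parameter (DBH, H, CW) when its value exceeds the bin mean minus one
    standard deviation.  Kept trees pass at least ``min_params`` of the
    three and have strictly more than ``min_rings`` rings.  A tree alone in
    its bin has no defined spread and passes by default (flagged).

    ``trees`` must be indexed by tree id with columns dbh, h, cw, age.
    """
    required = {"dbh", "h", "cw", "age"}
    if not required.issubset(trees.columns):
        raise ValueError(f"trees must have columns {sorted(required)}")
    bins = (trees["age"] // bin_width).astype(int)
    out = pd.DataFrame(index=trees.index)
    single = pd.Series(False, index=trees.index)
    passes = pd.DataFrame(index=trees.index, columns=["dbh", "h", "cw"], dtype=bool)
    for b in bins.unique():
        members = bins.index[bins == b]
        if len(members) < 2:
            single.loc[members] = True
            passes.loc[members, :] = True
            continue
        for param in ("dbh", "h", "cw"):
            v = trees.loc[members, param]
            threshold = v.mean() - v.std(ddof=1)
            passes.loc[members, param] = v > threshold
    n_pass = passes.sum(axis=1).astype(int)
    rings = pd.Series({t: ring_counts.get(t, 0) for t in trees.index})
    out["n_params_passed"] = n_pass
    out["biometric_ok"] = n_pass >= min_params
    out["rings"] = rings
    out["rings_ok"] = rings > min_rings  # strictly more than min_rings
    out["single_bin_flag"] = single
    out["keep"] = out["biometric_ok"] & out["rings_ok"]
    return out


def cumulative_dib(series: RingSeries | Sequence[float]) -> np.ndarray:
    """Cumulative diameter inside bark per cambial age: DIB(t) = 2*sum(w), mm.

    Strictly increasing; same length as the input series.
    """
    widths = series.widths if isinstance(series, RingSeries) else np.asarray(series, float)
    if np.any(widths <= 0):
        raise ValueError("ring widths must be positive")
    return 2.0 * np.cumsum(widths)


def age_structure(ages, bin_width: int = 5) -> pd.DataFrame:
    """Histogram of tree ages in fixed-width bins labelled by midpoint."""
    ages = np.asarray(ages, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(ages) == 0:
        return pd.DataFrame({"midpoint": [], "count": []})
    lo = math.floor(ages.min() / bin_width) * bin_width
    hi = math.ceil((ages.max() + 1e-9) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(ages, bins=edges)
    mid = edges[:-1] + bin_width / 2.0
    return pd.DataFrame({"midpoint": mid, "count": counts})


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample sd / mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    if len(v) < 2:
        return 0.0
    return float(100.0 * v.std(ddof=1) / m)


def cv_percent(mean: float, sd: float) -> float:
    """CV in percent from summary statistics: 100 * sd / mean."""
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return 100.0 * sd / mean
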