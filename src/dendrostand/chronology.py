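"""Detrending (standardization) and master-chronology construction.

Three growth-curve models are supported, one per age class in the default
pipeline:

* ``spline`` — cubic smoothing spline with a 50% frequency-response cutoff
  at a wavelength defaulting to 67% of the series length (the conventional
  dendrochronological stiffness), used for old trees;
* ``negexp`` — modified negative exponential a*exp(-b*t) + k with a, b > 0,
  falling back to a horizontal mean line when the fit fails or is not
  decreasing, used for mature trees;
* ``rcs`` — Regional Curve Standardization: one shared curve of mean width
  against cambial age (pith offsets applied), smoothed by a spline with a
  cutoff of 10% of the maximum cambial age, used for young trees, whose
  low-frequency signal a per-series fit would remove.

Indices are ratios width / fitted-curve, dimensionless with mean ~ 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

from .treering import RingSeries, first_order_autocorrelation, mean_sensitivity

__all__ = [
    "DetrendResult",
    "RegionalCurve",
    "detrend",
    "fit_regional_curve",
    "Chronology",
    "ChronologyStats",
    "build_chronology",
    "tukey_biweight_mean",
]


def _spline_lambda(wavelength: float) -> float:
    """Second-derivative penalty giving a ~50% frequency response at the
    given wavelength (|H(f)| = 1/(1 + lam*(2*pi*f)**4) with f = 1/wavelength)."""
    return (wavelength / (2.0 * math.pi)) ** 4


@dataclass
class DetrendResult:
    index: np.ndarray
    curve: np.ndarray
    method: str
    fallback: bool = False


def _fit_spline_curve(widths: np.ndarray, wavelength: float) -> np.ndarray:
    t = np.arange(len(widths), dtype=float)
    spl = make_smoothing_spline(t, widths, lam=_spline_lambda(wavelength))
    return np.asarray(spl(t))


def _negexp(t, a, b, k):
    return a * np.exp(-b * t) + k


def detrend(
    series: RingSeries | Sequence[float],
    method: str = "spline",
    stiffness: float | None = None,
    regional_curve: "RegionalCurve | None" = None,
) -> DetrendResult:
    """Standardize one series: index = width / fitted growth curve.

    ``stiffness`` is the spline cutoff wavelength in years (default 67% of
    the series length).  ``method="rcs"`` requires a fitted
    ``regional_curve`` and, for correct cambial alignment, a
    :class:`RingSeries` carrying its pith offset.
    """
    if isinstance(series, RingSeries):
        widths = series.widths
        offset = series.pith_offset_rings
    else:
        widths = np.asarray(series, dtype=float)
        offset = 0
    n = len(widths)
    if np.any(widths <= 0):
        raise ValueError("widths must be strictly positive")

    if method == "spline":
        if n < 10:
            raise ValueError("spline detrending needs at least 10 rings")
        wl = 0.67 * n if stiffness is None else float(stiffness)
        if wl <= 0:
            raise ValueError("spline stiffness must be positive")
        curve = _fit_spline_curve(widths, wl)
        fallback = False
        if np.any(curve <= 0):
            curve = np.full(n, widths.mean())
            fallback = True
        return DetrendResult(widths / curve, curve, "spline", fallback)

    if method == "negexp":
        if n < 10:
            raise ValueError("negative-exponential detrending needs at least 10 rings")
        t = np.arange(n, dtype=float)
        fallback = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p0 = (max(widths[0] - widths[-1], 1e-3), 2.0 / n, max(widths[-1], 1e-3))
                popt, _ = curve_fit(
                    _negexp, t, widths, p0=p0,
                    bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=10_000,
                )
            curve = _negexp(t, *popt)
            # a ~ 0 means the optimiser flattened the exponential: the series
            # carries no decreasing age trend, use the horizontal mean instead
            if popt[0] < 1e-3 * max(np.ptp(widths), 1e-12) or np.any(np.diff(curve) > 0) or np.any(curve <= 0):
                raise RuntimeError("fitted curve degenerate")
        except Exception:
            curve = np.full(n, widths.mean())
            fallback = True
        return DetrendResult(widths / curve, curve, "negexp", fallback)

    if method == "mean":
        curve = np.full(n, widths.mean())
        return DetrendResult(widths / curve, curve, "mean")

    if method == "rcs":
        if regional_curve is None:
            raise ValueError("rcs detrending requires a fitted regional curve")
        cambial = offset + 1 + np.arange(n)
        curve = regional_curve(cambial)
        return DetrendResult(widths / curve, curve, "rcs")

    raise ValueError(f"unknown detrending method {method!r}")


@dataclass
class RegionalCurve:
    """Smoothed mean ring width against cambial age for one cohort."""

    cambial_age: np.ndarray  # 1..max age
    curve: np.ndarray  # smoothed mean width (mm), strictly positive
    depth: np.ndarray  # sample depth per cambial age

    def __call__(self, cambial_age) -> np.ndarray:
        """Evaluate the curve; ages beyond support use the last supported value."""
        idx = np.clip(np.asarray(cambial_age, dtype=int) - 1, 0, len(self.curve) - 1)
        return self.curve[idx]


def fit_regional_curve(
    series: Sequence[RingSeries],
    smooth_frac: float = 0.10,
) -> RegionalCurve:
    """Align a cohort on cambial age (pith offsets applied), average, smooth.

    The mean curve is smoothed with a spline whose 50% cutoff is
    ``smooth_frac`` of the maximum cambial age, to avoid amplifying noise
    where the sample depth is low.
    """
    if not series:
        raise ValueError("need at least one series")
    max_age = max(s.pith_offset_rings + len(s.widths) for s in series)
    total = np.zeros(max_age)
    depth = np.zeros(max_age, dtype=int)
    for s in series:
        start = s.pith_offset_rings
        total[start : start + len(s.widths)] += s.widths
        depth[start : start + len(s.widths)] += 1
    covered = depth > 0
    ages = np.arange(1, max_age + 1, dtype=float)
    mean_w = np.empty(max_age)
    mean_w[covered] = total[covered] / depth[covered]
    if not covered.all():  # fill sparse interior gaps before smoothing
        mean_w[~covered] = np.interp(ages[~covered], ages[covered], mean_w[covered])
    wl = max(smooth_frac * max_age, 5.0)
    smooth = _fit_spline_curve(mean_w, wl)
    smooth = np.maximum(smooth, 1e-6)
    return RegionalCurve(cambial_age=np.arange(1, max_age + 1), curve=smooth, depth=depth)


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0, iters: int = 10) -> float:
    """Tukey's biweight robust mean (dendro convention, c = 9)."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    m = float(np.median(x))
    for _ in range(iters):
        s = float(np.median(np.abs(x - m)))
        if s == 0:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * x) / w.sum())
        if abs(m_new - m) < 1e-12:
            return m_new
        m = m_new
    return m


@dataclass
class ChronologyStats:
    """Descriptive statistics of a chronology and its constituent series.

    MSm: mean sensitivity of the master; MSi: mean of per-series mean
    sensitivities; CC: mean pairwise inter-series correlation over
    overlaps of at least ``min_overlap`` years; CM: mean correlation of
    each series with the master; AC1 on the raw and standardized master.
    """

    msm: float
    msi: float
    cc: float
    cm: float
    ac1_std: float
    ac1_raw: float | None = None


@dataclass
class Chronology:
    label: str
    index: pd.Series  # master index values, year-indexed
    depth: pd.Series  # sample depth per year
    stats: ChronologyStats
    n_series: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.index, "depth": self.depth})


def _aggregate(frame: pd.DataFrame, aggregation: str) -> pd.Series:
    if aggregation == "mean":
        return frame.mean(axis=1)
    if aggregation == "biweight":
        return frame.apply(lambda row: tukey_biweight_mean(row.dropna().to_numpy()), axis=1)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _mean_pairwise_correlation(frame: pd.DataFrame, min_overlap: int) -> float:
    cols = frame.columns
    rs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = frame[[cols[i], cols[j]]].dropna()
            if len(pair) < min_overlap:
                continue
            a, b = pair.iloc[:, 0], pair.iloc[:, 1]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def build_chronology(
    index_series: Mapping[str, pd.Series],
    label: str = "",
    raw_series: Mapping[str, pd.Series] | None = None,
    aggregation: str = "mean",
    min_overlap: int = 20,
) -> Chronology:
    """Aggregate standardized series into a master chronology with statistics.

    ``index_series`` maps series ids to year-indexed index values; the
    master is their per-year arithmetic mean (or Tukey biweight).  When
    ``raw_series`` is given, AC1 of the raw master (mean raw width per
    year) is reported alongside AC1 of the standardized master.
    """
    if not index_series:
        raise ValueError("need at least one index series")
    frame = pd.DataFrame(index_series).sort_index()
    master = _aggregate(frame, aggregation)
    depth = frame.notna().sum(axis=1)
    master = master[depth > 0]
    depth = depth[depth > 0]

    msm = mean_sensitivity(master.to_numpy()) if len(master) >= 2 else float("nan")
    msi = float(
        np.mean([mean_sensitivity(frame[c].dropna().to_numpy()) for c in frame.columns])
    )
    cc = _mean_pairwise_correlation(frame, min_overlap)
    cms = []
    for c in frame.columns:
        pair = pd.concat([frame[c], master], axis=1, join="inner").dropna()
        if len(pair) >= 3 and pair.iloc[:, 0].std() > 0 and pair.iloc[:, 1].std() > 0:
            cms.append(float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]))
    cm = float(np.mean(cms)) if cms else float("nan")
    ac1_std = first_order_autocorrelation(master.to_numpy()) if len(master) >= 3 else float("nan")

    ac1_raw = None
    if raw_series:
        raw_master = pd.DataFrame(raw_series).sort_index().mean(axis=1).dropna()
        if len(raw_master) >= 3:
            ac1_raw = first_order_autocorrelation(raw_master.to_numpy())

    stats = ChronologyStats(msm=msm, msi=msi, cc=cc, cm=cm, ac1_std=ac1_std, ac1_raw=ac1_raw)
    return Chronology(label=label, index=master, depth=depth, stats=stats, n_series=frame.shape[1])
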