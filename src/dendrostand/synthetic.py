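"""Synthetic stem maps, ring-width series and monthly climate.

The generators emulate the statistical structure a dendroecological
analysis of a multi-aged Mediterranean pine stand assumes: a circular
plot (default radius 40 m) holding three adult age classes with distinct
spatial processes plus an established-regeneration cohort; ring-width
series with a negative-exponential age trend, an AR(1) persistence term
and a linear monthly-climate signal on the log scale; and monthly climate
with Mediterranean seasonality (precipitation maximum in November,
minimum in July).

``generate_study`` assembles the full default stand — 111 adults mapped
with marks, 222 cores of which 26 are planted as undatable
(year-shuffled) and 33 trees are planted as biometrically stunted — so
every downstream screening stage has a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spatial import PointPattern, Window
from .treering import RingSeries, biometric_screen, fit_age_correction

__all__ = [
    "Poisson",
    "ThomasCluster",
    "Hardcore",
    "Repulsion",
    "Attraction",
    "SpatialScenario",
    "AgeCurve",
    "RingScenario",
    "ClimateScenario",
    "StudyData",
    "generate_point_pattern",
    "generate_ring_series",
    "generate_climate",
    "generate_study",
]

MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"]
MONTH_NUM = {m: i + 1 for i, m in enumerate(MONTH_ABBR)}

# ---------------------------------------------------------------------------
# point processes


@dataclass(frozen=True)
class Poisson:
    """Binomial process: n independent uniform points in the window."""


@dataclass(frozen=True)
class ThomasCluster:
    """Poisson cluster process: Gaussian offspring around Poisson parents.

    Parents are sampled in a window enlarged by 3*cluster_sd so clusters
    centred just outside still contribute points inside (avoids edge
    intensity bias); offspring falling outside the window are redrawn.
    """

    parent_intensity: float  # parents per m^2
    mean_offspring: float = 10.0
    cluster_sd: float = 2.0


@dataclass(frozen=True)
class Hardcore:
    """Simple sequential inhibition with a minimum inter-point distance."""

    min_distance: float


@dataclass(frozen=True)
class Repulsion:
    """Cross-class rule: classes keep min_distance from earlier classes."""

    min_distance: float


@dataclass(frozen=True)
class Attraction:
    """Cross-class rule: Thomas classes share one parent point set."""


@dataclass
class SpatialScenario:
    window_radius: float = 40.0
    n_per_class: Mapping[str, int] = field(default_factory=lambda: {"Y": 56, "M": 31, "O": 24})
    process_per_class: Mapping[str, object] = field(default_factory=dict)
    cross_class_rule: object = "independent"
    seed: int = 0


_MAX_TRIES = 200_000


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = 2 * math.pi * rng.random(n)
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


def _ok(cand: np.ndarray, accepted: list, min_self: float, avoid: np.ndarray | None, min_cross: float) -> bool:
    if min_self > 0 and accepted:
        arr = np.asarray(accepted)
        if np.min(np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1])) < min_self:
            return False
    if avoid is not None and len(avoid) and min_cross > 0:
        if np.min(np.hypot(avoid[:, 0] - cand[0], avoid[:, 1] - cand[1])) < min_cross:
            return False
    return True


def _sample_class(
    rng: np.random.Generator,
    process,
    n: int,
    radius: float,
    avoid: np.ndarray | None = None,
    min_cross: float = 0.0,
    shared_parents: np.ndarray | None = None,
):
    """Sample exactly n points of one class; returns (points, parents_used)."""
    if n == 0:
        return np.empty((0, 2)), None
    if isinstance(process, Hardcore):
        pts: list = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > _MAX_TRIES:
                raise RuntimeError(
                    f"infeasible hardcore packing: could not place {n} points "
                    f"with min_distance={process.min_distance} in radius {radius}"
                )
            cand = _uniform_disc(rng, 1, radius)[0]
            if _ok(cand, pts, process.min_distance, avoid, min_cross):
                pts.append(cand)
        return np.asarray(pts), None
    if isinstance(process, ThomasCluster):
        ext = radius + 3 * process.cluster_sd
        if shared_parents is not None:
            parents = shared_parents
        else:
            n_par = 0
            while n_par == 0:
                n_par = rng.poisson(process.parent_intensity * math.pi * ext**2)
            parents = _uniform_disc(rng, n_par, ext)
        pts = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > _MAX_TRIES:
                raise RuntimeError("could not place Thomas offspring inside the window")
            par = parents[rng.integers(len(parents))]
            cand = par + rng.normal(0.0, process.cluster_sd, size=2)
            if np.hypot(*cand) > radius:
                continue
            if _ok(cand, pts, 0.0, avoid, min_cross):
                pts.append(cand)
        return np.asarray(pts), parents
    # Poisson / default
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > _MAX_TRIES:
            raise RuntimeError("could not place Poisson points honouring the cross-class rule")
        cand = _uniform_disc(rng, 1, radius)[0]
        if _ok(cand, pts, 0.0, avoid, min_cross):
            pts.append(cand)
    return np.asarray(pts), None


def generate_point_pattern(scenario: SpatialScenario) -> PointPattern:
    """Marked point pattern with exactly the requested per-class counts."""
    if scenario.window_radius <= 0:
        raise ValueError("window_radius must be positive")
    rng = np.random.default_rng(scenario.seed)
    window = Window(scenario.window_radius)
    rule = scenario.cross_class_rule
    min_cross = rule.min_distance if isinstance(rule, Repulsion) else 0.0
    shared = None
    all_xy: list[np.ndarray] = []
    all_marks: list[str] = []
    placed = np.empty((0, 2))
    for label, n in scenario.n_per_class.items():
        if n < 0:
            raise ValueError("per-class counts must be nonnegative")
        proc = scenario.process_per_class.get(label, Poisson())
        use_shared = shared if isinstance(rule, Attraction) else None
        pts, parents = _sample_class(
            rng, proc, n, scenario.window_radius,
            avoid=placed if min_cross > 0 else None,
            min_cross=min_cross,
            shared_parents=use_shared,
        )
        if isinstance(rule, Attraction) and parents is not None and shared is None:
            shared = parents
        all_xy.append(pts)
        all_marks.extend([label] * n)
        placed = np.vstack([placed, pts]) if len(pts) else placed
    xy = np.vstack(all_xy) if all_xy else np.empty((0, 2))
    return PointPattern(xy, window, all_marks)


# ---------------------------------------------------------------------------
# climate

# Mediterranean monthly precipitation profile (mm), scaled to a 644.6 mm
# annual total, with the maximum in November and the minimum in July.
_P_SHAPE = np.array([60, 55, 50, 45, 35, 20, 5, 15, 45, 80, 95, 75], dtype=float)
DEFAULT_P_MEANS = _P_SHAPE * (644.6 / _P_SHAPE.sum())
DEFAULT_TMAX_MEANS = np.array([11.0, 12.0, 14.5, 17.5, 22.0, 26.0, 29.5, 29.5, 25.5, 20.5, 15.0, 12.0])
DEFAULT_TMIN_MEANS = np.array([2.5, 3.0, 5.0, 7.5, 11.0, 14.5, 17.0, 17.5, 14.5, 10.5, 6.5, 4.0])


@dataclass
class ClimateScenario:
    start_year: int = 1856
    end_year: int = 1997
    p_means: np.ndarray = field(default_factory=lambda: DEFAULT_P_MEANS.copy())
    p_sds: np.ndarray | None = None  # default: 45% of the monthly mean
    tmax_means: np.ndarray = field(default_factory=lambda: DEFAULT_TMAX_MEANS.copy())
    tmax_sds: np.ndarray | None = None  # default 1.5 C
    tmin_means: np.ndarray = field(default_factory=lambda: DEFAULT_TMIN_MEANS.copy())
    tmin_sds: np.ndarray | None = None  # default 1.5 C
    seed: int = 0


def generate_climate(scenario: ClimateScenario) -> pd.DataFrame:
    """Complete monthly table (year, month, p_mm, tmax_c, tmin_c).

    Monthly noise is independent; precipitation is truncated at zero and
    Tmin is capped just below Tmax so both physical invariants hold.
    """
    if scenario.end_year < scenario.start_year:
        raise ValueError("year range is empty")
    rng = np.random.default_rng(scenario.seed)
    years = np.arange(scenario.start_year, scenario.end_year + 1)
    ny = len(years)
    p_sds = np.asarray(scenario.p_sds if scenario.p_sds is not None else 0.45 * scenario.p_means, float)
    tmax_sds = np.asarray(scenario.tmax_sds if scenario.tmax_sds is not None else np.full(12, 1.5), float)
    tmin_sds = np.asarray(scenario.tmin_sds if scenario.tmin_sds is not None else np.full(12, 1.5), float)
    p = scenario.p_means + rng.normal(0.0, 1.0, (ny, 12)) * p_sds
    tmax = scenario.tmax_means + rng.normal(0.0, 1.0, (ny, 12)) * tmax_sds
    tmin = scenario.tmin_means + rng.normal(0.0, 1.0, (ny, 12)) * tmin_sds
    p = np.maximum(p, 0.0)
    tmin = np.minimum(tmin, tmax - 0.1)
    out = pd.DataFrame(
        {
            "year": np.repeat(years, 12),
            "month": np.tile(np.arange(1, 13), ny),
            "p_mm": p.ravel(),
            "tmax_c": tmax.ravel(),
            "tmin_c": tmin.ravel(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# ring-width series


@dataclass(frozen=True)
class AgeCurve:
    """Negative-exponential biological growth curve a*exp(-b*(t-1)) + k (mm)."""

    a: float = 2.5
    b: float = 0.05
    k: float = 1.0

    def __call__(self, cambial_age) -> np.ndarray:
        t = np.asarray(cambial_age, dtype=float)
        return self.a * np.exp(-self.b * (t - 1.0)) + self.k


# Planted monthly-climate signal on log ring width; keys are
# (variable, month-abbreviation, from-previous-year?).
DEFAULT_BETA: dict[tuple[str, str, bool], float] = {
    ("p", "oct", True): 0.28,
    ("p", "nov", True): 0.22,
    ("p", "dec", True): 0.12,
    ("p", "mar", False): 0.14,
    ("tmax", "jan", False): 0.10,
    ("tmin", "jan", False): 0.08,
}

DEFAULT_AGE_CURVES = {
    "Y": AgeCurve(a=2.2, b=0.12, k=0.85),
    "M": AgeCurve(a=2.8, b=0.035, k=1.15),
    "O": AgeCurve(a=2.8, b=0.035, k=0.80),
}


@dataclass
class RingScenario:
    n_per_class: Mapping[str, int] = field(default_factory=lambda: {"Y": 56, "M": 31, "O": 24})
    age_range_per_class: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"Y": (28, 40), "M": (41, 74), "O": (104, 136)}
    )
    age_curve_per_class: Mapping[str, AgeCurve] = field(default_factory=lambda: dict(DEFAULT_AGE_CURVES))
    beta: Mapping[tuple[str, str, bool], float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    phi: float = 0.6
    sigma: float = 0.138  # AR(1) innovation sd (tree level, log scale)
    sigma_core: float = 0.141  # white within-tree core noise (log scale)
    cores_per_tree: int = 2
    end_year: int = 1997
    pith_offset_range: tuple[int, int] = (0, 5)
    quantize: bool = True  # round widths to the 0.01 mm measurement resolution
    seed: int = 0


def climate_signal(climate: pd.DataFrame, beta: Mapping[tuple[str, str, bool], float]) -> pd.Series:
    """Linear log-scale climate signal per growth year.

    Each regressor is standardised (z-scored) over the full climate table,
    then combined with its coefficient; the value for growth year t uses
    calendar year t-1 for previous-year months.
    """
    col = {"p": "p_mm", "tmax": "tmax_c", "tmin": "tmin_c"}
    wide = climate.pivot(index="year", columns="month")
    years = wide.index.to_numpy()
    sig = pd.Series(0.0, index=years)
    for (var, mon, prev), coef in beta.items():
        vals = wide[(col[var], MONTH_NUM[mon])]
        z = (vals - vals.mean()) / vals.std(ddof=1)
        z = z.shift(1) if prev else z  # value at growth year t comes from t-1
        sig = sig.add(coef * z, fill_value=np.nan)
    return sig


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    e = np.zeros(n)
    if sigma == 0:
        return e
    stat_sd = sigma / math.sqrt(1 - phi**2) if abs(phi) < 1 else sigma
    e[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sigma, n)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t]
    return e


def simulate_tree_cores(
    rng: np.random.Generator,
    tree_id: str,
    curve: AgeCurve,
    age_dbh: int,
    offsets: Sequence[int],
    signal: pd.Series,
    phi: float,
    sigma: float,
    sigma_core: float,
    end_year: int,
    quantize: bool = True,
) -> list[RingSeries]:
    """Cores of one tree: shared age curve + climate signal + AR(1) tree noise,
    plus independent white core noise; the measured core misses the innermost
    ``offset`` rings when the pith was not reached."""
    years = np.arange(end_year - age_dbh + 1, end_year + 1)
    missing = [y for y in years if y not in signal.index or not np.isfinite(signal.loc[y])]
    if missing:
        raise ValueError(f"climate does not cover years {missing[:5]} of tree {tree_id}")
    cambial = np.arange(1, age_dbh + 1)
    log_common = np.log(curve(cambial)) + signal.loc[years].to_numpy() + _ar1(rng, age_dbh, phi, sigma)
    cores = []
    for c, off in enumerate(offsets):
        off = int(off)
        if off >= age_dbh:
            raise ValueError("pith offset must be smaller than the ring count")
        w = np.exp(log_common + rng.normal(0.0, sigma_core, age_dbh) if sigma_core > 0 else log_common)
        w = w[off:]
        if quantize:
            w = np.maximum(np.round(w, 2), 0.01)
        cores.append(
            RingSeries(
                tree_id=tree_id,
                core_id=f"{tree_id}{chr(ord('A') + c)}",
                first_year=int(years[off]),
                widths=w,
                pith_reached=off == 0,
                pith_offset_rings=off,
            )
        )
    return cores


def generate_ring_series(scenario: RingScenario, climate: pd.DataFrame) -> list[RingSeries]:
    """Collection of per-core ring series for a stand of trees.

    width(t) = agecurve(cambial age) * exp(beta . z(t) + AR(1) + core noise);
    widths are strictly positive by construction.
    """
    rng = np.random.default_rng(scenario.seed)
    signal = climate_signal(climate, scenario.beta) if scenario.beta else pd.Series(
        0.0, index=np.arange(climate["year"].min(), climate["year"].max() + 1)
    )
    series: list[RingSeries] = []
    for label, n in scenario.n_per_class.items():
        lo, hi = scenario.age_range_per_class[label]
        curve = scenario.age_curve_per_class[label]
        for i in range(n):
            age = int(rng.integers(lo, hi + 1))
            offs = rng.integers(
                scenario.pith_offset_range[0],
                scenario.pith_offset_range[1] + 1,
                scenario.cores_per_tree,
            )
            offs = np.minimum(offs, age - 2)
            series.extend(
                simulate_tree_cores(
                    rng, f"{label}{i + 1:03d}", curve, age, offs, signal,
                    scenario.phi, scenario.sigma, scenario.sigma_core,
                    scenario.end_year, scenario.quantize,
                )
            )
    return series


# ---------------------------------------------------------------------------
# the assembled default study


@dataclass
class StudyData:
    """Everything the pipeline consumes, with planted ground truth."""

    trees: pd.DataFrame
    pattern: PointPattern
    regeneration: pd.DataFrame
    series: list[RingSeries]
    climate: pd.DataFrame
    age_pairs: pd.DataFrame
    truth: dict


def _crown_area(radii: np.ndarray) -> np.ndarray:
    """Quarter-ellipse approximation from the four cardinal crown radii."""
    rn, re, rs, rw = radii.T
    return (math.pi / 4.0) * (rn * re + re * rs + rs * rw + rw * rn)


_RADII_COLS = ["cw_n_m", "cw_e_m", "cw_s_m", "cw_w_m"]


def _set_param(trees: pd.DataFrame, tid: str, param: str, target: float) -> None:
    row = trees["tree_id"] == tid
    if param == "cw_m2":
        current = float(trees.loc[row, "cw_m2"].iloc[0])
        scale = math.sqrt(max(target, 1e-6) / current)
        trees.loc[row, _RADII_COLS] = trees.loc[row, _RADII_COLS] * scale
        trees.loc[row, "cw_m2"] = _crown_area(trees.loc[row, _RADII_COLS].to_numpy())
    else:
        trees.loc[row, param] = max(target, 1e-6)


def _plant_screening_truth(
    trees: pd.DataFrame,
    survivors: Sequence[str],
    ring_counts: Mapping[str, int],
    protected: set[str],
    fill_order: Sequence[str],
    n_stunted: int = 33,
) -> tuple[pd.DataFrame, set[str]]:
    """Plant exactly ``n_stunted`` biometrically stunted trees.

    Trees already failing the 2-of-3 screen by natural spread are adopted
    into the stunted set first (protected trees are instead lifted to their
    bin mean), the set is filled from ``fill_order``, and each stunted
    tree's DBH/H/CW are lowered below the realized per-bin mean - sd
    thresholds by a fixed-point loop until the screen removes exactly the
    planted set."""
    trees = trees.copy()
    param_map = {"dbh_cm": "dbh", "h_m": "h", "cw_m2": "cw"}

    def screen_now():
        sub = trees.loc[trees["tree_id"].isin(survivors)].set_index("tree_id")
        renamed = sub.rename(columns={"dbh_cm": "dbh", "h_m": "h", "cw_m2": "cw",
                                      "corrected_age_est": "age"})
        scr = biometric_screen(renamed[["dbh", "h", "cw", "age"]],
                               {t: ring_counts[t] for t in sub.index})
        return scr, sub

    def bin_stats(sub, param):
        bins = (sub["corrected_age_est"] // 10).astype(int)
        col = sub[param]
        stats = {}
        for b in bins.unique():
            v = col[bins == b]
            if len(v) >= 2:
                stats[b] = (v.mean(), v.mean() - v.std(ddof=1))
        return bins, stats

    def lift(tid, scr, sub):
        for param in ("dbh_cm", "h_m", "cw_m2"):
            bins, stats = bin_stats(sub, param)
            if bins[tid] in stats:
                mean, _ = stats[bins[tid]]
                if sub.loc[tid, param] <= mean:
                    _set_param(trees, tid, param, 1.05 * mean)

    # protected trees must never fail the screen
    for _ in range(20):
        scr, sub = screen_now()
        bad = [t for t in protected if t in scr.index and not scr.loc[t, "keep"]]
        if not bad:
            break
        for t in bad:
            lift(t, scr, sub)

    # a mean - sd threshold cannot remove half a bin, so cap the planted
    # fraction per 10-yr bin at 40% of its members (singleton bins excluded)
    scr, sub = screen_now()
    bins_all = (sub["corrected_age_est"] // 10).astype(int)
    bin_sizes = bins_all.value_counts()
    cap = {b: int(0.40 * m) for b, m in bin_sizes.items() if m >= 2}
    used: dict[int, int] = {}
    stunted: list[str] = []

    def try_add(tid) -> bool:
        b = bins_all[tid]
        if b not in cap or used.get(b, 0) >= cap[b]:
            return False
        used[b] = used.get(b, 0) + 1
        stunted.append(tid)
        return True

    for tid in scr.index[~scr["keep"]]:
        if tid in protected or len(stunted) >= n_stunted:
            continue
        if not try_add(tid):
            lift(tid, scr, sub)  # natural failure beyond its bin cap: lift it
    for t in fill_order:
        if len(stunted) >= n_stunted:
            break
        if t not in stunted and t not in protected and t in scr.index:
            try_add(t)
    if len(stunted) < n_stunted:
        raise RuntimeError("not enough candidate trees to plant the stunted set")

    for factor in (0.7, 0.55, 0.4, 0.3):
        for _ in range(60):
            scr, sub = screen_now()
            removed = set(scr.index[~scr["keep"]])
            if removed == set(stunted):
                trees["cr_m"] = trees[_RADII_COLS].mean(axis=1)
                return trees, set(stunted)
            for tid in stunted:
                if tid in removed:
                    continue
                for param in ("dbh_cm", "h_m", "cw_m2"):
                    bins, stats = bin_stats(sub, param)
                    if bins[tid] in stats:
                        _, tau = stats[bins[tid]]
                        if sub.loc[tid, param] >= tau:
                            _set_param(trees, tid, param, factor * tau)
            for tid in removed - set(stunted):
                lift(tid, scr, sub)
    raise RuntimeError("could not plant stunted trees below the screening threshold")


def generate_study(seed: int = 0) -> StudyData:
    """Default synthetic study: a 40 m-radius plot with 111 adults in three
    age classes (Y 56 / M 31 / O 24) plus 50 established-regeneration
    plantlets, 222 cores with 26 planted undatable (year-shuffled) cores on
    O-class trees, and 33 planted stunted trees among the 103 trees that
    survive cross-dating — so the screening chain retains exactly 70."""
    root = np.random.SeedSequence(seed)
    rng_sp, rng_age, rng_bio, rng_ring, rng_pick = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    radius = 40.0
    window = Window(radius)

    # --- spatial structure: O random, M inhibited + repelled from O, Y and
    # ER clustered (Thomas)
    o_xy, _ = _sample_class(rng_sp, Poisson(), 24, radius)
    m_xy, _ = _sample_class(rng_sp, Hardcore(3.0), 31, radius, avoid=o_xy, min_cross=6.0)
    y_xy, _ = _sample_class(rng_sp, ThomasCluster(parent_intensity=8.5e-4, cluster_sd=2.5), 56, radius)
    er_xy, _ = _sample_class(rng_sp, ThomasCluster(parent_intensity=7e-4, cluster_sd=2.0), 50, radius)

    labels = ["O"] * 24 + ["M"] * 31 + ["Y"] * 56
    adult_xy = np.vstack([o_xy, m_xy, y_xy])
    pattern = PointPattern(
        np.vstack([adult_xy, er_xy]), window, labels + ["ER"] * 50
    )

    # --- ages at coring height and the coring-height correction
    ages = {}
    tree_ids = []
    # corrected ages then sit at ~111-142 (O) vs <= ~80 (M): a > 30 yr
    # recruitment gap separating the old cohort from the mature/young block
    for lab, n, (lo, hi) in (("O", 24, (106, 136)), ("M", 31, (41, 70)), ("Y", 56, (28, 40))):
        for i in range(n):
            tid = f"{lab}{i + 1:03d}"
            tree_ids.append(tid)
            ages[tid] = int(rng_age.integers(lo, hi + 1))
    # anchor trees guarantee the young chronology reaches back 40 years
    anchors = [f"Y{i + 1:03d}" for i in range(6)]
    for tid in anchors:
        ages[tid] = 40

    y2a = {
        tid: int(np.clip(round(16.0 - 0.1 * a + rng_age.normal(0.0, 0.5)), 0, None))
        for tid, a in ((t, ages[t]) for t in tree_ids)
    }
    sampled = sorted(rng_age.choice(tree_ids, size=len(tree_ids) // 2, replace=False))
    age_pairs = pd.DataFrame(
        {"age_at_dbh": [ages[t] for t in sampled], "ring_diff": [y2a[t] for t in sampled]}
    )

    # --- biometrics from corrected age (allometric means, lognormal noise)
    rows = []
    for idx, tid in enumerate(tree_ids):
        age_c = ages[tid] + y2a[tid]
        dbh = 50.0 * (1 - math.exp(-0.008 * age_c)) * math.exp(rng_bio.normal(0, 0.10))
        h = 1.3 + 16.0 * (1 - math.exp(-0.013 * age_c)) * math.exp(rng_bio.normal(0, 0.08))
        cr = 5.5 * (1 - math.exp(-0.013 * age_c))
        radii = np.maximum(cr * (1 + rng_bio.normal(0, 0.12, 4)), 0.2)
        x, y = adult_xy[idx]
        rows.append(
            dict(
                tree_id=tid,
                x=x,
                y=y,
                distance_m=math.hypot(x, y),
                azimuth_deg=math.degrees(math.atan2(x, y)) % 360.0,
                dbh_cm=dbh,
                h_m=h,
                cw_n_m=radii[0],
                cw_e_m=radii[1],
                cw_s_m=radii[2],
                cw_w_m=radii[3],
                age_dbh=ages[tid],
                years_to_add=y2a[tid],
                corrected_age=ages[tid] + y2a[tid],
                age_class=tid[0],
            )
        )
    trees = pd.DataFrame(rows)
    trees["cw_m2"] = _crown_area(trees[["cw_n_m", "cw_e_m", "cw_s_m", "cw_w_m"]].to_numpy())
    trees["cr_m"] = trees[["cw_n_m", "cw_e_m", "cw_s_m", "cw_w_m"]].mean(axis=1)
    # the screening stage bins trees by the *estimated* corrected age (ring
    # count at DBH plus the fitted coring-height correction), so the planted
    # stunted structure must be built against that same estimate
    age_model = fit_age_correction(age_pairs)
    trees["corrected_age_est"] = trees["age_dbh"] + age_model.predict(trees["age_dbh"].to_numpy())

    # --- climate and ring series
    climate = generate_climate(ClimateScenario(start_year=1856, end_year=1997, seed=int(root.spawn(1)[0].generate_state(1)[0] % 2**31)))
    signal = climate_signal(climate, DEFAULT_BETA)

    # pith-reaching cores: 25, spread over classes, anchors first
    o_ids = [t for t in tree_ids if t.startswith("O")]
    m_ids = [t for t in tree_ids if t.startswith("M")]
    y_ids = [t for t in tree_ids if t.startswith("Y")]
    pith_trees = anchors + o_ids[:6] + m_ids[:7] + [t for t in y_ids if t not in anchors][:6]
    pith_cores = {f"{t}A" for t in pith_trees}  # 25 cores

    series: list[RingSeries] = []
    for tid in tree_ids:
        curve = DEFAULT_AGE_CURVES[tid[0]]
        offs = []
        for c in range(2):
            cid = f"{tid}{chr(ord('A') + c)}"
            if cid in pith_cores or tid in anchors:
                offs.append(0)
            else:
                offs.append(int(rng_ring.integers(1, 6)))
        series.extend(
            simulate_tree_cores(
                rng_ring, tid, curve, ages[tid], offs, signal,
                phi=0.6, sigma=0.138, sigma_core=0.141, end_year=1997,
            )
        )

    # --- plant 26 undatable cores on O trees: 8 trees lose both cores,
    # 10 trees lose one -> 103 trees keep at least one datable core
    both_bad = o_ids[6:14]
    one_bad = o_ids[14:24]
    bad_cores = {f"{t}A" for t in both_bad} | {f"{t}B" for t in both_bad} | {f"{t}B" for t in one_bad}
    assert len(bad_cores) == 26
    for s in series:
        if s.core_id in bad_cores:
            s.widths = rng_pick.permutation(s.widths)

    survivors = [t for t in tree_ids if t not in both_bad]
    assert len(survivors) == 103

    # --- plant 33 stunted trees among the survivors; trees failing the
    # 2-of-3 screen by natural spread are adopted into the set, the rest
    # filled mostly from Y (mirrors the high Y variability), O kept last
    surviving_o = [t for t in o_ids if t not in both_bad]
    protected = set(anchors)
    fill_order = (
        [t for t in y_ids if t not in protected]
        + m_ids
        + [t for t in surviving_o if t not in pith_trees]
    )
    ring_counts = {}
    for s in series:
        if s.core_id not in bad_cores:
            ring_counts[s.tree_id] = max(ring_counts.get(s.tree_id, 0), len(s.widths))
    trees, stunted = _plant_screening_truth(
        trees, survivors, ring_counts, protected, fill_order, n_stunted=33
    )

    regeneration = pd.DataFrame(
        {
            "id": [f"ER{i + 1:03d}" for i in range(50)],
            "x": er_xy[:, 0],
            "y": er_xy[:, 1],
            "age": rng_age.integers(3, 16, 50),
        }
    )

    truth = {
        "bad_cores": bad_cores,
        "lost_trees": set(both_bad),
        "surviving_trees": set(survivors),
        "stunted_trees": set(stunted),
        "retained_trees": set(survivors) - set(stunted),
        "anchor_trees": set(anchors),
        "pith_cores": pith_cores,
        "beta": dict(DEFAULT_BETA),
    }
    return StudyData(trees, pattern, regeneration, series, climate, age_pairs, truth)
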