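"""End-to-end analysis pipeline for one stand.

Stages: (1) obtain the stand (synthesize, or read stem map / RWL / climate
files); (2) spatial point-pattern analysis per age class and between
classes; (3) cross-dating screen of the cores against the master (discard
r < 0.40 or undatable); (4) tree-level series, age correction and age
structure; (5) biometric screening; (6) class-specific detrending and
chronology statistics; (7) bootstrap response functions for the P-Tmax and
P-Tmin designs.

All randomness flows from the single configured seed through named
substreams, so changing the simulation count of one stage does not perturb
another; the same seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .chronology import Chronology, build_chronology, detrend, fit_regional_curve
from .climate import bootstrap_response_function, build_regressor_matrix
from .spatial import PointPattern, Window, bivariate_null_envelope, csr_envelope
from .synthetic import StudyData, generate_study
from .treering import (
    AgeModel,
    RingSeries,
    age_structure,
    assign_age_class,
    biometric_screen,
    correlation_with_master,
    coefficient_of_variation,
    fit_age_correction,
)

log = logging.getLogger("dendrostand")

__all__ = ["PipelineConfig", "run_pipeline", "substream", "crossdate_screen", "DEFAULT_AGE_MODEL"]

# fallback coring-height correction (years to add vs age at DBH) when no
# ground-level recount pairs are available
DEFAULT_AGE_MODEL = AgeModel(intercept=16.0, slope=-0.1, n=0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of the top-level seed."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, child]))


@dataclass
class PipelineConfig:
    """Every constant of the analysis in one place."""

    # inputs; all None -> synthesize the default study
    stem_map: str | None = None
    rwl: str | None = None
    climate_csv: str | None = None
    # spatial
    window_radius: float = 40.0
    d_max: float = 40.0
    step: float = 1.0
    n_sims: int = 99
    envelope_level: float = 0.95
    edge_correction: str = "none"
    # screening
    master_r_threshold: float = 0.40
    min_overlap: int = 20
    min_rings: int = 20
    min_params: int = 2
    biometric_bin_width: int = 10
    # ages / chronology
    age_bin_width: int = 5
    detrend_per_class: dict = field(default_factory=lambda: {"Y": "rcs", "M": "negexp", "O": "spline"})
    aggregation: str = "mean"
    # response functions
    n_boot: int = 1000
    period: tuple = (1958, 1997)
    temperature_designs: tuple = ("tmax", "tmin")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_radius", "d_max", "step", "n_sims", "envelope_level",
                     "master_r_threshold", "min_overlap", "min_rings", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["period"] = list(self.period)
        d["temperature_designs"] = list(self.temperature_designs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "period" in d:
            d["period"] = tuple(d["period"])
        if "temperature_designs" in d:
            d["temperature_designs"] = tuple(d["temperature_designs"])
        return cls(**d)


# ---------------------------------------------------------------------------
# cross-dating


def _highpass_index(series: RingSeries) -> pd.Series:
    wl = min(32.0, 0.67 * len(series.widths))  # short-wavelength spline, COFECHA-style
    res = detrend(series, method="spline", stiffness=wl)
    return pd.Series(res.index, index=series.years, name=series.core_id)


def crossdate_screen(
    series: list[RingSeries],
    r_threshold: float = 0.40,
    min_overlap: int = 20,
) -> tuple[list[RingSeries], pd.DataFrame]:
    """Screen cores against the leave-one-out master of detrended indices.

    Returns the kept series and a per-core report (r, flag).
    """
    idx = pd.DataFrame({s.core_id: _highpass_index(s) for s in series}).sort_index()
    total = idx.sum(axis=1)
    depth = idx.notna().sum(axis=1)
    report = []
    kept = []
    for s in series:
        col = idx[s.core_id]
        loo_depth = depth - col.notna().astype(int)
        with np.errstate(invalid="ignore"):
            master = (total - col.fillna(0.0)) / loo_depth.replace(0, np.nan)
        r, flag = correlation_with_master(col.dropna(), master.dropna(),
                                          min_overlap=min_overlap, r_threshold=r_threshold)
        report.append({"core_id": s.core_id, "tree_id": s.tree_id, "r_master": r, "flag": flag})
        if flag == "keep":
            kept.append(s)
    return kept, pd.DataFrame(report).set_index("core_id")


def _tree_level_series(cores: list[RingSeries]) -> dict[str, RingSeries]:
    """Average the kept cores of each tree into one series (mean width per
    year over the cores covering that year)."""
    by_tree: dict[str, list[RingSeries]] = {}
    for s in cores:
        by_tree.setdefault(s.tree_id, []).append(s)
    out: dict[str, RingSeries] = {}
    for tid, group in by_tree.items():
        frame = pd.DataFrame({s.core_id: s.to_series() for s in group}).sort_index()
        mean_w = frame.mean(axis=1)
        age_est = max(len(s.widths) + s.pith_offset_rings for s in group)
        rings = len(mean_w)
        out[tid] = RingSeries(
            tree_id=tid,
            core_id=tid,
            first_year=int(mean_w.index[0]),
            widths=mean_w.to_numpy(),
            pith_reached=any(s.pith_reached for s in group),
            pith_offset_rings=age_est - rings,
        )
    return out


# ---------------------------------------------------------------------------
# the pipeline


def _spatial_stage(pattern: PointPattern, cfg: PipelineConfig, outdir: Path) -> dict:
    results = {}
    classes = [c for c in ("Y", "M", "O", "ER") if (pattern.marks == c).any()]
    adults = pattern.subset("Y", "M", "O")
    rng = substream(cfg.seed, "spatial")
    targets = {"all_adults": adults}
    for c in classes:
        targets[c] = pattern.subset(c)
    for name, pat in targets.items():
        res = csr_envelope(pat, n_sims=cfg.n_sims, level=cfg.envelope_level,
                           d_max=cfg.d_max, step=cfg.step, rng=rng,
                           edge_correction=cfg.edge_correction)
        res.to_frame().to_csv(outdir / f"spatial_univariate_{name}.csv", index=False)
        results[("uni", name)] = res
    pairs = [(a, b) for a, b in (("Y", "M"), ("Y", "O"), ("M", "O")) if a in classes and b in classes]
    for a, b in pairs:
        res = bivariate_null_envelope(pattern, a, b, n_sims=cfg.n_sims,
                                      level=cfg.envelope_level, d_max=cfg.d_max,
                                      step=cfg.step, rng=rng,
                                      edge_correction=cfg.edge_correction)
        res.to_frame().to_csv(outdir / f"spatial_bivariate_{a}_vs_{b}.csv", index=False)
        results[("biv", a, b)] = res
    if "ER" in classes:
        merged = PointPattern(
            pattern.xy, pattern.window,
            np.where(pattern.marks == "ER", "ER", "A"),
        )
        res = bivariate_null_envelope(merged, "ER", "A", n_sims=cfg.n_sims,
                                      level=cfg.envelope_level, d_max=cfg.d_max,
                                      step=cfg.step, rng=rng,
                                      edge_correction=cfg.edge_correction)
        res.to_frame().to_csv(outdir / "spatial_bivariate_ER_vs_adults.csv", index=False)
        results[("biv", "ER", "A")] = res
    return results


def _table1(trees: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for c in ("Y", "M", "O"):
        sub = trees[trees["age_class"] == c]
        if sub.empty:
            continue
        row = {"age_class": c, "n_trees": len(sub)}
        for col, name in (("dbh_cm", "dbh"), ("h_m", "h"), ("cw_m2", "cw"), ("cr_m", "cr")):
            row[f"{name}_mean"] = sub[col].mean()
            row[f"{name}_sd"] = sub[col].std(ddof=1)
            row[f"{name}_cv_pct"] = coefficient_of_variation(sub[col].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir, data: StudyData | None = None) -> dict:
    """Run the full chain and write the report bundle to ``outdir``."""
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 0: data
    if data is None:
        if cfg.stem_map is not None:
            trees, _ = dio.read_stem_map(cfg.stem_map, cfg.window_radius)
            trees = trees.rename(columns={"id": "tree_id"})
            series = dio.read_rwl(cfg.rwl)
            climate = dio.read_climate(cfg.climate_csv)
            regeneration = None
            age_pairs = None
        else:
            log.info("no input files given: synthesizing the default study (seed=%d)", cfg.seed)
            data = generate_study(cfg.seed)
    if data is not None:
        trees = data.trees.copy()
        series = list(data.series)
        climate = data.climate
        regeneration = data.regeneration
        age_pairs = data.age_pairs

    # --- stage 1: cross-dating screen
    kept_cores, core_report = crossdate_screen(series, cfg.master_r_threshold, cfg.min_overlap)
    discarded = core_report[core_report["flag"] != "keep"]
    core_report.to_csv(outdir / "crossdating_report.csv")
    discarded.to_csv(outdir / "discarded_cores.csv")
    log.info("cross-dating: %d of %d cores discarded", len(discarded), len(series))

    # --- stage 2: tree-level series, ages, classes
    tree_series = _tree_level_series(kept_cores)
    age_model = fit_age_correction(age_pairs) if age_pairs is not None and len(age_pairs) >= 3 else DEFAULT_AGE_MODEL
    rows = []
    for tid, s in tree_series.items():
        age_dbh = len(s.widths) + s.pith_offset_rings
        corr_age = age_dbh + int(age_model.predict(age_dbh))
        # chronological classes follow the age at coring height
        rows.append({"tree_id": tid, "age_dbh_est": age_dbh, "corrected_age": corr_age,
                     "age_class": assign_age_class(age_dbh)})
    ages = pd.DataFrame(rows).set_index("tree_id")
    trees = trees.set_index("tree_id")
    trees.loc[ages.index, "age_dbh_est"] = ages["age_dbh_est"]
    trees.loc[ages.index, "corrected_age_est"] = ages["corrected_age"]
    trees.loc[ages.index, "age_class_est"] = ages["age_class"]

    hist_ages = trees.loc[ages.index, "corrected_age_est"].dropna()
    age_structure(hist_ages.to_numpy(), cfg.age_bin_width).to_csv(
        outdir / "age_structure.csv", index=False
    )

    # --- stage 3: spatial patterns (all mapped stems, marks from age class)
    marks = trees["age_class"].astype(str).to_numpy() if "age_class" in trees.columns else trees["age_class_est"].fillna("").to_numpy()
    xy = trees[["x", "y"]].to_numpy()
    if regeneration is not None and len(regeneration):
        xy = np.vstack([xy, regeneration[["x", "y"]].to_numpy()])
        marks = np.concatenate([marks, ["ER"] * len(regeneration)])
    pattern = PointPattern(xy, Window(cfg.window_radius), marks)
    spatial_results = _spatial_stage(pattern, cfg, outdir)

    # --- stage 4: biometric screening
    screen_in = trees.loc[ages.index, ["dbh_cm", "h_m", "cw_m2"]].copy()
    screen_in.columns = ["dbh", "h", "cw"]
    screen_in["age"] = trees.loc[ages.index, "corrected_age_est"]
    ring_counts = {tid: len(s.widths) for tid, s in tree_series.items()}
    screen = biometric_screen(screen_in, ring_counts,
                              bin_width=cfg.biometric_bin_width,
                              min_params=cfg.min_params, min_rings=cfg.min_rings)
    screen.to_csv(outdir / "biometric_screen.csv")
    retained = sorted(screen.index[screen["keep"]])
    log.info("biometric screen: %d of %d trees retained", len(retained), len(screen))

    # --- stage 5: detrending and chronologies per class
    table1 = _table1(trees.reset_index())
    table1.to_csv(outdir / "table1_biometrics.csv", index=False)

    chronologies: dict[str, Chronology] = {}
    table2_rows = []
    response_results: dict[tuple[str, str], object] = {}
    rng_boot = substream(cfg.seed, "response")
    for c in ("Y", "M", "O"):
        ids = [t for t in retained if ages.loc[t, "age_class"] == c]
        if not ids:
            continue
        cohort = [tree_series[t] for t in ids]
        method = cfg.detrend_per_class.get(c, "spline")
        regional = fit_regional_curve(cohort) if method == "rcs" else None
        index_map, raw_map = {}, {}
        for s in cohort:
            res = detrend(s, method=method, regional_curve=regional)
            index_map[s.tree_id] = pd.Series(res.index, index=s.years)
            raw_map[s.tree_id] = s.to_series()
        chron = build_chronology(index_map, label=c, raw_series=raw_map,
                                 aggregation=cfg.aggregation, min_overlap=cfg.min_overlap)
        chronologies[c] = chron
        chron.to_frame().to_csv(outdir / f"chronology_{c}.csv")
        mrw = float(np.mean([s.mean_ring_width for s in cohort]))
        row = {
            "age_class": c, "n_trees": len(ids),
            "n_cores": int(sum(1 for k in kept_cores if k.tree_id in ids)),
            "first_year": int(chron.index.index.min()),
            "last_year": int(chron.index.index.max()),
            "mrw_mm": mrw, "msm": chron.stats.msm, "msi": chron.stats.msi,
            "cc": chron.stats.cc, "cm": chron.stats.cm,
            "ac1_raw": chron.stats.ac1_raw, "ac1_std": chron.stats.ac1_std,
        }
        # --- stage 6: response functions
        y0, y1 = cfg.period
        idx = chron.index.loc[(chron.index.index >= y0) & (chron.index.index <= y1)]
        if len(idx) == (y1 - y0 + 1):
            for temp in cfg.temperature_designs:
                X = build_regressor_matrix(climate, y0, y1, temperature=temp)
                rf = bootstrap_response_function(idx.set_axis(X.index), X,
                                                 n_boot=cfg.n_boot, rng=rng_boot)
                response_results[(c, temp)] = rf
                rf.coefficients.to_csv(outdir / f"response_{c}_{temp}.csv")
                row[f"rv_{temp}"] = rf.r_v
                row[f"r_over_s_{temp}"] = rf.r_over_s
                row[f"p_{temp}"] = rf.p_band
        else:
            log.warning("class %s chronology does not cover %d-%d; response skipped", c, y0, y1)
        table2_rows.append(row)
    table2 = pd.DataFrame(table2_rows)
    table2.to_csv(outdir / "table2_chronology_response.csv", index=False)

    summary = {
        "n_cores_in": len(series),
        "n_cores_discarded": int(len(discarded)),
        "n_trees_with_cores": int(len(screen)),
        "n_trees_retained": len(retained),
        "response": {
            f"{c}_{t}": {"r_v": r.r_v, "r_over_s": r.r_over_s, "p": r.p_band}
            for (c, t), r in response_results.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_schema(outdir)
    return {
        "trees": trees,
        "pattern": pattern,
        "spatial": spatial_results,
        "core_report": core_report,
        "screen": screen,
        "retained": retained,
        "chronologies": chronologies,
        "table1": table1,
        "table2": table2,
        "response": response_results,
        "summary": summary,
    }


def _write_schema(outdir: Path) -> None:
    schema = {
        "spatial_*.csv": {"d_m": "distance (m)", "k_m2": "Ripley K (m^2)",
                          "l_m": "Besag L (m)", "env_low_m": "envelope lower bound (m)",
                          "env_high_m": "envelope upper bound (m)",
                          "classification": "per-distance pattern label"},
        "age_structure.csv": {"midpoint": "age-class midpoint (yr)", "count": "trees"},
        "crossdating_report.csv": {"r_master": "Pearson r with leave-one-out master",
                                   "flag": "keep | discard | undatable"},
        "biometric_screen.csv": {"n_params_passed": "of DBH/H/CW above bin mean - sd",
                                 "rings": "measured rings", "keep": "retained for climate analysis"},
        "table1_biometrics.csv": {"*_mean": "class mean (cm, m, m^2)", "*_sd": "sample sd",
                                  "*_cv_pct": "100*sd/mean (%)"},
        "chronology_*.csv": {"index": "standardized master index (dimensionless)",
                             "depth": "sample depth (trees)"},
        "response_*.csv": {"mean_coef": "mean bootstrap standardized coefficient",
                           "sd_coef": "bootstrap sd", "significant": "|mean/sd| >= 1.96"},
        "table2_chronology_response.csv": {"mrw_mm": "mean ring width (mm)",
                                           "msm/msi": "mean sensitivity (master / mean of series)",
                                           "cc": "mean inter-series correlation",
                                           "cm": "mean correlation with master",
                                           "ac1_raw/ac1_std": "lag-1 autocorrelation",
                                           "rv_*": "mean verification correlation R_V",
                                           "r_over_s_*": "R_V / sd", "p_*": "significance band"},
    }
    (outdir / "schema.json").write_text(json.dumps(schema, indent=2))
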