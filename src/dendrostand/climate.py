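"""Bootstrap orthogonalized response functions of tree growth on climate.

The design matrix holds 24 monthly regressors over the *biological year* —
October of the year preceding growth (t-1) through September of the growth
year (t): 12 monthly precipitation totals plus either the 12 monthly
maximum or the 12 monthly minimum temperatures (the two designs are always
run separately, never joined).

For each of ``n_boot`` bootstrap replications, calibration years are drawn
with replacement and the out-of-bag years form the verification set.  The
regressors are standardized on the calibration sample, orthogonalized by
principal components (components with eigenvalue above the mean retained),
the chronology regressed on the retained components, and the coefficients
back-rotated to the original regressors.  A regressor is significant when
|mean coefficient| / bootstrap sd >= 1.96.  The verification correlation
R_V is the mean Pearson r between predicted and observed indices on the
out-of-bag years; its ratio to the across-replicate sd (r/s) is the global
significance statistic: >= 1.96 in absolute value maps to p < 0.05,
>= 1.645 to p < 0.1, else not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BIOLOGICAL_YEAR_MONTHS",
    "ClimateMatrix",
    "ResponseFunctionResult",
    "build_regressor_matrix",
    "bootstrap_response_function",
    "pband_label",
]

# month order of the biological year: Oct(t-1) .. Sep(t)
BIOLOGICAL_YEAR_MONTHS: list[tuple[int, bool]] = [
    (10, True), (11, True), (12, True),
    (1, False), (2, False), (3, False), (4, False), (5, False), (6, False),
    (7, False), (8, False), (9, False),
]
_ABBR = {1: "jan", 2: "feb", 3: "mar", 4: "apr", 5: "may", 6: "jun",
         7: "jul", 8: "aug", 9: "sep", 10: "oct", 11: "nov", 12: "dec"}


def regressor_names(temperature: str) -> list[str]:
    names = []
    for var in ("p", temperature):
        for month, prev in BIOLOGICAL_YEAR_MONTHS:
            names.append(f"{var}_{_ABBR[month]}{'_prev' if prev else ''}")
    return names


ClimateMatrix = pd.DataFrame  # rows: growth years; 24 named monthly regressors


def build_regressor_matrix(
    climate: pd.DataFrame,
    start_year: int,
    end_year: int,
    temperature: str = "tmax",
) -> ClimateMatrix:
    """24-column biological-year design matrix for growth years
    ``start_year..end_year``.

    ``climate`` is a long monthly table with columns year, month, p_mm,
    tmax_c, tmin_c; it must cover October(start_year-1) through
    September(end_year) with no missing month.
    """
    if temperature not in ("tmax", "tmin"):
        raise ValueError("temperature must be 'tmax' or 'tmin'")
    if end_year < start_year:
        raise ValueError("empty year range")
    col = {"p": "p_mm", "tmax": "tmax_c", "tmin": "tmin_c"}
    lut = climate.set_index(["year", "month"])
    years = np.arange(start_year, end_year + 1)
    missing = []
    data: dict[str, list[float]] = {}
    for var in ("p", temperature):
        for month, prev in BIOLOGICAL_YEAR_MONTHS:
            name = f"{var}_{_ABBR[month]}{'_prev' if prev else ''}"
            vals = []
            for y in years:
                key = (y - 1 if prev else y, month)
                try:
                    vals.append(float(lut.loc[key, col[var]]))
                except KeyError:
                    missing.append(key)
                    vals.append(np.nan)
            data[name] = vals
    if missing:
        raise ValueError(f"climate table is missing months: {sorted(set(missing))[:10]}")
    return pd.DataFrame(data, index=pd.Index(years, name="year"))


def pband_label(r_over_s: float) -> str:
    """Significance band of the verification statistic |r/s|."""
    if not np.isfinite(r_over_s):
        raise ValueError("r/s must be finite")
    a = abs(r_over_s)
    if a >= 1.96:
        return "<0.05"
    if a >= 1.645:
        return "<0.1"
    return "ns"


@dataclass
class ResponseFunctionResult:
    coefficients: pd.DataFrame  # per regressor: mean_coef, sd_coef, significant
    r_v: float  # mean verification correlation
    r_over_s: float  # R_V / sd of verification correlations
    p_band: str
    n_bootstrap: int
    verification_r: np.ndarray

    def significant_regressors(self) -> list[str]:
        return self.coefficients.index[self.coefficients["significant"]].tolist()


def bootstrap_response_function(
    indices: pd.Series,
    matrix: ClimateMatrix,
    n_boot: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    retain: str | int = "mean_eigenvalue",
) -> ResponseFunctionResult:
    """Bootstrap orthogonalized response function of a chronology.

    ``indices`` and ``matrix`` must share an identical year index.
    ``retain`` selects principal components by the mean-eigenvalue
    (Guttman) rule or as a fixed count.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not indices.index.equals(matrix.index):
        raise ValueError("chronology and climate matrix must cover identical years")
    X = matrix.to_numpy(dtype=float)
    y = indices.to_numpy(dtype=float)
    n, p = X.shape
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = matrix.columns[np.flatnonzero(sds == 0)][0]
        raise ValueError(f"degenerate (constant) regressor: {bad}")
    if isinstance(retain, int) and not 0 < retain <= p:
        raise ValueError("retained component count out of range")
    if n <= (retain if isinstance(retain, int) else 2):
        raise ValueError("need more years than retained components")

    coefs = np.empty((n_boot, p))
    ver_r = np.empty(n_boot)
    all_idx = np.arange(n)
    b = 0
    guard = 0
    while b < n_boot:
        guard += 1
        if guard > 50 * n_boot:
            raise RuntimeError("bootstrap failed to produce valid replicates")
        cal = rng.integers(0, n, n)
        oob = np.setdiff1d(all_idx, cal)
        if len(oob) < 3:
            continue
        Xc, yc = X[cal], y[cal]
        mu, sd = Xc.mean(axis=0), Xc.std(axis=0, ddof=1)
        if np.any(sd == 0) or yc.std() == 0:
            continue
        Zc = (Xc - mu) / sd
        y_mu, y_sd = yc.mean(), yc.std(ddof=1)
        yz = (yc - y_mu) / y_sd
        corr = (Zc.T @ Zc) / (n - 1)
        eigval, eigvec = np.linalg.eigh(corr)
        if retain == "mean_eigenvalue":
            keep = eigval > eigval.mean()
        else:
            keep = np.zeros(p, dtype=bool)
            keep[np.argsort(eigval)[-int(retain):]] = True
        E = eigvec[:, keep]
        U = Zc @ E
        c, *_ = np.linalg.lstsq(U, yz, rcond=None)
        beta = E @ c  # back-rotated standardized coefficients
        Zo = (X[oob] - mu) / sd
        pred = Zo @ beta
        yo = y[oob]
        if pred.std() == 0 or yo.std() == 0:
            continue
        coefs[b] = beta
        ver_r[b] = float(np.corrcoef(pred, yo)[0, 1])
        b += 1

    mean_c = coefs.mean(axis=0)
    sd_c = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        signif = np.abs(mean_c / sd_c) >= 1.96
    table = pd.DataFrame(
        {"mean_coef": mean_c, "sd_coef": sd_c, "significant": signif},
        index=matrix.columns,
    )
    r_v = float(ver_r.mean())
    s = float(ver_r.std(ddof=1))
    r_over_s = r_v / s if s > 0 else float("inf") * np.sign(r_v)
    return ResponseFunctionResult(
        coefficients=table,
        r_v=r_v,
        r_over_s=float(r_over_s),
        p_band=pband_label(r_over_s),
        n_bootstrap=n_boot,
        verification_r=ver_r,
    )
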