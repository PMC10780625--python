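"""File formats: stem-map CSV, Tucson RWL ring-width files, climate CSV.

Stem maps use field-convention polar coordinates — azimuth in degrees
clockwise from north, distance in metres from the plot centre — so
``x = r*sin(theta)``, ``y = r*cos(theta)``.  Crown projection area is the
quarter-ellipse approximation from the four cardinal crown radii,
``CW = pi/4 * (rN*rE + rE*rS + rS*rW + rW*rN)`` (exactly ``pi*r**2`` when
all four radii are equal), and CR is their plain mean.

RWL files follow the decadal Tucson layout in 0.01 mm units; both the
``999`` and ``-9999`` stop markers are accepted on read, ``999`` is
written.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spatial import PointPattern, Window
from .treering import RingSeries

__all__ = [
    "read_stem_map",
    "write_stem_map",
    "read_rwl",
    "write_rwl",
    "read_climate",
    "write_climate",
    "crown_area",
]

STEM_COLUMNS = ["id", "azimuth_deg", "distance_m", "dbh_cm", "h_m",
                "cw_n_m", "cw_e_m", "cw_s_m", "cw_w_m"]
CLIMATE_COLUMNS = ["year", "month", "p_mm", "tmax_c", "tmin_c"]


def crown_area(rn, re, rs, rw) -> np.ndarray:
    """Quarter-ellipse crown projection area from four cardinal radii (m^2)."""
    rn, re, rs, rw = (np.asarray(v, dtype=float) for v in (rn, re, rs, rw))
    return (math.pi / 4.0) * (rn * re + re * rs + rs * rw + rw * rn)


def polar_to_xy(azimuth_deg, distance_m) -> tuple[np.ndarray, np.ndarray]:
    theta = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    r = np.asarray(distance_m, dtype=float)
    return r * np.sin(theta), r * np.cos(theta)


def read_stem_map(path, window_radius: float = 40.0) -> tuple[pd.DataFrame, PointPattern]:
    """Stem-map CSV -> (tree table with derived columns, marked PointPattern).

    An optional ``age_class`` column provides the marks; a point farther
    from the centre than ``window_radius`` raises an error naming the tree.
    """
    df = pd.read_csv(path)
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stem map is missing columns: {missing}")
    outside = df.loc[df["distance_m"] > window_radius * (1 + 1e-9), "id"]
    if len(outside):
        raise ValueError(f"tree(s) outside the plot window: {outside.tolist()}")
    df = df.copy()
    df["x"], df["y"] = polar_to_xy(df["azimuth_deg"], df["distance_m"])
    df["cw_m2"] = crown_area(df["cw_n_m"], df["cw_e_m"], df["cw_s_m"], df["cw_w_m"])
    df["cr_m"] = df[["cw_n_m", "cw_e_m", "cw_s_m", "cw_w_m"]].mean(axis=1)
    marks = df["age_class"].astype(str).tolist() if "age_class" in df.columns else None
    pattern = PointPattern(df[["x", "y"]].to_numpy(), Window(window_radius), marks)
    return df, pattern


def write_stem_map(trees: pd.DataFrame, path) -> None:
    cols = [c for c in STEM_COLUMNS + ["age_class"] if c in trees.columns]
    out = trees.rename(columns={"tree_id": "id"}) if "tree_id" in trees.columns else trees
    cols = [c for c in STEM_COLUMNS + ["age_class"] if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Tucson RWL

_STOP_MARKERS = (999, -9999)


def write_rwl(series: Iterable[RingSeries], path) -> None:
    """Decadal Tucson layout, units 0.01 mm, stop marker 999."""
    lines = []
    for s in series:
        sid = s.core_id[:8]
        vals = [int(round(w * 100)) for w in s.widths]
        year = s.first_year
        pos = 0
        stop_written = False
        while pos < len(vals):
            decade_end = (year // 10) * 10 + 9
            take = min(decade_end - year + 1, len(vals) - pos)
            chunk = vals[pos : pos + take]
            fields = "".join(f"{v:6d}" for v in chunk)
            if pos + take == len(vals) and take < 10:
                fields += f"{999:6d}"
                stop_written = True
            lines.append(f"{sid:<8}{year:4d}{fields}")
            pos += take
            year += take
        if not stop_written:
            lines.append(f"{sid:<8}{year:4d}{999:6d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rwl(path) -> list[RingSeries]:
    """Parse a Tucson RWL file into per-core ring series (widths in mm)."""
    text = Path(path).read_text()
    segments: dict[str, dict] = {}
    order: list[str] = []
    finished: list[RingSeries] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:].split()
        if not sid or len(rest) < 1:
            raise ValueError(f"malformed RWL line {lineno}: {raw!r}")
        try:
            year = int(rest[0])
            tokens = [int(t) for t in rest[1:]]
        except ValueError as exc:
            raise ValueError(f"malformed RWL line {lineno}: {raw!r}") from exc
        seg = segments.get(sid)
        if seg is None:
            seg = segments[sid] = {"first_year": year, "values": [], "next_year": year}
            order.append(sid)
        elif year != seg["next_year"]:
            raise ValueError(
                f"RWL line {lineno}: year {year} does not continue series {sid} "
                f"(expected {seg['next_year']})"
            )
        ended = False
        for t in tokens:
            if t in _STOP_MARKERS:
                ended = True
                break
            if t <= 0:
                raise ValueError(f"RWL line {lineno}: nonpositive ring width {t}")
            seg["values"].append(t / 100.0)
        seg["next_year"] = seg["first_year"] + len(seg["values"])
        if ended:
            finished.append(
                RingSeries(
                    tree_id=sid[:-1] if len(sid) > 1 else sid,
                    core_id=sid,
                    first_year=seg["first_year"],
                    widths=np.asarray(seg["values"]),
                )
            )
            del segments[sid]
    for sid, seg in segments.items():  # series without explicit stop marker
        if seg["values"]:
            finished.append(
                RingSeries(
                    tree_id=sid[:-1] if len(sid) > 1 else sid,
                    core_id=sid,
                    first_year=seg["first_year"],
                    widths=np.asarray(seg["values"]),
                )
            )
    return finished


# ---------------------------------------------------------------------------
# climate


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"climate table is missing columns: {missing}")
    return df[CLIMATE_COLUMNS]


def write_climate(climate: pd.DataFrame, path) -> None:
    climate[CLIMATE_COLUMNS].to_csv(path, index=False, float_format="%.2f")
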