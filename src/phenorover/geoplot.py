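"""Geo-referencing of raw sensor streams.

Turns the GNSS fixes logged by the platform into planar field coordinates,
reconstructs each boom-mounted sensor's position from the vehicle heading
and its lateral offset, and assigns every reading to the plot polygon (or to
no plot, when the reading was taken over an alley).

The projection is a local spherical equirectangular one: field trials span
well under a kilometre, where the distortion of this projection is below a
centimetre, so no UTM zone logic is needed.
"""

from __future__ import annotations

import json
import logging
import math
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_field import FieldLayout

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres (IUGG mean radius).
EARTH_RADIUS_M = 6_371_008.8

#: Required columns of a multispectral/ultrasonic log file.
SENSOR_LOG_COLUMNS = [
    "iso_timestamp", "lat", "lon", "sensor_id",
    "rho_nir", "rho_red_edge", "rho_red", "distance_m",
]

#: Required columns of an environmental log file.
ENV_LOG_COLUMNS = [
    "iso_timestamp", "lat", "lon", "sensor_id",
    "temp_c", "rh_pct", "pressure_hpa", "par_in", "par_refl",
]

ENV_VARIABLES = ["temp_c", "rh_pct", "pressure_hpa", "par_in", "par_refl"]


def _validate_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("latitude/longitude must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def project(lat, lon, origin: tuple[float, float]):
    """Project geographic coordinates to planar metres east/north of *origin*.

    ``x = R cos(lat0) dlon``, ``y = R dlat`` (angles in radians) on a sphere
    of radius :data:`EARTH_RADIUS_M`. The origin maps to (0, 0).
    """
    _validate_latlon(lat, lon)
    _validate_latlon(*origin)
    lat0, lon0 = origin
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def unproject(x, y, origin: tuple[float, float]):
    """Inverse of :func:`project` for the same origin."""
    lat0, lon0 = origin
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lat, lon


# ---------------------------------------------------------------------------
# Heading estimation and boom-offset correction
# ---------------------------------------------------------------------------

def compute_headings(x, y, half_window: int = 1, block_ids=None):
    """Unit heading vectors along a timestamped fix sequence.

    The heading at fix *i* is the direction of the chord from fix
    ``i - half_window`` to ``i + half_window`` (clamped at block boundaries,
    so endpoints use one-sided chords). ``block_ids`` marks contiguous
    driving passes; chords never cross a block boundary, because the
    (unlogged) turns between passes would corrupt them. Coincident fixes
    carry the previous heading; a leading degenerate fix gets due north.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two fixes to estimate headings")
    if block_ids is None:
        block_ids = np.zeros(n, dtype=int)
    block_ids = np.asarray(block_ids)
    idx = np.arange(n)
    # block start/end index for each fix
    starts = np.empty(n, dtype=int)
    ends = np.empty(n, dtype=int)
    for _, sl in pd.Series(idx).groupby(pd.Series(block_ids)):
        i0, i1 = sl.index[0], sl.index[-1]
        starts[i0:i1 + 1] = i0
        ends[i0:i1 + 1] = i1
    lo = np.maximum(starts, idx - half_window)
    hi = np.minimum(ends, idx + half_window)
    dx = x[hi] - x[lo]
    dy = y[hi] - y[lo]
    norm = np.hypot(dx, dy)
    hx = np.zeros(n)
    hy = np.zeros(n)
    ok = norm > 0
    hx[ok] = dx[ok] / norm[ok]
    hy[ok] = dy[ok] / norm[ok]
    # coincident fixes (or single-fix blocks): carry previous heading,
    # defaulting to due north if there is no previous valid one
    prev_hx, prev_hy = 0.0, 1.0
    for i in range(n):
        if ok[i]:
            prev_hx, prev_hy = hx[i], hy[i]
        else:
            hx[i], hy[i] = prev_hx, prev_hy
    return hx, hy


def apply_lateral_offset(x, y, hx, hy, offset):
    """Shift positions perpendicular to travel; positive = left of travel."""
    offset = np.asarray(offset, dtype=float)
    return x - offset * np.asarray(hy), y + offset * np.asarray(hx)


def heading_and_offset(fixes: pd.DataFrame, lateral_offset: float,
                       half_window: int = 1) -> pd.DataFrame:
    """Offset-corrected positions for one sensor along a fix sequence.

    ``fixes`` needs columns ``x`` and ``y`` (planar metres) in time order;
    an optional ``block`` column separates driving passes.
    """
    blocks = fixes["block"].to_numpy() if "block" in fixes else None
    hx, hy = compute_headings(fixes["x"].to_numpy(), fixes["y"].to_numpy(),
                              half_window=half_window, block_ids=blocks)
    sx, sy = apply_lateral_offset(fixes["x"].to_numpy(), fixes["y"].to_numpy(),
                                  hx, hy, lateral_offset)
    out = fixes.copy()
    out["heading_x"], out["heading_y"] = hx, hy
    out["x"], out["y"] = sx, sy
    return out


# ---------------------------------------------------------------------------
# Plot assignment
# ---------------------------------------------------------------------------

def validate_layout(layout) -> None:
    """Raise if any two plot rectangles overlap (violates the layout model)."""
    rects = np.array([p.rect for p in layout.plots], dtype=float)
    n = len(rects)
    for i in range(n):
        x0, y0, x1, y1 = rects[i]
        others = np.concatenate([rects[:i], rects[i + 1:]]) if n > 1 else rects[:0]
        if len(others) == 0:
            continue
        ox0, oy0, ox1, oy1 = others.T
        if np.any((x0 < ox1) & (ox0 < x1) & (y0 < oy1) & (oy0 < y1)):
            raise ValueError(f"plot rectangles overlap (plot {layout.plots[i].plot_id})")


def assign_plots(x, y, layout, validate: bool = True, chunk: int = 50_000):
    """Plot id containing each point, or ``None``.

    Containment is half-open: a point on a rectangle's lower/left edge
    belongs to it, one on the upper/right edge does not, so a point on the
    shared boundary of two adjacent plots resolves to exactly one of them.
    """
    if not layout.plots:
        raise ValueError("layout has no plots")
    if validate:
        validate_layout(layout)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    rects = np.array([p.rect for p in layout.plots], dtype=float)
    ids = np.array([p.plot_id for p in layout.plots], dtype=object)
    x0, y0, x1, y1 = rects.T
    out = np.full(len(x), None, dtype=object)
    for s in range(0, len(x), chunk):
        xs = x[s:s + chunk, None]
        ys = y[s:s + chunk, None]
        inside = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
        hit = inside.any(axis=1)
        out[s:s + chunk][hit] = ids[inside.argmax(axis=1)[hit]]
    return out


def assign_plot(p: tuple[float, float], layout):
    """Scalar convenience wrapper around :func:`assign_plots`."""
    return assign_plots([p[0]], [p[1]], layout)[0]


# ---------------------------------------------------------------------------
# Layout GeoJSON I/O
# ---------------------------------------------------------------------------

def write_layout_geojson(layout, path) -> None:
    """Write a layout as an RFC 7946 FeatureCollection (WGS84 polygons)."""
    features = []
    for p in layout.plots:
        x0, y0, x1, y1 = p.rect
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
        ring = []
        for cx, cy in corners:
            lat, lon = unproject(cx, cy, layout.origin)
            ring.append([float(lon), float(lat)])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "plot_id": p.plot_id,
                "variety": p.variety,
                "row_spacing_mm": p.row_spacing_mm,
                "density_per_ha": p.density_per_ha,
                "n_rows": p.n_rows,
            },
        })
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "origin": {"lat": layout.origin[0], "lon": layout.origin[1]},
        "grid_rows": layout.grid_rows,
        "grid_cols": layout.grid_cols,
        "alley_width_m": layout.alley_width,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_layout_geojson(path):
    """Read a layout FeatureCollection back into a :class:`FieldLayout`.

    Polygon coordinates (WGS84) are converted to planar field coordinates via
    :func:`project` on load, using the collection's declared origin.
    """
    from .synthetic_field import FieldLayout, PlotSpec

    with open(path) as fh:
        doc = json.load(fh)
    origin = (doc["origin"]["lat"], doc["origin"]["lon"])
    plots = []
    for feat in doc["features"]:
        ring = feat["geometry"]["coordinates"][0]
        lons = [c[0] for c in ring]
        lats = [c[1] for c in ring]
        xs, ys = project(np.array(lats), np.array(lons), origin)
        props = feat["properties"]
        plots.append(PlotSpec(
            plot_id=props["plot_id"],
            rect=(float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())),
            variety=props["variety"],
            row_spacing_mm=props["row_spacing_mm"],
            density_per_ha=props["density_per_ha"],
            n_rows=props.get("n_rows", 4),
        ))
    return FieldLayout(
        plots=plots,
        grid_rows=doc["grid_rows"],
        grid_cols=doc["grid_cols"],
        alley_width=doc["alley_width_m"],
        origin=origin,
    )


# ---------------------------------------------------------------------------
# Log parsing
# ---------------------------------------------------------------------------

def _parse_log(path, required: list[str], numeric: list[str]) -> tuple[pd.DataFrame, int]:
    df = pd.read_csv(path, comment="#", dtype={"sensor_id": str})
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    n_raw = len(df)
    ts = pd.to_datetime(df["iso_timestamp"], errors="coerce", format="ISO8601")
    df = df.assign(timestamp=ts)
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = df["timestamp"].notna() & df[numeric].notna().all(axis=1)
    n_bad = int((~keep).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s) of %d", path, n_bad, n_raw)
    df = df[keep].sort_values(["timestamp", "sensor_id"], kind="mergesort")
    return df.reset_index(drop=True), n_bad


def _fix_blocks(fix_times: pd.Series, gap_factor: float = 5.0) -> np.ndarray:
    """Split a fix sequence into contiguous passes on large time gaps."""
    dt = fix_times.diff().dt.total_seconds().to_numpy()
    med = np.nanmedian(dt[1:]) if len(dt) > 1 else 0.0
    if not np.isfinite(med) or med <= 0:
        return np.zeros(len(fix_times), dtype=int)
    new_block = np.zeros(len(fix_times), dtype=bool)
    new_block[1:] = dt[1:] > gap_factor * med
    return np.cumsum(new_block)


def _correct_and_assign(df: pd.DataFrame, layout, offsets: Mapping[str, float] | None,
                        apply_offset: bool, heading_half_window: int) -> pd.DataFrame:
    df["x"], df["y"] = project(df["lat"].to_numpy(), df["lon"].to_numpy(), layout.origin)
    if apply_offset:
        if offsets is None:
            raise ValueError("lateral offsets required when apply_offset=True")
        unknown = set(df["sensor_id"]) - set(offsets)
        if unknown:
            raise ValueError(f"no lateral offset configured for sensor id(s): {sorted(unknown)}")
        # all sensors on the boom share the vehicle fix at a given timestamp
        fixes = df.drop_duplicates("timestamp")[["timestamp", "x", "y"]].reset_index(drop=True)
        blocks = _fix_blocks(fixes["timestamp"])
        hw = min(heading_half_window, max(1, len(fixes) - 1))
        hx, hy = compute_headings(fixes["x"].to_numpy(), fixes["y"].to_numpy(),
                                  half_window=hw, block_ids=blocks)
        head = pd.DataFrame({"timestamp": fixes["timestamp"], "_hx": hx, "_hy": hy})
        df = df.merge(head, on="timestamp", how="left")
        off = df["sensor_id"].map(offsets).to_numpy(dtype=float)
        df["x"], df["y"] = apply_lateral_offset(
            df["x"].to_numpy(), df["y"].to_numpy(),
            df["_hx"].to_numpy(), df["_hy"].to_numpy(), off)
        df = df.drop(columns=["_hx", "_hy"])
    df["plot_id"] = assign_plots(df["x"].to_numpy(), df["y"].to_numpy(), layout)
    return df


def parse_sensor_log(path, layout, offsets: Mapping[str, float] | None = None,
                     apply_offset: bool = True, heading_half_window: int = 50) -> pd.DataFrame:
    """Parse a multispectral/ultrasonic log into plot-assigned records.

    Malformed rows (unparsable timestamps or non-numeric measurements) are
    counted, logged and skipped; the count is available as
    ``df.attrs["n_malformed"]``. Records are sorted by timestamp.
    """
    numeric = ["lat", "lon", "rho_nir", "rho_red_edge", "rho_red", "distance_m"]
    df, n_bad = _parse_log(path, SENSOR_LOG_COLUMNS, numeric)
    if len(df):
        df = _correct_and_assign(df, layout, offsets, apply_offset, heading_half_window)
    else:
        df["x"] = df["y"] = np.nan
        df["plot_id"] = None
    df.attrs["n_malformed"] = n_bad
    return df


def parse_env_log(path, layout, offsets: Mapping[str, float] | None = None,
                  apply_offset: bool = True, heading_half_window: int = 50) -> pd.DataFrame:
    """Parse an environmental (weather) log into plot-assigned records."""
    numeric = ["lat", "lon"] + ENV_VARIABLES
    df, n_bad = _parse_log(path, ENV_LOG_COLUMNS, numeric)
    if len(df):
        df = _correct_and_assign(df, layout, offsets, apply_offset, heading_half_window)
    else:
        df["x"] = df["y"] = np.nan
        df["plot_id"] = None
    df.attrs["n_malformed"] = n_bad
    return df


def parse_logs(sensor_csv, env_csv, layout, spectral_offsets=None, env_offsets=None,
               apply_offset: bool = True, heading_half_window: int = 50):
    """Parse both raw log files of one campaign date."""
    sensor = parse_sensor_log(sensor_csv, layout, spectral_offsets,
                              apply_offset, heading_half_window)
    env = parse_env_log(env_csv, layout, env_offsets,
                        apply_offset, heading_half_window)
    return sensor, env
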