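"""Envirotype feature construction.

Pairs every plot with the environmental conditions it experienced: weather
records are averaged per plot and campaign date, expanded into four
temporal aggregation schemes (same date, previous measured date, cumulative
mean to date, cumulative mean to the previous date), and sparse soil-core
chemistry is interpolated to plot centroids by Inverse Distance Weighting.
"Previous date" always means the previous *measurement* date of the
campaign, not the previous calendar day — the platform only records weather
while scanning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geoplot import ENV_VARIABLES

#: scheme codes -> meaning
SCHEMES = {
    "a": "same date",
    "b": "previous measured date",
    "c": "cumulative mean to date",
    "d": "cumulative mean to previous date",
}


def env_per_plot_date(env_records: pd.DataFrame, date: str,
                      variables: list[str] | None = None,
                      layout=None) -> pd.DataFrame:
    """Arithmetic mean of each environmental variable per plot for one date.

    Input records must carry plot assignments; unassigned records are
    dropped. With *layout*, plots without any record appear with NaN means
    and ``missing=True``.
    """
    variables = variables or ENV_VARIABLES
    df = env_records[env_records["plot_id"].notna()]
    means = df.groupby("plot_id")[variables].mean()
    means.insert(0, "date", date)
    means["n_records"] = df.groupby("plot_id").size()
    if layout is not None:
        means = means.reindex(layout.plot_ids)
        means["date"] = date
        means["missing"] = means["n_records"].isna()
    return means.reset_index().rename(columns={"index": "plot_id"})


def scheme_features(env_plot_date: pd.DataFrame, dates: list[str],
                    schemes: str = "abcd",
                    variables: list[str] | None = None) -> pd.DataFrame:
    """Weather features under the four temporal aggregation schemes.

    ``env_plot_date`` is the stacked output of :func:`env_per_plot_date`
    over all campaign dates. For each plot/variable and each date d (in the
    declared campaign order): scheme a = value at d; b = value at the
    previous measured date; c = mean of values at all measured dates <= d;
    d = mean at all measured dates < d. Schemes b and d are undefined (NaN)
    at the first date.
    """
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme: {s!r}")
    if list(dates) != sorted(set(dates), key=list(dates).index) or len(set(dates)) != len(dates):
        raise ValueError("dates must be unique")
    variables = variables or [v for v in ENV_VARIABLES if v in env_plot_date.columns]
    order = {d: i for i, d in enumerate(dates)}
    df = env_plot_date[env_plot_date["date"].isin(order)].copy()
    df["_ord"] = df["date"].map(order)
    df = df.sort_values(["plot_id", "_ord"])
    frames = []
    for var in variables:
        g = df.groupby("plot_id", sort=True)[var]
        vals = {"a": df[var]}
        if "b" in schemes:
            vals["b"] = g.shift(1)
        if "c" in schemes:
            vals["c"] = g.expanding().mean().reset_index(level=0, drop=True)
        if "d" in schemes:
            vals["d"] = g.apply(lambda s: s.expanding().mean().shift(1)).reset_index(level=0, drop=True)
        for s in schemes:
            frames.append(pd.DataFrame({
                "plot_id": df["plot_id"].to_numpy(),
                "date": df["date"].to_numpy(),
                "variable": var, "scheme": s,
                "value": vals[s].to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)


def idw(sample_points, sample_values, query_points, power: float = 2.0):
    """Inverse Distance Weighted interpolation.

    value(q) = sum(w_i v_i) / sum(w_i) with w_i = d(q, p_i)^(-power).
    A query closer than 1e-9 m to a sample returns that sample's value
    exactly (the weights' singular limit). Accepts a single query point or
    an (m, 2) array.
    """
    pts = np.asarray(sample_points, dtype=float).reshape(-1, 2)
    vals = np.asarray(sample_values, dtype=float)
    if pts.shape[0] == 0:
        raise ValueError("need at least one sample point")
    if pts.shape[0] != vals.shape[0]:
        raise ValueError("sample_points and sample_values length mismatch")
    if power <= 0:
        raise ValueError("power must be > 0")
    q = np.asarray(query_points, dtype=float)
    scalar = q.ndim == 1
    q = q.reshape(-1, 2)
    d = cdist(q, pts)
    out = np.empty(len(q))
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[has_exact] = 0.0
    out[~has_exact] = (w[~has_exact] * vals).sum(axis=1) / w[~has_exact].sum(axis=1)
    if has_exact.any():
        out[has_exact] = vals[exact.argmax(axis=1)[has_exact]]
    return float(out[0]) if scalar else out


def soil_features(soil_samples: pd.DataFrame, layout,
                  power: float = 2.0) -> pd.DataFrame:
    """IDW-interpolated soil chemistry at every plot centroid.

    ``soil_samples`` is the long core table (x, y, depth, property, value).
    Features are named ``soil:<depth>:<property>``; all cores of the
    matching depth contribute (no neighbourhood cutoff — with six locations
    truncation would be meaningless).
    """
    frame = layout.frame()
    queries = frame[["cx", "cy"]].to_numpy()
    out = pd.DataFrame(index=frame.index)
    for (depth, prop), grp in soil_samples.groupby(["depth", "property"], sort=True):
        pts = grp[["x", "y"]].to_numpy()
        vals = grp["value"].to_numpy()
        out[f"soil:{depth}:{prop}"] = idw(pts, vals, queries, power=power)
    return out.reset_index()
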