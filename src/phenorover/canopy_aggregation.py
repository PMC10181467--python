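"""Per-reading traits and Otsu-principle plot aggregation.

A proximal sensor scanning across crop rows sees both canopy and the soil
between rows, so the per-plot distribution of a trait (NDVI, NDRE, CI or
height) is bimodal: a soil mode and a plant mode, modelled as the sum of two
normal components. To summarise the *plants* rather than the plot surface,
each plot x date x trait set of readings is split at the threshold that
maximizes the between-class variance of its histogram (Otsu's principle on
a 1-D histogram), and the plot is summarised by the maximum reading and the
mean of readings strictly above the threshold. A simple arithmetic mean is
kept alongside as the handheld-protocol benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAITS = ["ndvi", "ndre", "ci", "height"]


# ---------------------------------------------------------------------------
# Per-reading traits
# ---------------------------------------------------------------------------

def compute_vis(rho_nir, rho_red_edge, rho_red):
    """Vegetation indices from the three band reflectances.

    NDVI = (rho_NIR - rho_Red) / (rho_NIR + rho_Red),
    NDRE = (rho_NIR - rho_RedEdge) / (rho_NIR + rho_RedEdge),
    CI   = rho_NIR / rho_RedEdge - 1.

    Works on scalars or arrays; raises on non-positive reflectances.
    """
    nir = np.asarray(rho_nir, dtype=float)
    red_edge = np.asarray(rho_red_edge, dtype=float)
    red = np.asarray(rho_red, dtype=float)
    if np.any(nir <= 0) or np.any(red_edge <= 0) or np.any(red <= 0):
        raise ValueError("reflectances must be > 0")
    ndvi = (nir - red) / (nir + red)
    ndre = (nir - red_edge) / (nir + red_edge)
    ci = nir / red_edge - 1.0
    return ndvi, ndre, ci


def distance_to_height(distance, mount_height: float):
    """Plant height from the ultrasonic distance reading.

    height = max(0, mount_height - distance); readings farther away than the
    (bare ground) mount height are clipped to zero height and flagged.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if mount_height <= 0:
        raise ValueError("mount_height must be > 0")
    height = np.maximum(0.0, mount_height - d)
    flagged = d > mount_height
    return height, flagged


def records_to_traits(records: pd.DataFrame, mount_height: float) -> pd.DataFrame:
    """Long (plot_id, trait, value) table from parsed sensor records."""
    ndvi, ndre, ci = compute_vis(records["rho_nir"], records["rho_red_edge"],
                                 records["rho_red"])
    height, _ = distance_to_height(records["distance_m"], mount_height)
    wide = pd.DataFrame({
        "plot_id": records["plot_id"].to_numpy(),
        "ndvi": ndvi, "ndre": ndre, "ci": ci, "height": height,
    })
    return wide.melt(id_vars="plot_id", var_name="trait", value_name="value")


# ---------------------------------------------------------------------------
# Otsu-principle thresholding
# ---------------------------------------------------------------------------

@dataclass
class OtsuResult:
    threshold: float
    curve: np.ndarray       # between-class variance at each interior bin edge
    bin_edges: np.ndarray
    bimodality_ok: bool
    n: int


def otsu_threshold(values, n_bins: int = 64, min_n: int = 20,
                   min_effectiveness: float = 0.8) -> OtsuResult:
    """Histogram threshold maximizing the between-class variance.

    A uniform ``n_bins`` histogram is built over [min, max] and every
    interior bin edge is scored by omega0*omega1*(mu0-mu1)^2 (class weights
    and means from the histogram, using bin centres); the argmax edge is the
    threshold. With well-separated modes the score is exactly flat across
    the empty gap between them, so ties resolve to the midmost maximizing
    edge — the threshold sits centred between the modes rather than hugging
    one of them. ``bimodality_ok`` is
    False when the split is untrustworthy: the winning edge lies within the
    first or last 5% of bins, the class means are closer than one pooled
    within-class standard deviation, the between-class variance explains
    less than ``min_effectiveness`` of the total variance (Otsu's
    effectiveness metric — an optimal split of a unimodal Gaussian only
    reaches ~0.64, a genuinely bimodal soil/plant mixture >0.85), either
    class is (nearly) empty, or the sample is degenerate (all values equal).
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} readings, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        edges = np.linspace(vmin - 0.5, vmax + 0.5, n_bins + 1)
        return OtsuResult(threshold=vmin, curve=np.zeros(n_bins - 1),
                          bin_edges=edges, bimodality_ok=False, n=v.size)

    counts, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    w = counts / total
    cum_w = np.cumsum(w)[:-1]                      # weight below edge k (k=1..n-1)
    cum_m = np.cumsum(w * centers)[:-1]            # partial first moment
    grand = float(np.sum(w * centers))
    w0 = cum_w
    w1 = 1.0 - cum_w
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, cum_m / w0, 0.0)
        mu1 = np.where(w1 > 0, (grand - cum_m) / w1, 0.0)
    curve = w0 * w1 * (mu0 - mu1) ** 2
    ties = np.flatnonzero(curve == curve.max())
    k = int(ties[(len(ties) - 1) // 2]) + 1        # midmost maximizing edge
    threshold = float(edges[k])

    margin = max(1, int(np.ceil(0.05 * n_bins)))
    ok = margin <= k <= n_bins - margin
    below = v[v < threshold]
    above = v[v >= threshold]
    if below.size < 2 or above.size < 2:
        ok = False
    else:
        var_within = (below.size * below.var() + above.size * above.var()) / v.size
        pooled_sd = float(np.sqrt(var_within))
        if abs(above.mean() - below.mean()) < pooled_sd:
            ok = False
        var_total = float(v.var())
        if var_total > 0 and 1.0 - var_within / var_total < min_effectiveness:
            ok = False
    return OtsuResult(threshold=threshold, curve=curve, bin_edges=edges,
                      bimodality_ok=bool(ok), n=int(v.size))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class PlotDateAggregate:
    n_readings: int
    threshold: float
    max_value: float
    mean_above_threshold: float
    simple_mean: float
    bimodality_ok: bool


def mean_above(values, threshold: float) -> float:
    """Mean of values strictly above the threshold (NaN when none)."""
    v = np.asarray(values, dtype=float)
    sel = v > threshold
    return float(v[sel].mean()) if sel.any() else float("nan")


def aggregate_plot_date(values, mode: str = "thresholded", n_bins: int = 64,
                        min_n: int = 20) -> PlotDateAggregate:
    """Reduce one plot x date x trait reading set to its summary aggregate.

    ``thresholded`` mode applies :func:`otsu_threshold` and reports the
    maximum plus the mean of readings strictly above the threshold; when the
    histogram is not credibly bimodal (or too small to threshold) all
    readings are used and the aggregate is flagged. ``simple_mean`` mode is
    the handheld benchmark: plain arithmetic mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty reading set: plot/date should be marked missing")
    simple = float(v.mean())
    if mode == "simple_mean":
        return PlotDateAggregate(n_readings=v.size, threshold=float("nan"),
                                 max_value=float(v.max()),
                                 mean_above_threshold=simple,
                                 simple_mean=simple, bimodality_ok=False)
    if mode != "thresholded":
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    if v.size < min_n:
        return PlotDateAggregate(n_readings=v.size, threshold=float("nan"),
                                 max_value=float(v.max()),
                                 mean_above_threshold=simple,
                                 simple_mean=simple, bimodality_ok=False)
    res = otsu_threshold(v, n_bins=n_bins, min_n=min_n)
    if res.bimodality_ok:
        m_above = mean_above(v, res.threshold)
    else:
        m_above = simple
    return PlotDateAggregate(n_readings=v.size, threshold=res.threshold,
                             max_value=float(v.max()),
                             mean_above_threshold=m_above,
                             simple_mean=simple,
                             bimodality_ok=res.bimodality_ok)


def aggregate_table(long_df: pd.DataFrame, date: str, layout=None,
                    mode: str = "thresholded", n_bins: int = 64,
                    min_n: int = 20, shared_mask_trait: str | None = None) -> pd.DataFrame:
    """Aggregate a long (plot_id, trait, value) table for one date.

    Readings without a plot assignment are dropped. When *layout* is given,
    plots with no readings appear as rows with NaN aggregates (missing
    plots are reported, not silently absent). ``shared_mask_trait``
    optionally derives the above-threshold mask from a single trait (e.g.
    NDVI) and applies it to all traits instead of thresholding each trait
    independently.
    """
    df = long_df[long_df["plot_id"].notna()]
    rows = []
    if shared_mask_trait is not None:
        masks = {}
        for plot_id, grp in df[df["trait"] == shared_mask_trait].groupby("plot_id"):
            v = grp["value"].to_numpy()
            if v.size >= min_n:
                res = otsu_threshold(v, n_bins=n_bins, min_n=min_n)
                if res.bimodality_ok:
                    masks[plot_id] = (grp.index, grp["value"].to_numpy() > res.threshold)
    for (plot_id, trait), grp in df.groupby(["plot_id", "trait"], sort=True):
        v = grp["value"].to_numpy()
        if shared_mask_trait is not None:
            if plot_id in masks:
                _, mask = masks[plot_id]
                sel = v[mask] if len(mask) == len(v) else v
                agg = PlotDateAggregate(
                    n_readings=v.size, threshold=float("nan"),
                    max_value=float(v.max()),
                    mean_above_threshold=float(sel.mean()) if sel.size else float("nan"),
                    simple_mean=float(v.mean()), bimodality_ok=True)
            else:
                agg = aggregate_plot_date(v, mode="simple_mean")
        else:
            agg = aggregate_plot_date(v, mode=mode, n_bins=n_bins, min_n=min_n)
        rows.append({"plot_id": plot_id, "date": date, "trait": trait,
                     "n": agg.n_readings, "threshold": agg.threshold,
                     "max": agg.max_value, "mean_above": agg.mean_above_threshold,
                     "simple_mean": agg.simple_mean,
                     "bimodality_ok": agg.bimodality_ok})
    out = pd.DataFrame(rows)
    if layout is not None:
        traits = sorted(df["trait"].unique()) if len(df) else TRAITS
        full = pd.MultiIndex.from_product([layout.plot_ids, traits],
                                          names=["plot_id", "trait"]).to_frame(index=False)
        out = full.merge(out, on=["plot_id", "trait"], how="left")
        out["date"] = date
        out["missing"] = out["n"].isna()
    return out


def trait_histogram(values, n_bins: int = 64):
    """Binned counts for population/plot histograms; counts sum to n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    if v.min() == v.max():
        edges = np.linspace(v.min() - 0.5, v.max() + 0.5, n_bins + 1)
        counts, edges = np.histogram(v, bins=edges)
    else:
        counts, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    return counts, edges
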