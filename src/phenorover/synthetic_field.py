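"""Synthetic field trial generator.

Emulates the data a boom-equipped scout vehicle collects while driving the
alleys of a bean variety trial: a grid field layout with management factors,
a serpentine GNSS trajectory, multispectral + ultrasonic readings whose
per-plot histograms are two-component normal mixtures (a soil class and a
plant class), plot-smooth weather and soil fields, and a sparse linear
ground-truth model tying traits and yield to environmental, management and
genetic covariates. Because every distributional parameter is recorded in a
:class:`TruthParams` object, downstream stages can be tested by parameter
recovery rather than by eyeballing.

The generator is phenomenological: class distributions are declared, not
derived from radiative transfer or crop growth, and no camera imagery is
simulated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import geoplot
from .geoplot import assign_plots, unproject

logger = logging.getLogger(__name__)

#: Traits drawn at reading level. CI is induced by NDRE through the exact
#: algebraic identity CI = 2*NDRE/(1-NDRE), so it is not drawn separately.
GEN_TRAITS = ["ndvi", "ndre", "height"]

SOIL_PROPERTIES = ["organic_matter", "N", "P", "K", "Ca", "Mg", "Na"]
SOIL_DEPTHS = ["shallow", "deep"]

DEFAULT_DATES = [
    "2020-08-17", "2020-08-20", "2020-08-24",
    "2020-08-27", "2020-08-31", "2020-09-03",
]

DEFAULT_ORIGIN = (45.4272, -73.9392)

DEFAULT_VARIETIES = [
    "Rampart", "Blackbeard", "Etna", "Apex", "T9905", "Windbreaker",
    "Zorro", "Merlot", "Nautica", "Redhawk", "RedRover",
]

ROW_SPACING_LEVELS_MM = (559, 762)       # 22 in / 30 in
DENSITY_LEVELS_PER_HA = (24700, 37100)   # 10k / 15k plants per acre


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PlotSpec:
    plot_id: str
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1) planar metres
    variety: str
    row_spacing_mm: int
    density_per_ha: int
    n_rows: int = 4

    @property
    def centroid(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return (0.5 * (x0 + x1), 0.5 * (y0 + y1))

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    @property
    def corners(self) -> list[tuple[float, float]]:
        x0, y0, x1, y1 = self.rect
        return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


@dataclass
class FieldLayout:
    plots: list[PlotSpec]
    grid_rows: int
    grid_cols: int
    alley_width: float
    origin: tuple[float, float]

    def plot(self, plot_id: str) -> PlotSpec:
        return self._index[plot_id]

    @property
    def _index(self) -> dict[str, PlotSpec]:
        return {p.plot_id: p for p in self.plots}

    @property
    def plot_ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]

    def bounds(self) -> tuple[float, float, float, float]:
        rects = np.array([p.rect for p in self.plots])
        return (rects[:, 0].min(), rects[:, 1].min(),
                rects[:, 2].max(), rects[:, 3].max())

    def frame(self) -> pd.DataFrame:
        """Plot attributes as a DataFrame indexed by plot_id."""
        rows = []
        for p in self.plots:
            cx, cy = p.centroid
            rows.append({"plot_id": p.plot_id, "variety": p.variety,
                         "row_spacing_mm": p.row_spacing_mm,
                         "density_per_ha": p.density_per_ha,
                         "cx": cx, "cy": cy})
        return pd.DataFrame(rows).set_index("plot_id")


@dataclass
class TrajectoryConfig:
    speed: float = 0.8                  # m/s, nominal scan speed
    sampling_interval: float = 0.05     # s between fixes (hardware-rate 0.006)
    spectral_offsets: dict[str, float] = field(default_factory=lambda: {
        "ms1": -2.6, "ms2": -1.9, "ms3": -1.2,
        "ms4": 1.2, "ms5": 1.9, "ms6": 2.6,
    })
    env_offsets: dict[str, float] = field(default_factory=lambda: {
        "env1": -1.5, "env2": 1.5,
    })
    gps_noise_sd: float = 0.3           # m, isotropic uncorrected GNSS
    mount_height: float = 1.5           # m, ultrasonic sensor above ground
    vehicle_footprint: float = 1.5      # m, for the narrow-alley warning
    turn_time: float = 12.0             # s between passes (not logged)
    margin: float = 2.0                 # m driven past the field ends

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")


@dataclass
class TruthParams:
    """Complete distributional ground truth of a synthetic campaign."""

    seed: int
    dates: list[str]
    mix_fraction: float                       # P(reading over a plot is soil)
    soil_class: dict                          # trait -> {mean, sd}
    plant_base: dict                          # trait -> per-date mean list
    variety_effect: dict                      # trait -> {variety: offset}
    reading_sd: dict                          # trait -> plant-class reading sd
    plot_noise_sd: dict                       # response -> plot-level sd
    trait_model: dict                         # response -> {feature: coef}
    weather_fields: dict                      # var -> date -> field spec
    soil_surfaces: dict                       # depth -> prop -> field spec
    soil_sample_noise_sd: float = 0.0
    rho_nir: dict = field(default_factory=lambda: {"plant": 0.45, "soil": 0.30})

    def validate(self) -> None:
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must be in [0, 1]")
        for trait, per_date in self.plant_base.items():
            if np.any(np.diff(per_date) > 1e-12):
                raise ValueError(f"plant_base[{trait}] must be non-increasing over dates")
        for trait, spec in self.soil_class.items():
            if spec["sd"] <= 0:
                raise ValueError(f"soil_class[{trait}] sd must be > 0")


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _balanced_labels(levels, n, rng):
    reps = -(-n // len(levels))  # ceil
    labels = np.tile(np.asarray(levels, dtype=object), reps)[:n]
    rng.shuffle(labels)
    return labels


def gen_layout(grid_rows: int, grid_cols: int, plot_area: float,
               varieties: list[str], factor_assignment: str = "balanced",
               seed: int = 0, plot_width: float = 3.0, alley_width: float = 2.0,
               plot_gap: float = 1.0, origin: tuple[float, float] = DEFAULT_ORIGIN,
               row_spacing_levels=ROW_SPACING_LEVELS_MM,
               density_levels=DENSITY_LEVELS_PER_HA, n_rows: int = 4) -> FieldLayout:
    """Generate a grid field layout with seeded stratified randomization.

    Plot columns are separated by drivable alleys of ``alley_width`` metres;
    rows are separated by ``plot_gap``. Varieties and the two management
    factors are assigned by balanced randomization: each level appears
    equally often (up to remainder) in a seeded random arrangement.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if plot_area <= 0:
        raise ValueError("plot_area must be > 0")
    if not varieties:
        raise ValueError("variety list must not be empty")
    if factor_assignment != "balanced":
        raise ValueError(f"unknown factor_assignment rule: {factor_assignment!r}")
    rng = np.random.default_rng(seed)
    n = grid_rows * grid_cols
    variety_lab = _balanced_labels(varieties, n, rng)
    spacing_lab = _balanced_labels(row_spacing_levels, n, rng)
    density_lab = _balanced_labels(density_levels, n, rng)
    plot_length = plot_area / plot_width
    plots = []
    k = 0
    for r in range(grid_rows):
        y0 = r * (plot_length + plot_gap)
        for c in range(grid_cols):
            x0 = alley_width + c * (plot_width + alley_width)
            plots.append(PlotSpec(
                plot_id=f"r{r + 1:02d}c{c + 1:02d}",
                rect=(x0, y0, x0 + plot_width, y0 + plot_length),
                variety=str(variety_lab[k]),
                row_spacing_mm=int(spacing_lab[k]),
                density_per_ha=int(density_lab[k]),
                n_rows=n_rows,
            ))
            k += 1
    return FieldLayout(plots=plots, grid_rows=grid_rows, grid_cols=grid_cols,
                       alley_width=alley_width, origin=origin)


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def alley_centerlines(layout: FieldLayout) -> list[float]:
    """x-coordinates of the drivable lanes between (and beside) plot columns."""
    bands = sorted({(p.rect[0], p.rect[2]) for p in layout.plots})
    lanes = [bands[0][0] - layout.alley_width / 2.0]
    for (_, x1a), (x0b, _) in zip(bands[:-1], bands[1:]):
        lanes.append(0.5 * (x1a + x0b))
    lanes.append(bands[-1][1] + layout.alley_width / 2.0)
    return lanes


def gen_trajectory(layout: FieldLayout, config: TrajectoryConfig) -> pd.DataFrame:
    """Serpentine noiseless path through every alley of the field.

    Returns a DataFrame with columns ``t`` (s), ``x``, ``y`` (planar m),
    ``heading_x``, ``heading_y`` and ``pass_id``. Consecutive fixes within a
    pass are ``speed * sampling_interval`` metres apart; passes are
    separated by an unlogged turning interval. A ``narrow_alley_warning``
    flag is set in ``df.attrs`` when the alleys are no wider than the
    vehicle footprint.
    """
    lanes = alley_centerlines(layout)
    x_min, y_min, x_max, y_max = layout.bounds()
    y_lo, y_hi = y_min - config.margin, y_max + config.margin
    step = config.speed * config.sampling_interval
    # first fix sits half an interval into the pass, so fixes do not land
    # exactly on plot-boundary coordinates
    n_steps = int(np.floor((y_hi - y_lo) / step)) - 1
    frames = []
    t0 = 0.0
    for i, lane_x in enumerate(lanes):
        ys = y_lo + (np.arange(n_steps + 1) + 0.5) * step
        hy = 1.0
        if i % 2 == 1:  # alternate direction
            ys = ys[::-1]
            hy = -1.0
        t = t0 + np.arange(n_steps + 1) * config.sampling_interval
        frames.append(pd.DataFrame({
            "t": t, "x": np.full(n_steps + 1, lane_x), "y": ys,
            "heading_x": 0.0, "heading_y": hy, "pass_id": i,
        }))
        t0 = t[-1] + config.turn_time
    traj = pd.concat(frames, ignore_index=True)
    warn = layout.alley_width <= config.vehicle_footprint
    if warn:
        logger.warning("alley width %.2f m <= vehicle footprint %.2f m",
                       layout.alley_width, config.vehicle_footprint)
    traj.attrs["narrow_alley_warning"] = bool(warn)
    return traj


# ---------------------------------------------------------------------------
# Smooth scalar fields (weather trends and soil surfaces)
# ---------------------------------------------------------------------------

def _random_field_spec(rng, mean: float, gradient_scale: float,
                       harmonic_amp: float, extent: float,
                       n_harmonics: int = 6,
                       wavelength_range: tuple[float, float] = (0.12, 0.6)) -> dict:
    """Linear trend plus random sinusoids down to ~15 m wavelength.

    The harmonics give each variable its own within-field heterogeneity:
    two purely linear fields over the same plane are exactly collinear once
    an intercept is in the model, and with only long wavelengths any two
    smooth fields share so few spatial degrees of freedom that they
    correlate strongly by chance. Wavelengths stay well above the plot
    scale, so fields remain smooth within a plot.
    """
    theta = rng.uniform(0, 2 * np.pi)
    g = gradient_scale / max(extent, 1.0)
    spec = {"mean": float(mean),
            "gx": float(g * np.cos(theta)), "gy": float(g * np.sin(theta))}
    harmonics = []
    for _ in range(n_harmonics):
        wavelength = rng.uniform(*wavelength_range) * extent
        phi = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / wavelength
        harmonics.append({
            "amp": float(harmonic_amp * rng.uniform(0.3, 0.8)),
            "kx": float(k * np.cos(phi)), "ky": float(k * np.sin(phi)),
            "phase": float(rng.uniform(0, 2 * np.pi)),
        })
    spec["harmonics"] = harmonics
    return spec


def eval_field(spec: dict, x, y):
    """Evaluate a smooth field spec at planar coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v = spec["mean"] + spec["gx"] * x + spec["gy"] * y
    for h in spec.get("harmonics", []):
        v = v + h["amp"] * np.sin(h["kx"] * x + h["ky"] * y + h["phase"])
    return v


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

_WEATHER_DEFAULTS = {
    # var: (seasonal level, between-date jitter sd, gradient span, harmonic amp, record noise sd)
    "temp_c": (22.0, 2.5, 1.2, 0.8, 0.3),
    "rh_pct": (55.0, 8.0, 4.0, 3.0, 1.5),
    "pressure_hpa": (1012.0, 4.0, 0.2, 0.1, 0.3),
    "par_in": (1400.0, 150.0, 80.0, 60.0, 40.0),
    "par_refl": (90.0, 15.0, 8.0, 6.0, 8.0),
}

_SOIL_LEVELS = {
    "organic_matter": (4.0, 0.6), "N": (20.0, 3.0), "P": (30.0, 5.0),
    "K": (150.0, 20.0), "Ca": (1200.0, 150.0), "Mg": (180.0, 25.0),
    "Na": (25.0, 5.0),
}

_DEFAULT_TRAIT_MODEL = {
    "ndvi": {"soil:shallow:organic_matter": 0.030, "soil:deep:Na": -0.015,
             "wx:temp_c": -0.020, "wx:par_in": 0.015, "wx:par_refl": -0.010},
    "ndre": {"soil:shallow:organic_matter": 0.022, "soil:deep:Na": -0.012,
             "wx:temp_c": -0.015, "wx:par_in": 0.012, "wx:par_refl": -0.008},
    "height": {"soil:shallow:organic_matter": 0.045, "soil:deep:Ca": 0.020,
               "wx:temp_c": -0.030, "wx:par_in": 0.020, "row_spacing_mm": -0.030},
    "yield": {"intercept": 3.0, "soil:shallow:organic_matter": 0.40,
              "soil:shallow:Ca": 0.20, "wx:temp_c": -0.25, "wx:par_in": 0.20,
              "row_spacing_mm": -0.30},
}

_VARIETY_EFFECT_SD = {"ndvi": 0.02, "ndre": 0.015, "height": 0.04, "yield": 0.30}

_PLANT_BASE_RANGE = {"ndvi": (0.82, 0.62), "ndre": (0.44, 0.30), "height": (0.55, 0.44)}


def default_truth(layout: FieldLayout, dates: list[str] | None = None,
                  seed: int = 0, mix_fraction: float = 0.3) -> TruthParams:
    """Default ground-truth parameter set for a campaign over *layout*.

    Plant-class trait means decline over the campaign (a senescing bean
    crop scanned late in the season), soil-class means sit near bare-soil
    values, and each trait/yield response carries a sparse linear dependence
    on soil, weather and management covariates plus a variety effect.
    """
    dates = list(dates) if dates is not None else list(DEFAULT_DATES)
    rng = np.random.default_rng([seed, 0xFEED])
    x_min, y_min, x_max, y_max = layout.bounds()
    extent = float(np.hypot(x_max - x_min, y_max - y_min))
    varieties = sorted({p.variety for p in layout.plots})

    plant_base = {
        t: list(np.linspace(hi, lo, len(dates)))
        for t, (hi, lo) in _PLANT_BASE_RANGE.items()
    }
    variety_effect = {
        resp: {v: float(rng.normal(0.0, sd)) for v in varieties}
        for resp, sd in _VARIETY_EFFECT_SD.items()
    }
    weather_fields = {}
    for var, (level, jitter, grad, amp, noise_sd) in _WEATHER_DEFAULTS.items():
        per_date = {}
        for d in dates:
            mean = level + rng.normal(0.0, jitter)
            spec = _random_field_spec(rng, mean, grad, amp, extent)
            spec["noise_sd"] = noise_sd
            per_date[d] = spec
        weather_fields[var] = per_date
    soil_surfaces = {}
    for depth in SOIL_DEPTHS:
        soil_surfaces[depth] = {}
        for prop, (level, scale) in _SOIL_LEVELS.items():
            mean = level * (0.85 if depth == "deep" and prop == "organic_matter" else 1.0)
            soil_surfaces[depth][prop] = _random_field_spec(
                rng, mean + rng.normal(0.0, 0.1 * scale), 2.0 * scale, scale, extent)

    return TruthParams(
        seed=seed,
        dates=dates,
        mix_fraction=mix_fraction,
        soil_class={"ndvi": {"mean": 0.15, "sd": 0.04},
                    "ndre": {"mean": 0.08, "sd": 0.03},
                    "height": {"mean": 0.0, "sd": 0.015}},
        plant_base=plant_base,
        variety_effect=variety_effect,
        reading_sd={"ndvi": 0.05, "ndre": 0.04, "height": 0.05},
        plot_noise_sd={"ndvi": 0.02, "ndre": 0.015, "height": 0.03, "yield": 0.25},
        trait_model={k: dict(v) for k, v in _DEFAULT_TRAIT_MODEL.items()},
        weather_fields=weather_fields,
        soil_surfaces=soil_surfaces,
    )


def true_covariates(truth: TruthParams, layout: FieldLayout,
                    date_index: int) -> pd.DataFrame:
    """Noise-free covariates at plot centroids for one campaign date.

    Management factors carry their raw values; soil and weather columns are
    the true surface/trend values (``soil:<depth>:<prop>`` and ``wx:<var>``,
    the latter at the given date).
    """
    date = truth.dates[date_index]
    frame = layout.frame()
    cx, cy = frame["cx"].to_numpy(), frame["cy"].to_numpy()
    out = pd.DataFrame(index=frame.index)
    out["row_spacing_mm"] = frame["row_spacing_mm"].astype(float)
    out["density_per_ha"] = frame["density_per_ha"].astype(float)
    for depth, props in truth.soil_surfaces.items():
        for prop, spec in props.items():
            out[f"soil:{depth}:{prop}"] = eval_field(spec, cx, cy)
    for var, per_date in truth.weather_fields.items():
        out[f"wx:{var}"] = eval_field(per_date[date], cx, cy)
    return out


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (df - df.mean()) / sd


def plot_plant_means(truth: TruthParams, layout: FieldLayout,
                     date_index: int) -> pd.DataFrame:
    """True plant-class mean of every trait for each plot at one date.

    mean = date base + variety effect + sparse linear term in the z-scored
    true covariates + a plot-level residual (seeded, so repeated calls
    agree). This is the quantity the thresholded aggregation stage is meant
    to recover.
    """
    if not 0 <= date_index < len(truth.dates):
        raise IndexError(f"date_index {date_index} out of range")
    z = _zscore(true_covariates(truth, layout, date_index))
    frame = layout.frame()
    rng = np.random.default_rng([truth.seed, 3, date_index])
    out = pd.DataFrame(index=frame.index)
    for trait in GEN_TRAITS:
        mu = np.full(len(frame), truth.plant_base[trait][date_index])
        mu += frame["variety"].map(truth.variety_effect[trait]).to_numpy()
        for feat, coef in truth.trait_model[trait].items():
            if feat == "intercept":
                mu += coef
            else:
                mu += coef * z[feat].to_numpy()
        mu += rng.normal(0.0, truth.plot_noise_sd[trait], len(frame))
        out[trait] = mu
    return out


# ---------------------------------------------------------------------------
# Sensor and environmental logs
# ---------------------------------------------------------------------------

def _sensor_positions(trajectory: pd.DataFrame, offsets: dict[str, float]):
    """True position of each boom sensor at each fix (long arrays)."""
    n = len(trajectory)
    ids = sorted(offsets)
    m = len(ids)
    fx = trajectory["x"].to_numpy()
    fy = trajectory["y"].to_numpy()
    hx = trajectory["heading_x"].to_numpy()
    hy = trajectory["heading_y"].to_numpy()
    off = np.array([offsets[i] for i in ids])
    sx = (fx[:, None] - off[None, :] * hy[:, None]).ravel()
    sy = (fy[:, None] + off[None, :] * hx[:, None]).ravel()
    sensor_id = np.tile(np.array(ids, dtype=object), n)
    fix_index = np.repeat(np.arange(n), m)
    return sx, sy, sensor_id, fix_index


def _timestamps(date: str, t_seconds: np.ndarray, start: str = "13:00:00") -> pd.Series:
    base = pd.Timestamp(f"{date} {start}")
    ts = base + pd.to_timedelta(np.round(t_seconds, 3), unit="s")
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3]


def _noisy_latlon(trajectory, fix_index, gps_noise_sd, origin, rng):
    n = len(trajectory)
    noise = rng.normal(0.0, gps_noise_sd, (n, 2)) if gps_noise_sd > 0 else np.zeros((n, 2))
    gx = trajectory["x"].to_numpy() + noise[:, 0]
    gy = trajectory["y"].to_numpy() + noise[:, 1]
    lat, lon = unproject(gx, gy, origin)
    return lat[fix_index], lon[fix_index]


def gen_sensor_log(layout: FieldLayout, truth: TruthParams,
                   trajectory: pd.DataFrame, date_index: int,
                   config: TrajectoryConfig | None = None) -> pd.DataFrame:
    """Multispectral + ultrasonic records for one campaign date.

    Each record's class (soil vs plant) is drawn from the mix fraction of
    the plot under the sensor footprint — pure soil over alleys. NDVI/NDRE
    are drawn per class and the three band reflectances solved from them
    with a fixed per-class NIR reflectance, so the vegetation-index
    operations downstream are genuinely exercised. Plant height is drawn per
    class and converted to the ultrasonic distance reading through the mount
    height. Columns ``true_plot_id`` and ``true_class`` carry generator
    truth for recovery tests; the CSV writer drops them.
    """
    if not 0 <= date_index < len(truth.dates):
        raise IndexError(f"date_index {date_index} out of range "
                         f"(campaign has {len(truth.dates)} dates)")
    config = config or TrajectoryConfig()
    rng = np.random.default_rng([truth.seed, 10, date_index])
    sx, sy, sensor_id, fix_index = _sensor_positions(trajectory, config.spectral_offsets)
    plots = assign_plots(sx, sy, layout, validate=False)
    over_plot = np.array([p is not None for p in plots])
    is_soil = ~over_plot | (rng.uniform(size=len(sx)) < truth.mix_fraction)

    means = plot_plant_means(truth, layout, date_index)
    plot_pos = pd.Index(means.index)
    loc = np.zeros(len(sx), dtype=int)
    loc[over_plot] = plot_pos.get_indexer(pd.Index(plots[over_plot].astype(str)))

    values = {}
    for trait in GEN_TRAITS:
        mu_plant = means[trait].to_numpy()[loc]
        mu = np.where(is_soil, truth.soil_class[trait]["mean"], mu_plant)
        sd = np.where(is_soil, truth.soil_class[trait]["sd"], truth.reading_sd[trait])
        values[trait] = rng.normal(mu, sd)
    ndvi = np.clip(values["ndvi"], -0.95, 0.98)
    ndre = np.clip(values["ndre"], -0.95, 0.98)
    height = values["height"]

    rho_nir = np.where(is_soil, truth.rho_nir["soil"], truth.rho_nir["plant"])
    rho_red = rho_nir * (1.0 - ndvi) / (1.0 + ndvi)
    rho_red_edge = rho_nir * (1.0 - ndre) / (1.0 + ndre)
    distance = np.maximum(config.mount_height - height, 0.02)

    lat, lon = _noisy_latlon(trajectory, fix_index, config.gps_noise_sd,
                             layout.origin, rng)
    df = pd.DataFrame({
        "iso_timestamp": _timestamps(truth.dates[date_index],
                                     trajectory["t"].to_numpy()[fix_index]),
        "lat": lat, "lon": lon, "sensor_id": sensor_id,
        "rho_nir": rho_nir, "rho_red_edge": rho_red_edge, "rho_red": rho_red,
        "distance_m": distance,
        "true_plot_id": plots, "true_class": np.where(is_soil, "soil", "plant"),
    })
    return df


def gen_env_log(layout: FieldLayout, truth: TruthParams,
                trajectory: pd.DataFrame, date_index: int,
                config: TrajectoryConfig | None = None) -> pd.DataFrame:
    """Environmental (weather) records for one campaign date.

    Each value is the date's smooth spatial trend evaluated at the sensor's
    true position plus record-level noise; relative humidity is clipped to
    [0, 100].
    """
    if not 0 <= date_index < len(truth.dates):
        raise IndexError(f"date_index {date_index} out of range")
    config = config or TrajectoryConfig()
    date = truth.dates[date_index]
    rng = np.random.default_rng([truth.seed, 20, date_index])
    sx, sy, sensor_id, fix_index = _sensor_positions(trajectory, config.env_offsets)
    plots = assign_plots(sx, sy, layout, validate=False)
    cols = {}
    for var, per_date in truth.weather_fields.items():
        spec = per_date[date]
        v = eval_field(spec, sx, sy)
        if spec.get("noise_sd", 0.0) > 0:
            v = v + rng.normal(0.0, spec["noise_sd"], len(sx))
        if var == "rh_pct":
            v = np.clip(v, 0.0, 100.0)
        cols[var] = v
    lat, lon = _noisy_latlon(trajectory, fix_index, config.gps_noise_sd,
                             layout.origin, rng)
    df = pd.DataFrame({
        "iso_timestamp": _timestamps(date, trajectory["t"].to_numpy()[fix_index]),
        "lat": lat, "lon": lon, "sensor_id": sensor_id,
        **cols,
        "true_plot_id": plots,
    })
    return df


# ---------------------------------------------------------------------------
# Soil samples and yield
# ---------------------------------------------------------------------------

#: Fractional positions of the six soil cores around the field.
SOIL_SAMPLE_FRACTIONS = [
    (0.08, 0.08), (0.50, 0.12), (0.92, 0.08),
    (0.08, 0.92), (0.50, 0.88), (0.92, 0.92),
]


def gen_soil_and_yield(layout: FieldLayout, truth: TruthParams):
    """Soil-sample table (6 locations x 2 depths) and per-plot yield table.

    Soil values are the true surfaces at the core locations (plus optional
    sampling noise); yield applies the ground-truth sparse linear model to
    each plot's covariates at the last campaign date, in t/ha.
    """
    x_min, y_min, x_max, y_max = layout.bounds()
    rng = np.random.default_rng([truth.seed, 4])
    rows = []
    for fx, fy in SOIL_SAMPLE_FRACTIONS:
        x = x_min + fx * (x_max - x_min)
        y = y_min + fy * (y_max - y_min)
        for depth in SOIL_DEPTHS:
            for prop, spec in truth.soil_surfaces[depth].items():
                v = float(eval_field(spec, x, y))
                if truth.soil_sample_noise_sd > 0:
                    v += rng.normal(0.0, truth.soil_sample_noise_sd)
                rows.append({"x": x, "y": y, "depth": depth,
                             "property": prop, "value": v})
    soil = pd.DataFrame(rows)

    last = len(truth.dates) - 1
    z = _zscore(true_covariates(truth, layout, last))
    frame = layout.frame()
    y_val = np.zeros(len(frame))
    for feat, coef in truth.trait_model["yield"].items():
        if feat == "intercept":
            y_val += coef
        else:
            y_val += coef * z[feat].to_numpy()
    y_val += frame["variety"].map(truth.variety_effect["yield"]).to_numpy()
    noise_sd = truth.plot_noise_sd.get("yield", 0.0)
    if noise_sd > 0:
        y_val += rng.normal(0.0, noise_sd, len(frame))
    yield_df = pd.DataFrame({"plot_id": frame.index, "yield_t_ha": y_val})
    return soil, yield_df


# ---------------------------------------------------------------------------
# Writers / serialization
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_sensor_log(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(df[geoplot.SENSOR_LOG_COLUMNS], path, seed)


def write_env_log(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(df[geoplot.ENV_LOG_COLUMNS], path, seed)


def write_soil_csv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(df[["x", "y", "depth", "property", "value"]], path, seed)


def write_yield_csv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _write_csv(df[["plot_id", "yield_t_ha"]], path, seed)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth_yaml(truth: TruthParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(truth)), fh, sort_keys=True)


def read_truth_yaml(path) -> TruthParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return TruthParams(**doc)


# ---------------------------------------------------------------------------
# Feature-level selection problems (for recovery studies)
# ---------------------------------------------------------------------------

def selection_feature_table(truth: TruthParams, layout: FieldLayout) -> dict[str, pd.DataFrame]:
    """Per-date predictor matrices built from generator truth.

    Columns follow the pipeline naming: raw management values, z-scored soil
    and weather features (weather expanded into the four temporal schemes,
    with the scheme-(a) fallback at the first date), and dummy-coded variety
    (reference level dropped).
    """
    frame = layout.frame()
    dates = truth.dates
    per_date_cov = [true_covariates(truth, layout, i) for i in range(len(dates))]
    varieties = sorted(frame["variety"].unique())
    dummies = pd.get_dummies(frame["variety"]).astype(float)
    dummies = dummies[varieties].iloc[:, 1:]
    dummies.columns = [f"variety:{v}" for v in dummies.columns]
    out = {}
    for i, date in enumerate(dates):
        X = pd.DataFrame(index=frame.index)
        X["row_spacing_mm"] = per_date_cov[i]["row_spacing_mm"]
        X["density_per_ha"] = per_date_cov[i]["density_per_ha"]
        for col in per_date_cov[i].columns:
            if col.startswith("soil:"):
                X[col] = per_date_cov[i][col]
        for var in truth.weather_fields:
            series = np.array([c[f"wx:{var}"].to_numpy() for c in per_date_cov])
            a = series[i]
            b = series[i - 1] if i > 0 else a
            c = series[:i + 1].mean(axis=0)
            d = series[:i].mean(axis=0) if i > 0 else a
            X[f"wx:{var}[a]"], X[f"wx:{var}[b]"] = a, b
            X[f"wx:{var}[c]"], X[f"wx:{var}[d]"] = c, d
        X = pd.concat([X, dummies], axis=1)
        out[date] = X
    return out


def make_selection_problem(layout: FieldLayout, true_features: list[str],
                           snr: float = 3.0, seed: int = 0,
                           dates: list[str] | None = None):
    """Sparse-recovery test problem for forward selection.

    Responses are generated per date as an equal-weight combination of the
    (standardized) true feature columns plus iid noise scaled so that
    sd(signal)/sd(noise) equals *snr*. Returns ``(per_date, true_features)``
    where ``per_date`` maps date -> (X, y).
    """
    truth = default_truth(layout, dates, seed=seed)
    tables = selection_feature_table(truth, layout)
    rng = np.random.default_rng([seed, 77])
    signals = {}
    for date, X in tables.items():
        missing = [f for f in true_features if f not in X.columns]
        if missing:
            raise ValueError(f"unknown true features: {missing}")
        Z = _zscore(X[true_features].astype(float))
        signals[date] = Z.sum(axis=1)
    pooled_sd = float(np.std(np.concatenate([s.to_numpy() for s in signals.values()])))
    noise_sd = pooled_sd / snr
    per_date = {}
    for date, X in tables.items():
        y = signals[date] + rng.normal(0.0, noise_sd, len(X))
        per_date[date] = (X, pd.Series(y, index=X.index, name="response"))
    return per_date, list(true_features)
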