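"""Synthetic scene generation for winter-wheat yield estimation.

The study's field data (gridded combine yields, Sentinel-2 monthly
reflectance, single-date 163-band hyperspectral spectra, management
trials) are not deposited, so this module generates data with the same
statistical structure.  A latent-trait model drives everything: each
grid cell has a yield drawn from a centre-high/edge-low spatial field,
and two latent canopy traits -- greenness and water content -- are
monotone (linear) functions of that yield.  Band reflectances are
affine maps of the latents plus Gaussian noise, arranged so that the
downstream vegetation indices (simple ratio, water index, ...) carry
yield signal with the correct sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    MS_BAND_NAMES,
    MONTH_LABELS,
    VI_NAMES,
    ConfigError,
    SceneConfig,
)

__all__ = [
    "YieldGrid",
    "MultispectralSeries",
    "HyperspectralTable",
    "ManagementTable",
    "hyperspectral_band_centers",
    "default_planted_pairs",
    "nearest_band",
    "generate_yield_grid",
    "simulate_multispectral_series",
    "simulate_hyperspectral_samples",
    "simulate_vi_sequences",
    "generate_management_table",
]

# seed offsets so each generator stage draws an independent stream
_GRID_SEED = 0
_MS_SEED = 1
_HS_SEED = 2
_MGMT_SEED = 3
_VISEQ_SEED = 4


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class YieldGrid:
    """Gridded yield in t/ha on a regular metre grid.

    ``values`` is (n_rows, n_cols); ``mask`` flags valid cells.  The
    flattened valid cells, in row-major order, are the per-sample
    labels used downstream.
    """

    values: np.ndarray
    cell_size_m: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)

    @property
    def yields(self) -> np.ndarray:
        """Valid-cell yields, row-major."""
        return self.values[self.mask]

    @property
    def n_samples(self) -> int:
        return int(self.mask.sum())


@dataclass
class MultispectralSeries:
    """Per-sample multispectral reflectance across repeated scenes.

    ``reflectance`` is (n_samples, n_bands, n_scenes) in [0, 1].  Each
    scene belongs to a month (``scene_month`` indexes
    ``month_labels``) and carries a whole-scene cloud fraction in
    percent; scenes above the cloud threshold are dropped during
    monthly compositing.
    """

    reflectance: np.ndarray
    band_names: tuple[str, ...] = MS_BAND_NAMES
    scene_month: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    cloud_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    month_labels: tuple[str, ...] = MONTH_LABELS
    yields: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if tuple(self.band_names) != MS_BAND_NAMES:
            raise ConfigError(f"band set must be exactly {MS_BAND_NAMES}")
        if self.reflectance.ndim != 3:
            raise ConfigError("reflectance must be (samples, bands, scenes)")

    def band(self, name: str) -> np.ndarray:
        """(n_samples, n_scenes) reflectance of one named band."""
        return self.reflectance[:, self.band_names.index(name), :]

    def to_frame(self) -> pd.DataFrame:
        n, b, s = self.reflectance.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.band_names, range(s)],
            names=["sample", "band", "scene"],
        )
        df = pd.DataFrame(
            {"reflectance": self.reflectance.ravel()}, index=idx
        ).reset_index()
        df["month"] = df["scene"].map(lambda sc: self.month_labels[self.scene_month[sc]])
        df["cloud_fraction"] = self.cloud_fraction[df["scene"].to_numpy()]
        return df


@dataclass
class HyperspectralTable:
    """Per-sample 163-band reflectance spectra with yield labels."""

    reflectance: np.ndarray          # (n_samples, 163)
    band_centers_nm: np.ndarray      # (163,), strictly increasing
    yields: np.ndarray               # (n_samples,), t/ha

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.reflectance.shape[1] != self.band_centers_nm.size:
            raise ConfigError("band count mismatch between spectra and centers")
        if np.any(np.diff(self.band_centers_nm) <= 0):
            raise ConfigError("band centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.band_centers_nm.size

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c:.1f}" for c in self.band_centers_nm]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "yield_t_ha", self.yields)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HyperspectralTable":
        y = df["yield_t_ha"].to_numpy()
        band_cols = [c for c in df.columns if c != "yield_t_ha"]
        centers = np.array([float(c) for c in band_cols])
        return cls(df[band_cols].to_numpy(), centers, y)


@dataclass
class ManagementTable:
    """Per-sample management factors and yield, as a tidy table."""

    data: pd.DataFrame

    FACTORS = ("seeding_rate_kg_ha", "tillage", "fertilizer", "irrigation_mm")

    def __post_init__(self) -> None:
        missing = set(self.FACTORS) - set(self.data.columns)
        if missing or "yield_t_ha" not in self.data.columns:
            raise ConfigError(f"management table missing columns: {missing}")


# ---------------------------------------------------------------------------
# hyperspectral band grid
# ---------------------------------------------------------------------------

def hyperspectral_band_centers() -> np.ndarray:
    """Band centres (nm) of the 163 effective hyperspectral bands.

    The sensor records 76 VNIR bands (396-1040 nm, ~9 nm spacing) and
    90 SWIR bands (1006-2501 nm, ~17 nm spacing); the three SWIR bands
    overlapping the VNIR range are dropped, leaving 163 strictly
    increasing centres.
    """
    vnir = np.linspace(396.0, 1040.0, 76)
    swir = np.linspace(1006.0, 2501.0, 90)
    centers = np.concatenate([vnir, swir[3:]])
    assert centers.size == 163
    return centers


def nearest_band(wavelength_nm: float, centers: np.ndarray | None = None) -> int:
    """Index of the band centre closest to ``wavelength_nm``."""
    if centers is None:
        centers = hyperspectral_band_centers()
    return int(np.argmin(np.abs(np.asarray(centers) - wavelength_nm)))


def default_planted_pairs() -> list[tuple[int, int, int]]:
    """Default informative band pairs.

    A visible/NIR pair (near 516 and 765 nm) whose pair indices
    correlate negatively with yield, and a SWIR pair (near 1779 and
    2216 nm) correlating positively -- the sign pattern observed in
    field spectra of ripening wheat.
    """
    c = hyperspectral_band_centers()
    return [
        (nearest_band(516, c), nearest_band(765, c), -1),
        (nearest_band(1779, c), nearest_band(2216, c), +1),
    ]


# ---------------------------------------------------------------------------
# yield grid
# ---------------------------------------------------------------------------

def generate_yield_grid(config: SceneConfig) -> YieldGrid:
    """Generate a centre-high / edge-low yield field in t/ha.

    The field is a radial trend plus spatially correlated Gaussian
    noise, min-max rescaled into [yield_min, yield_max]; with a flat
    trend and zero noise every cell sits at the range midpoint.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed + _GRID_SEED)
    r = np.arange(config.n_rows)[:, None]
    c = np.arange(config.n_cols)[None, :]
    rc, cc = (config.n_rows - 1) / 2.0, (config.n_cols - 1) / 2.0
    half = max(max(rc, cc), 1.0)
    radial = 1.0 - (((r - rc) / half) ** 2 + ((c - cc) / half) ** 2) / 2.0
    field_ = config.trend_amplitude * radial
    if config.spatial_noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=(config.n_rows, config.n_cols))
        noise = ndimage.gaussian_filter(noise, sigma=2.0, mode="reflect")
        noise /= max(noise.std(), 1e-12)
        field_ = field_ + config.spatial_noise_sd * noise
    lo, hi = field_.min(), field_.max()
    mid = 0.5 * (config.yield_min + config.yield_max)
    if hi - lo < 1e-12:
        values = np.full_like(field_, mid)
    else:
        values = config.yield_min + (field_ - lo) / (hi - lo) * (
            config.yield_max - config.yield_min
        )
    return YieldGrid(values=values, cell_size_m=config.cell_size_m)


# ---------------------------------------------------------------------------
# multispectral time series
# ---------------------------------------------------------------------------

# Seasonal envelopes of the latent traits over Oct..Jun: near-zero
# cover at sowing and dormancy, rapid green-up in spring, peak canopy
# in May, early senescence by June (harvest is mid-June).
_GREENNESS_SEASON = np.array([0.10, 0.15, 0.10, 0.05, 0.10, 0.35, 0.70, 1.00, 0.55])
_WATER_SEASON = np.array([0.10, 0.12, 0.08, 0.05, 0.10, 0.30, 0.65, 1.00, 0.45])

# Affine band maps: reflectance = intercept + slope * latent.  The red
# band (B4) and blue band (B2) are held at their soil/background level
# so that the simple ratio B8/B4 is exactly linear in the greenness
# latent (and hence in yield) in the noiseless limit.
_BAND_MODEL = {
    "B2": (0.05, 0.0, "g"),
    "B3": (0.08, 0.05, "g"),
    "B4": (0.25, 0.0, "g"),
    "B5": (0.18, 0.03, "g"),
    "B6": (0.24, 0.22, "g"),
    "B7": (0.16, 0.30, "g"),
    "B8": (0.15, 0.35, "g"),
    "B11": (0.30, -0.18, "w"),
}


def _seasonal_envelope(base: np.ndarray, n_months: int) -> np.ndarray:
    if n_months == base.size:
        return base
    x = np.linspace(0, 1, base.size)
    return np.interp(np.linspace(0, 1, n_months), x, base)


def simulate_multispectral_series(
    grid: YieldGrid, config: SceneConfig
) -> MultispectralSeries:
    """Simulate repeated multispectral scenes for every grid cell.

    Latent greenness and water trajectories are linear in cell yield,
    scaled by fixed seasonal envelopes; band reflectances are affine
    in the latents plus N(0, noise_sd) noise, clipped to [0, 1].  Each
    month yields ``n_scenes_per_month`` scenes whose cloud fractions
    are drawn from a clear/cloudy mixture so that the >30% filter has
    scenes to discard.
    """
    if config.n_months < 2:
        raise ConfigError("n_months must be >= 2")
    rng = np.random.default_rng(config.seed + _MS_SEED)
    y = grid.yields
    n = y.size
    yn = (y - config.yield_min) / (config.yield_max - config.yield_min)

    g_season = _seasonal_envelope(_GREENNESS_SEASON, config.n_months)
    w_season = _seasonal_envelope(_WATER_SEASON, config.n_months)

    n_scenes = config.n_months * config.n_scenes_per_month
    scene_month = np.repeat(np.arange(config.n_months), config.n_scenes_per_month)

    # cloud mixture: mostly clear scenes, a fraction decisively cloudy
    cloudy = rng.random(n_scenes) < config.cloudy_scene_prob
    cloud_fraction = np.where(
        cloudy, rng.uniform(35.0, 90.0, n_scenes), rng.uniform(0.0, 28.0, n_scenes)
    )
    if config.noise_sd == 0 and config.cloudy_scene_prob == 0:
        cloud_fraction[:] = 0.0

    refl = np.empty((n, len(MS_BAND_NAMES), n_scenes))
    g = yn[:, None] * g_season[scene_month][None, :]   # (n, n_scenes)
    w = yn[:, None] * w_season[scene_month][None, :]
    for b, name in enumerate(MS_BAND_NAMES):
        icept, slope, latent = _BAND_MODEL[name]
        lat = g if latent == "g" else w
        refl[:, b, :] = icept + slope * lat
    if config.noise_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)

    labels = (
        MONTH_LABELS
        if config.n_months == len(MONTH_LABELS)
        else tuple(f"M{m}" for m in range(config.n_months))
    )
    return MultispectralSeries(
        reflectance=refl,
        scene_month=scene_month,
        cloud_fraction=cloud_fraction,
        month_labels=labels,
        yields=y,
    )


# ---------------------------------------------------------------------------
# hyperspectral spectra
# ---------------------------------------------------------------------------

def _baseline_spectrum(centers: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like reflectance baseline over wavelength."""
    lam = centers / 1000.0  # micrometres
    base = 0.05 + 0.02 * np.exp(-((lam - 0.55) ** 2) / (2 * 0.03**2))  # green bump
    base = base + 0.38 / (1.0 + np.exp(-(lam - 0.72) / 0.02))          # red edge
    base = base - 0.18 / (1.0 + np.exp(-(lam - 1.35) / 0.08))          # water falloff
    base = base + 0.08 * np.exp(-((lam - 1.65) ** 2) / (2 * 0.08**2))  # SWIR peak 1
    base = base + 0.06 * np.exp(-((lam - 2.2) ** 2) / (2 * 0.1**2))    # SWIR peak 2
    return np.clip(base, 0.02, 0.95)


def simulate_hyperspectral_samples(
    yields: np.ndarray, config: SceneConfig
) -> HyperspectralTable:
    """Simulate 163-band spectra whose planted band pairs track yield.

    Every band starts from a smooth vegetation-like baseline, scaled
    per sample by a random brightness factor (uncorrelated with yield)
    and perturbed by N(0, noise_sd) noise.  For each planted pair
    (i, j, sign) the two bands are pushed apart in proportion to the
    sample's standardized yield, so the difference/ratio/normalized
    pair indices correlate with yield with the requested sign.  With
    ``noise_sd = 0`` the brightness factor and noise vanish and only
    the planted pairs vary across samples.
    """
    rng = np.random.default_rng(config.seed + _HS_SEED)
    y = np.asarray(yields, dtype=float)
    centers = hyperspectral_band_centers()
    pairs = (
        list(config.planted_pairs)
        if config.planted_pairs is not None
        else default_planted_pairs()
    )
    for i, j, _sign in pairs:
        if i == j:
            raise ConfigError("planted pair must use two distinct bands")
        if not (0 <= i < centers.size and 0 <= j < centers.size):
            raise ConfigError("planted pair band index out of range")

    n = y.size
    base = _baseline_spectrum(centers)
    refl = np.tile(base, (n, 1))

    sd = max(y.std(), 1e-12)
    z = np.clip((y - y.mean()) / sd, -2.5, 2.5)
    amp = config.planted_amplitude
    for i, j, sign in pairs:
        refl[:, i] = base[i] * (1.0 + 0.35 * amp * sign * z)
        refl[:, j] = base[j] * (1.0 - 0.35 * amp * sign * z)

    if config.noise_sd > 0:
        brightness = 1.0 + 5.0 * config.noise_sd * rng.normal(size=(n, 1))
        refl = refl * np.clip(brightness, 0.5, 1.5)
        refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
    refl = np.clip(refl, 1e-4, 1.0)
    return HyperspectralTable(refl, centers, y)


# ---------------------------------------------------------------------------
# direct VI-sequence simulation (model-input generator)
# ---------------------------------------------------------------------------

def simulate_vi_sequences(
    config: SceneConfig,
    n_samples: int,
    dominant_vi: str = "SR",
    nonlinear: bool = True,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-sample VI trajectories with one informative index.

    Returns ``(values, yields)`` with ``values`` of shape
    (n_samples, 4, n_months) in the order EVI, SR, NDWI, REP.  The
    dominant index's trajectory encodes yield through its amplitude
    and -- when ``nonlinear`` -- through the timing of its seasonal
    peak, so recovering yield requires reading the temporal shape, not
    just a single-month level.  The remaining indices are seasonal
    shapes with per-sample random scaling, uncorrelated with yield.
    """
    if dominant_vi not in VI_NAMES:
        raise ConfigError(f"dominant_vi must be one of {VI_NAMES}")
    rng = np.random.default_rng(config.seed + _VISEQ_SEED)
    T = config.n_months
    t = np.arange(T, dtype=float)
    y = rng.uniform(config.yield_min, config.yield_max, size=n_samples)
    yn = (y - config.yield_min) / (config.yield_max - config.yield_min)
    noise = config.noise_sd if noise_sd is None else noise_sd

    # plausible scale/offset per index (REP is a wavelength in nm)
    scales = {"EVI": (0.05, 0.7), "SR": (1.0, 6.0), "NDWI": (-0.1, 0.5), "REP": (705.0, 25.0)}

    values = np.empty((n_samples, len(VI_NAMES), T))
    season = _seasonal_envelope(_GREENNESS_SEASON, T)
    for k, name in enumerate(VI_NAMES):
        off, sc = scales[name]
        if name == dominant_vi:
            if nonlinear:
                amp = 0.3 + 0.7 * yn**2
                peak = 0.45 * T + 0.25 * T * yn
                width = 0.12 * T + 0.05 * T * (1 - yn)
                shape = amp[:, None] * np.exp(
                    -((t[None, :] - peak[:, None]) ** 2) / (2 * width[:, None] ** 2)
                )
            else:
                shape = yn[:, None] * season[None, :]
            values[:, k, :] = off + sc * shape
        else:
            jitter = 1.0 + 0.25 * rng.normal(size=(n_samples, 1))
            values[:, k, :] = off + sc * 0.5 * jitter * season[None, :]
    if noise > 0:
        for k, name in enumerate(VI_NAMES):
            _off, sc = scales[name]
            values[:, k, :] += rng.normal(0.0, noise * abs(sc), size=(n_samples, T))
    return values, y


# ---------------------------------------------------------------------------
# management-factor trials
# ---------------------------------------------------------------------------

_SEEDING_LEVELS = (180.0, 225.0, 270.0, 315.0)
_SEEDING_EFFECT = {180.0: -0.25, 225.0: 0.45, 270.0: 0.0, 315.0: -0.55}
_TILLAGE_LEVELS = ("conventional", "rotational", "no-till")
_TILLAGE_EFFECT = {"conventional": 0.0, "rotational": 0.35, "no-till": -0.10}
_FERT_LEVELS = ("fixed", "variable")
_FERT_EFFECT = {"fixed": 0.0, "variable": 0.30}
_IRRIGATION_LEVELS = (0.0, 20.0, 40.0, 60.0)


def generate_management_table(
    config: SceneConfig, n_samples: int | None = None
) -> ManagementTable:
    """Generate a management-trial table with known group effects.

    Expected yield peaks at a seeding rate of 225 kg/ha (inverted-U:
    denser sowing depresses yield through lodging and competition),
    rises monotonically with irrigation up to 60 mm, and is higher
    under rotational tillage and variable-rate fertilization.  Effect
    sizes scale with ``management_effect_scale``; zero gives equal
    group means up to sampling noise.
    """
    rng = np.random.default_rng(config.seed + _MGMT_SEED)
    n = config.n_hyper_samples if n_samples is None else n_samples
    s = config.management_effect_scale

    seeding = rng.choice(_SEEDING_LEVELS, size=n)
    tillage = rng.choice(_TILLAGE_LEVELS, size=n)
    fert = rng.choice(_FERT_LEVELS, size=n)
    irrigation = rng.choice(_IRRIGATION_LEVELS, size=n)

    base = 0.5 * (config.yield_min + config.yield_max)
    y = (
        base
        + s * np.array([_SEEDING_EFFECT[v] for v in seeding])
        + s * np.array([_TILLAGE_EFFECT[v] for v in tillage])
        + s * np.array([_FERT_EFFECT[v] for v in fert])
        + s * 0.5 * (irrigation / 60.0)
        + rng.normal(0.0, 0.12, size=n)
    )
    y = np.clip(y, config.yield_min, config.yield_max)
    df = pd.DataFrame(
        {
            "seeding_rate_kg_ha": seeding,
            "tillage": tillage,
            "fertilizer": fert,
            "irrigation_mm": irrigation,
            "yield_t_ha": y,
        }
    )
    return ManagementTable(df)


# ---------------------------------------------------------------------------
# provenance sidecar
# ---------------------------------------------------------------------------

def write_scene_sidecar(config: SceneConfig, path: str | Path) -> None:
    """Write the full SceneConfig next to generated data as JSON."""
    import dataclasses
    import json

    d = dataclasses.asdict(config)
    if d["planted_pairs"] is not None:
        d["planted_pairs"] = [list(p) for p in d["planted_pairs"]]
    Path(path).write_text(json.dumps(d, indent=2))
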