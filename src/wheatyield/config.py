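"""Configuration objects for the yield-estimation pipeline.

Every stage of the pipeline is driven by a small dataclass.  A single
global seed in :class:`PipelineConfig` derives per-stage seeds by fixed
offsets so that each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Sentinel-2 band subset used throughout: blue, green, red, three
#: red-edge bands, wide NIR, SWIR1.
MS_BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B11")

#: Month labels for the winter-wheat season, sowing (October) to
#: harvest (June).
MONTH_LABELS = ("Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May", "Jun")

#: Conventional vegetation indices computed from the multispectral bands.
VI_NAMES = ("EVI", "SR", "NDWI", "REP")

#: Acquisition dates for the hyperspectral (single-scene) variant.
DEFAULT_HYPER_DATES = ("2021-03-24", "2021-03-30", "2021-04-28", "2021-05-01")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SceneConfig:
    """Parameters of the synthetic scene generator.

    The defaults reproduce the study conditions: yields spanning
    1.39-6.75 t/ha on a 5 m grid, nine monthly time steps from October
    to June, and 39 hyperspectral ground samples.  The default grid is
    32 x 32 cells to keep generation fast; the full-survey scale
    (~15,709 cells) is reached by enlarging ``n_rows``/``n_cols``.
    """

    n_rows: int = 32
    n_cols: int = 32
    cell_size_m: float = 5.0
    n_months: int = 9
    n_hyper_samples: int = 39
    yield_min: float = 1.39
    yield_max: float = 6.75
    noise_sd: float = 0.01
    seed: int = 0
    #: Informative hyperspectral band pairs as (band_i, band_j, sign)
    #: where ``sign`` is the sign of the correlation between the pair
    #: index and yield.  ``None`` selects the defaults: a visible-NIR
    #: pair correlating negatively and a SWIR pair correlating
    #: positively with yield.
    planted_pairs: Sequence[tuple[int, int, int]] | None = None
    #: Amplitude of the radial centre-high / edge-low yield trend;
    #: 0 gives a flat field.
    trend_amplitude: float = 1.0
    #: Standard deviation of the spatially correlated yield noise,
    #: in trend units before rescaling to [yield_min, yield_max].
    spatial_noise_sd: float = 0.15
    #: Scenes acquired per month (cloud filtering keeps a subset).
    n_scenes_per_month: int = 3
    #: Probability that a scene is cloudy (>30% cover) and hence
    #: discarded by the compositing filter.
    cloudy_scene_prob: float = 0.25
    #: Relative reflectance perturbation per unit of standardized yield
    #: applied to the planted hyperspectral bands.
    planted_amplitude: float = 0.15
    #: Multiplier on all management-factor effect sizes; 0 removes all
    #: group differences.
    management_effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if self.n_months < 2:
            raise ConfigError("n_months must be >= 2")
        if not self.yield_min < self.yield_max:
            raise ConfigError("yield_min must be < yield_max")
        for name in ("noise_sd", "spatial_noise_sd", "planted_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_hyper_samples < 3:
            raise ConfigError("n_hyper_samples must be >= 3")
        if self.planted_pairs is not None:
            for i, j, sign in self.planted_pairs:
                if i == j:
                    raise ConfigError("planted pair must use two distinct bands")
                if sign not in (-1, 1):
                    raise ConfigError("planted pair sign must be -1 or +1")


@dataclass
class SplitSpec:
    """Random train/test partition; the study used a 9:1 ratio."""

    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")


@dataclass
class LSTMConfig:
    """Hyperparameters of the two-layer LSTM regressor.

    Defaults follow the study settings: two stacked LSTM layers of 100
    units, ReLU before the dense head, dropout 0.3, L2 regularization,
    Adam at learning rate 0.001, batch size 64, 700 epochs, MSE loss.
    The L2 coefficient is not fixed by the study; 1e-4 is the package
    default.
    """

    n_layers: int = 2
    hidden_units: int = 100
    dropout: float = 0.3
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 700
    seed: int = 0
    #: Optional (low, high) clip applied to predictions, in t/ha.
    clip_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_units < 1:
            raise ConfigError("n_layers and hidden_units must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        for name in ("learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.l2_lambda < 0:
            raise ConfigError("l2_lambda must be >= 0")


@dataclass
class BaselineConfig:
    """Hyperparameters of the RF / GBDT / SVR baseline regressors.

    Defaults are the study's tuned settings: RF with 150 trees and
    random state 200 (out-of-bag scoring on); GBDT with 1250 trees,
    subsample 0.6, learning rate 0.1; SVR with an RBF kernel, C = 1e5,
    gamma = 0.5.
    """

    model: str = "RF"
    rf_n_trees: int = 150
    rf_random_state: int = 200
    gbdt_n_trees: int = 1250
    gbdt_subsample: float = 0.6
    gbdt_learning_rate: float = 0.1
    svr_kernel: str = "rbf"
    svr_c: float = 1e5
    svr_gamma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("RF", "GBDT", "SVR"):
            raise ConfigError("model must be one of RF, GBDT, SVR")
        for name in (
            "rf_n_trees",
            "gbdt_n_trees",
            "gbdt_subsample",
            "gbdt_learning_rate",
            "svr_c",
            "svr_gamma",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    """Full pipeline configuration: scene + split + models + options."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    cloud_threshold: float = 30.0
    selection_alpha: float = 0.001
    hyper_dates: Sequence[str] = DEFAULT_HYPER_DATES
    output_dir: str = "runs/run"
    seed: int = 0

    # per-stage seed offsets, documented so stages can be rerun alone
    SEED_OFFSETS = {
        "scene": 0,
        "split": 1,
        "lstm": 2,
        "importance": 3,
    }

    def __post_init__(self) -> None:
        if not 0 < self.cloud_threshold <= 100:
            raise ConfigError("cloud_threshold must be a percentage in (0, 100]")
        if not 0 < self.selection_alpha < 1:
            raise ConfigError("selection_alpha must be in (0, 1)")
        # propagate the global seed into stage configs by fixed offsets
        self.scene = dataclasses.replace(
            self.scene, seed=self.seed + self.SEED_OFFSETS["scene"]
        )
        self.split = dataclasses.replace(
            self.split, seed=self.seed + self.SEED_OFFSETS["split"]
        )
        self.lstm = dataclasses.replace(
            self.lstm, seed=self.seed + self.SEED_OFFSETS["lstm"]
        )

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["scene"]["planted_pairs"] is not None:
            d["scene"]["planted_pairs"] = [
                list(p) for p in d["scene"]["planted_pairs"]
            ]
        d["hyper_dates"] = list(d["hyper_dates"])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            scene = dict(d["scene"])
            if scene.get("planted_pairs") is not None:
                scene["planted_pairs"] = [tuple(p) for p in scene["planted_pairs"]]
            d["scene"] = SceneConfig(**scene)
        if "split" in d:
            d["split"] = SplitSpec(**d["split"])
        if "lstm" in d:
            lstm = dict(d["lstm"])
            if lstm.get("clip_range") is not None:
                lstm["clip_range"] = tuple(lstm["clip_range"])
            d["lstm"] = LSTMConfig(**lstm)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
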