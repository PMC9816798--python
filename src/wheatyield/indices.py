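"""Vegetation indices, cloud filtering and monthly compositing.

Four indices are computed from the eight multispectral bands:

* EVI  = 2.5 * (B8 - B4) / (B8 + 6*B4 - 7.5*B2 + 1)   (greenness)
* SR   = B8 / B4                                       (greenness)
* NDWI = (B8 - B11) / (B8 + B11)                       (canopy water)
* REP  = 705 + 35 * (0.5*(B4 + B7) - B5) / (B6 - B5)   (red-edge position, nm)

Scenes with whole-scene cloud cover strictly greater than the
threshold (default 30%) are discarded; surviving scenes are averaged
per index within calendar months; empty months are filled by linear
interpolation between neighbouring months.  Guard violations (zero
denominators) yield NaN, which compositing treats as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MONTH_LABELS, VI_NAMES
from .synth import MultispectralSeries

__all__ = [
    "compute_evi",
    "compute_sr",
    "compute_ndwi",
    "compute_rep",
    "VIMatrix",
    "monthly_composite",
    "flatten_vi_matrix",
    "unflatten_vi_matrix",
]

_EPS = 1e-9


def compute_evi(b2, b4, b8):
    """Enhanced vegetation index; NaN where the denominator vanishes."""
    b2, b4, b8 = np.asarray(b2, float), np.asarray(b4, float), np.asarray(b8, float)
    denom = b8 + 6.0 * b4 - 7.5 * b2 + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < _EPS, np.nan, 2.5 * (b8 - b4) / denom)
    return out[()] if out.ndim == 0 else out


def compute_sr(b4, b8):
    """Simple ratio B8/B4; NaN where the red band is zero."""
    b4, b8 = np.asarray(b4, float), np.asarray(b8, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(b4) < _EPS, np.nan, b8 / b4)
    return out[()] if out.ndim == 0 else out


def compute_ndwi(b8, b11):
    """Normalized difference water index, in [-1, 1]; NaN where B8+B11=0."""
    b8, b11 = np.asarray(b8, float), np.asarray(b11, float)
    denom = b8 + b11
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < _EPS, np.nan, (b8 - b11) / denom)
    return out[()] if out.ndim == 0 else out


def compute_rep(b4, b5, b6, b7):
    """Red-edge position in nm by linear interpolation.

    705 + 35 * (0.5*(B4+B7) - B5) / (B6 - B5); reduces to 705 nm when
    the midpoint of the red and third red-edge bands equals the first
    red-edge band.  NaN where B6 = B5.
    """
    b4 = np.asarray(b4, float)
    b5 = np.asarray(b5, float)
    b6 = np.asarray(b6, float)
    b7 = np.asarray(b7, float)
    denom = b6 - b5
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            np.abs(denom) < _EPS, np.nan, 705.0 + 35.0 * (0.5 * (b4 + b7) - b5) / denom
        )
    return out[()] if out.ndim == 0 else out


@dataclass
class VIMatrix:
    """Per-sample vegetation-index-by-month matrix (the model input).

    ``values`` has shape (n_samples, n_vi, n_months); rows follow
    ``vi_names`` (EVI, SR, NDWI, REP by default), columns follow
    ``month_labels`` in calendar order October to June.
    """

    values: np.ndarray
    vi_names: tuple[str, ...] = VI_NAMES
    month_labels: tuple[str, ...] = MONTH_LABELS
    yields: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (samples, vi, months)")
        if self.values.shape[1] != len(self.vi_names):
            raise ValueError("vi axis does not match vi_names")
        if self.values.shape[2] != len(self.month_labels):
            raise ValueError("month axis does not match month_labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def sequences(self) -> np.ndarray:
        """Time-major view (n_samples, n_months, n_vi) for sequence models."""
        return np.transpose(self.values, (0, 2, 1))

    def to_tidy(self) -> pd.DataFrame:
        n, v, t = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.vi_names, self.month_labels],
            names=["sample", "vi", "month"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "VIMatrix":
        vis = list(dict.fromkeys(df["vi"]))
        months = list(dict.fromkeys(df["month"]))
        n = df["sample"].nunique()
        pivot = df.pivot_table(
            index="sample", columns=["vi", "month"], values="value", sort=False
        )
        values = np.empty((n, len(vis), len(months)))
        for i, vi in enumerate(vis):
            for j, m in enumerate(months):
                values[:, i, j] = pivot[(vi, m)].to_numpy()
        return cls(values, tuple(vis), tuple(months))


#: REP values outside this window (nm) come from a near-degenerate
#: red-edge interpolation and are treated as missing per scene.
_REP_VALID_NM = (600.0, 820.0)


def _scene_vi(series: MultispectralSeries) -> np.ndarray:
    """Per-scene VI values, shape (n_samples, 4, n_scenes)."""
    b = series.band
    rep = compute_rep(b("B4"), b("B5"), b("B6"), b("B7"))
    rep = np.where((rep < _REP_VALID_NM[0]) | (rep > _REP_VALID_NM[1]), np.nan, rep)
    return np.stack(
        [
            compute_evi(b("B2"), b("B4"), b("B8")),
            compute_sr(b("B4"), b("B8")),
            compute_ndwi(b("B8"), b("B11")),
            rep,
        ],
        axis=1,
    )


def monthly_composite(
    series: MultispectralSeries, cloud_threshold: float = 30.0
) -> VIMatrix:
    """Cloud-filter scenes and average per-scene VIs within months.

    A scene is retained iff its cloud fraction is <= ``cloud_threshold``
    (strictly greater is discarded, so a scene at exactly 30.0% stays).
    Each matrix cell is the mean of the retained scenes' index values
    for that month; NaN index values are excluded from the mean.
    Months left empty (no retained scene, or all values missing) are
    filled by linear interpolation over month index, extrapolating
    flat at the ends.  If every month is empty a ValueError is raised.
    """
    vi_scene = _scene_vi(series)                     # (n, 4, S)
    keep = series.cloud_fraction <= cloud_threshold
    n_months = len(series.month_labels)
    n, n_vi, _ = vi_scene.shape
    out = np.full((n, n_vi, n_months), np.nan)
    for m in range(n_months):
        sel = keep & (series.scene_month == m)
        if not sel.any():
            continue
        with np.errstate(invalid="ignore"):
            out[:, :, m] = np.nanmean(vi_scene[:, :, sel], axis=2)

    month_ok = ~np.all(np.isnan(out), axis=(0, 1))
    if not month_ok.any():
        raise ValueError("no month retains any usable scene")

    # interpolate missing cells along the month axis
    if np.isnan(out).any():
        t = np.arange(n_months, dtype=float)
        flat = out.reshape(-1, n_months)
        bad_rows = np.isnan(flat).any(axis=1)
        for row in np.flatnonzero(bad_rows):
            v = flat[row]
            good = ~np.isnan(v)
            if not good.any():
                raise ValueError("a sample/index has no usable scene in any month")
            flat[row] = np.interp(t, t[good], v[good])
        out = flat.reshape(n, n_vi, n_months)

    return VIMatrix(out, month_labels=series.month_labels, yields=series.yields)


def flatten_vi_matrix(m: VIMatrix) -> np.ndarray:
    """Row-major (index-major) flattening to (n_samples, n_vi * n_months).

    The first ``n_months`` entries are the first index's trajectory,
    and so on; a 4 x 9 matrix becomes a length-36 vector.  Missing
    entries are rejected: impute (composite) first.
    """
    if np.isnan(m.values).any():
        raise ValueError("VI matrix contains missing entries; impute before flattening")
    n, v, t = m.values.shape
    return m.values.reshape(n, v * t)


def unflatten_vi_matrix(
    flat: np.ndarray,
    vi_names: tuple[str, ...] = VI_NAMES,
    month_labels: tuple[str, ...] = MONTH_LABELS,
) -> VIMatrix:
    """Inverse of :func:`flatten_vi_matrix`."""
    flat = np.asarray(flat, float)
    n = flat.shape[0]
    return VIMatrix(
        flat.reshape(n, len(vi_names), len(month_labels)), vi_names, month_labels
    )
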