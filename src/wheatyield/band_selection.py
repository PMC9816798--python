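"""Exhaustive two-band spectral-index screening against yield.

Three pair indices are formed from any two of the 163 hyperspectral
bands (reflectances R_i, R_j):

* SSI(i, j)  = R_i - R_j                (simple difference)
* RSI(i, j)  = R_i / R_j                (ratio)
* NDSI(i, j) = (R_i - R_j) / (R_i + R_j) (normalized difference)

Every pair's index is correlated (Pearson) with yield across samples;
the pairs with the strongest positive and negative correlations that
pass a significance threshold (p < 0.001) become the custom features
of the hyperspectral model variant.  SSI and NDSI are antisymmetric
in (i, j), so the search enumerates unordered pairs -- 163 bands give
163*162/2 = 13,203 combinations -- and fills the lower triangle by
sign flip; RSI is not antisymmetric and is searched over ordered
pairs by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import HyperspectralTable

__all__ = [
    "INDEX_TYPES",
    "compute_pair_index",
    "BandPairSurface",
    "pairwise_correlation_surface",
    "PairCorrelation",
    "ExtremePairs",
    "SelectionResult",
    "select_extreme_pairs",
    "select_all_index_types",
    "extract_custom_features",
    "plot_surface",
]

INDEX_TYPES = ("SSI", "RSI", "NDSI")
_EPS = 1e-12


def compute_pair_index(spectra, i: int, j: int, index_type: str):
    """Pair index of bands ``i`` and ``j`` for each sample.

    ``spectra`` is (n_samples, n_bands) (or a single spectrum).  Guard
    violations (R_j = 0 for RSI; R_i + R_j = 0 for NDSI) yield NaN for
    the affected samples.
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"index_type must be one of {INDEX_TYPES}")
    spectra = np.atleast_2d(np.asarray(spectra, float))
    ri, rj = spectra[:, i], spectra[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        if index_type == "SSI":
            out = ri - rj
        elif index_type == "RSI":
            out = np.where(np.abs(rj) < _EPS, np.nan, ri / rj)
        else:
            s = ri + rj
            out = np.where(np.abs(s) < _EPS, np.nan, (ri - rj) / s)
    return out if out.size > 1 else float(out[0])


@dataclass
class BandPairSurface:
    """Correlation-with-yield surface over all band pairs.

    ``r[i, j]`` and ``p[i, j]`` hold the Pearson correlation between
    the (i, j) pair index and yield and its two-sided p-value; NaN
    marks pairs that are undefined (diagonal for SSI/NDSI, constant
    index, fewer than three valid samples).
    """

    index_type: str
    r: np.ndarray
    p: np.ndarray
    band_centers_nm: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.band_centers_nm.size

    @property
    def n_unordered_pairs(self) -> int:
        """Number of unordered pairs i < j with a defined correlation."""
        iu, ju = np.triu_indices(self.n_bands, k=1)
        return int(np.isfinite(self.r[iu, ju]).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (i_nm, j_nm, index_type, r, p), upper triangle."""
        iu, ju = np.triu_indices(self.n_bands, k=1)
        c = self.band_centers_nm
        return pd.DataFrame(
            {
                "i_nm": c[iu],
                "j_nm": c[ju],
                "index_type": self.index_type,
                "r": self.r[iu, ju],
                "p": self.p[iu, ju],
            }
        )


def _pearson_with_target(values: np.ndarray, y: np.ndarray):
    """Column-wise Pearson r and two-sided p against ``y``, NaN-aware.

    ``values`` is (n_samples, n_cols); columns with fewer than three
    valid samples or zero variance get NaN.
    """
    valid = np.isfinite(values)
    n = valid.sum(axis=0).astype(float)
    v = np.where(valid, values, 0.0)
    yv = np.where(valid, y[:, None], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sv, sy = v.sum(0), yv.sum(0)
        svv, syy, svy = (v * v).sum(0), (yv * yv).sum(0), (v * yv).sum(0)
        cov = svy - sv * sy / n
        var_v = svv - sv**2 / n
        var_y = syy - sy**2 / n
        denom = np.sqrt(var_v * var_y)
        r = np.where((n >= 3) & (denom > _EPS), cov / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, _EPS))
        p = np.where(np.isfinite(r), 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    return r, p


def pairwise_correlation_surface(
    table: HyperspectralTable, index_type: str, ordered: bool | None = None
) -> BandPairSurface:
    """Correlate every band-pair index with yield across samples.

    For SSI/NDSI the computation runs over unordered pairs i < j and
    the lower triangle is filled by antisymmetry, r(j, i) = -r(i, j);
    for RSI all ordered pairs i != j are evaluated (``ordered`` can
    override either default).  The diagonal is NaN (the pair index is
    constant there).
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"index_type must be one of {INDEX_TYPES}")
    if ordered is None:
        ordered = index_type == "RSI"
    R = table.reflectance
    y = table.yields
    nb = table.n_bands
    r_mat = np.full((nb, nb), np.nan)
    p_mat = np.full((nb, nb), np.nan)

    iu, ju = np.triu_indices(nb, k=1)
    vals = compute_pair_index(R, iu, ju, index_type)  # (n_samples, n_pairs)
    r_u, p_u = _pearson_with_target(vals, y)
    r_mat[iu, ju], p_mat[iu, ju] = r_u, p_u
    if index_type in ("SSI", "NDSI"):
        # antisymmetry halves the computation
        r_mat[ju, iu], p_mat[ju, iu] = -r_u, p_u
    elif ordered:
        vals_l = compute_pair_index(R, ju, iu, index_type)
        r_l, p_l = _pearson_with_target(vals_l, y)
        r_mat[ju, iu], p_mat[ju, iu] = r_l, p_l
    return BandPairSurface(index_type, r_mat, p_mat, table.band_centers_nm)


@dataclass
class PairCorrelation:
    """One selected band pair with its correlation and wavelengths."""

    i: int
    j: int
    r: float
    p: float
    i_nm: float
    j_nm: float

    def to_dict(self) -> dict:
        return {
            "i": self.i,
            "j": self.j,
            "r": self.r,
            "p": self.p,
            "i_nm": self.i_nm,
            "j_nm": self.j_nm,
        }


@dataclass
class ExtremePairs:
    """Strongest positive and negative pairs for one index type."""

    index_type: str
    positive: PairCorrelation | None
    negative: PairCorrelation | None

    @property
    def best(self) -> PairCorrelation | None:
        """The pair with the largest |r| among the two extremes."""
        cands = [c for c in (self.positive, self.negative) if c is not None]
        if not cands:
            return None
        return max(cands, key=lambda c: abs(c.r))

    def to_dict(self) -> dict:
        return {
            "index_type": self.index_type,
            "positive": self.positive.to_dict() if self.positive else None,
            "negative": self.negative.to_dict() if self.negative else None,
        }


#: Selection across all three index types.
SelectionResult = dict[str, ExtremePairs]


def _argext(surface: BandPairSurface, alpha: float, sign: int) -> PairCorrelation | None:
    r, p = surface.r, surface.p
    ok = np.isfinite(r) & (p < alpha)
    if surface.index_type in ("SSI", "NDSI"):
        # antisymmetric surfaces: search unordered pairs i < j only,
        # otherwise the negative extreme is always the positive's mirror
        ok &= np.triu(np.ones_like(ok, dtype=bool), k=1)
    if sign > 0:
        ok &= r > 0
    else:
        ok &= r < 0
    if not ok.any():
        return None
    masked = np.where(ok, r, -np.inf if sign > 0 else np.inf)
    target = masked.max() if sign > 0 else masked.min()
    ii, jj = np.nonzero(np.isclose(masked, target, rtol=0, atol=0))
    # ties broken by smaller (i, then j): nonzero returns row-major order
    i, j = int(ii[0]), int(jj[0])
    c = surface.band_centers_nm
    return PairCorrelation(i, j, float(r[i, j]), float(p[i, j]), float(c[i]), float(c[j]))


def select_extreme_pairs(surface: BandPairSurface, alpha: float = 0.001) -> ExtremePairs:
    """Strongest positive and negative significant pairs of one surface.

    Returns the argmax and argmin of r over pairs with p < ``alpha``
    (unordered pairs i < j for the antisymmetric SSI/NDSI, all ordered
    pairs for RSI); ties are broken by the lexicographically smaller
    (i, j).  A sign
    with no significant pair is reported as None with a warning; a
    surface with no finite correlation at all is an error.
    """
    if not np.isfinite(surface.r).any():
        raise ValueError("correlation surface is fully missing")
    pos = _argext(surface, alpha, +1)
    neg = _argext(surface, alpha, -1)
    if pos is None or neg is None:
        missing = [s for s, c in (("positive", pos), ("negative", neg)) if c is None]
        warnings.warn(
            f"{surface.index_type}: no significant {'/'.join(missing)} pair "
            f"at alpha={alpha}",
            stacklevel=2,
        )
    return ExtremePairs(surface.index_type, pos, neg)


def select_all_index_types(
    table: HyperspectralTable, alpha: float = 0.001
) -> SelectionResult:
    """Run the exhaustive search for SSI, RSI and NDSI."""
    return {
        t: select_extreme_pairs(pairwise_correlation_surface(table, t), alpha)
        for t in INDEX_TYPES
    }


def extract_custom_features(
    tables: HyperspectralTable | list[HyperspectralTable],
    selection: SelectionResult,
    dates: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-sample custom-index features, one per index type per date.

    ``tables`` holds one spectra table per acquisition date (a single
    table counts as one date).  For each index type the pair with the
    largest |r| in ``selection`` is evaluated on each date's spectra,
    giving an (n_samples, 3, n_dates) array plus the index-type and
    date labels.  The 3 x n_dates matrix per sample is the input of
    the hyperspectral model variant.
    """
    if isinstance(tables, HyperspectralTable):
        tables = [tables]
    if dates is None:
        dates = [f"date{k}" for k in range(len(tables))]
    if len(dates) != len(tables):
        raise ValueError("one date label per table required")
    for t in INDEX_TYPES:
        if t not in selection or selection[t].best is None:
            raise ValueError(f"selection has no usable pair for {t}")
    n = tables[0].reflectance.shape[0]
    out = np.empty((n, len(INDEX_TYPES), len(tables)))
    for d, tab in enumerate(tables):
        if tab.reflectance.shape[0] != n:
            raise ValueError("all dates must cover the same samples")
        for k, t in enumerate(INDEX_TYPES):
            best = selection[t].best
            out[:, k, d] = compute_pair_index(tab.reflectance, best.i, best.j, t)
    return out, list(INDEX_TYPES), list(dates)


def plot_surface(surface: BandPairSurface, ax=None):
    """Heatmap of the correlation surface over band wavelengths."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 5))
    c = surface.band_centers_nm
    im = ax.pcolormesh(c, c, surface.r, cmap="RdBu_r", vmin=-1, vmax=1, shading="auto")
    ax.set_xlabel("band j wavelength (nm)")
    ax.set_ylabel("band i wavelength (nm)")
    ax.set_title(f"{surface.index_type}(i, j) correlation with yield")
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax
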