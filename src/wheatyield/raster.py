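"""GeoTIFF export of gridded yield maps.

Rasters are written with tifffile, carrying the GeoTIFF
ModelPixelScale and ModelTiepoint tags for the synthetic affine grid
plus the GDAL nodata convention for masked cells.  That is enough
georeference for a map viewer; no coordinate reference system is
attached (the scene is a synthetic local grid).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .synth import YieldGrid

__all__ = ["write_yield_map", "read_yield_map", "NODATA"]

NODATA = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_yield_map(grid: YieldGrid, predictions: np.ndarray, path: str | Path) -> Path:
    """Write predictions aligned to a yield grid as a float32 GeoTIFF.

    ``predictions`` is either a full (n_rows, n_cols) array or a
    vector over the grid's valid cells (row-major); masked cells are
    encoded as the nodata value.
    """
    path = Path(path)
    pred = np.asarray(predictions, float)
    if pred.ndim == 1:
        if pred.size != grid.n_samples:
            raise ValueError(
                f"got {pred.size} predictions for {grid.n_samples} valid cells"
            )
        full = np.full(grid.values.shape, NODATA)
        full[grid.mask] = pred
    elif pred.shape == grid.values.shape:
        full = np.where(grid.mask, pred, NODATA)
    else:
        raise ValueError(f"prediction shape {pred.shape} does not match grid")

    sx = sy = float(grid.cell_size_m)
    x0, y0 = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA)),
    ]
    tifffile.imwrite(path, full.astype(np.float32), extratags=extratags)
    return path


def read_yield_map(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a yield map back; returns (values, georeference dict).

    Nodata cells are returned as NaN.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    geo = {}
    if _TAG_PIXEL_SCALE in tags:
        geo["cell_size_m"] = float(tags[_TAG_PIXEL_SCALE][0])
    if _TAG_TIEPOINT in tags:
        tp = tags[_TAG_TIEPOINT]
        geo["origin"] = (float(tp[3]), float(tp[4]))
    nodata = float(tags.get(_TAG_GDAL_NODATA, NODATA))
    values = np.where(values == np.float32(nodata), np.nan, values)
    return values, geo
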