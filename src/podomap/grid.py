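"""Raster data model and spatial primitives.

All spatial computation in the pipeline runs on regular planar grids:
covariate layers, suitability surfaces, population and zone rasters share a
single :class:`GridSpec`. Coordinates are projected (km by convention), row 0
is the northernmost row, and cells own the half-open box
``[x0, x0 + cell) x [y0, y0 + cell)`` so that a point on a shared edge belongs
deterministically to the cell on its right / top.

GeoTIFF I/O is implemented on :mod:`tifffile`, using the standard GeoTIFF
georeferencing tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger("podomap")

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class GridError(ValueError):
    """Raised for invalid grid specifications or misaligned rasters."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid.

    ``x_min, y_min`` are the coordinates of the grid's lower-left corner and
    ``cell_size`` the square cell edge, all in the same projected units
    (km throughout the synthetic scenarios). Row 0 is the northernmost row.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    crs_label: str = "planar-km"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(f"grid must have >=1 rows and cols, got {self.n_rows}x{self.n_cols}")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned(self, other: "GridSpec") -> bool:
        return self == other

    def x_centres(self) -> np.ndarray:
        """Cell-centre x coordinates, west to east (length n_cols)."""
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        """Cell-centre y coordinates, north to south (length n_rows)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention.

        Returns ``(row, col, inside)``; row/col are meaningless where
        ``inside`` is False.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        # row counted from the bottom, edge point belongs to the cell above
        row_from_bottom = np.floor((y - self.y_min) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class GridRaster:
    """A georeferenced 2-D value grid with explicit nodata handling.

    ``nodata_mask`` is True where the cell holds no data; masked cells are
    excluded from every statistic and propagate through every operation.
    """

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.nodata_mask.shape != self.spec.shape:
            raise GridError(
                f"raster arrays {self.values.shape} do not match grid {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy(self) -> "GridRaster":
        return GridRaster(self.spec, self.values.copy(), self.nodata_mask.copy())

    def with_values(self, values: np.ndarray, extra_mask: np.ndarray | None = None) -> "GridRaster":
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return GridRaster(self.spec, np.asarray(values, dtype=float), mask)


@dataclass
class CovariateStack:
    """Aligned, named covariate layers; the model's environmental space."""

    names: list[str]
    layers: list[GridRaster]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.layers):
            raise GridError("names and layers length mismatch")
        if len(set(self.names)) != len(self.names):
            raise GridError("covariate names must be unique")
        if self.layers:
            spec = self.layers[0].spec
            for name, layer in zip(self.names, self.layers):
                if not layer.spec.aligned(spec):
                    raise GridError(f"layer {name!r} is not aligned with the stack grid")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    def layer(self, name: str) -> GridRaster:
        try:
            return self.layers[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no covariate named {name!r}") from None

    def valid_mask(self) -> np.ndarray:
        """A cell is stack-valid iff valid in every layer."""
        mask = np.ones(self.spec.shape, dtype=bool)
        for layer in self.layers:
            mask &= layer.valid_mask
        return mask

    def table(self, cell_mask: np.ndarray | None = None) -> pd.DataFrame:
        """Covariate values of (a subset of) stack-valid cells, row-major order."""
        mask = self.valid_mask() if cell_mask is None else (self.valid_mask() & cell_mask)
        return pd.DataFrame(
            {name: layer.values[mask] for name, layer in zip(self.names, self.layers)}
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(path, raster: GridRaster, nodata: float = DEFAULT_NODATA) -> None:
    """Write a single-band float32 GeoTIFF with explicit nodata tag."""
    spec = raster.spec
    out = raster.values.astype(np.float32)
    out[raster.nodata_mask] = np.float32(nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0), True),
        # tiepoint anchors raster (0,0) pixel corner at (x_min, y_max)
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata)), True),
    ]
    tifffile.imwrite(
        path,
        out,
        extratags=extratags,
        metadata=None,
        description=spec.crs_label,
    )


def read_raster(path) -> GridRaster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale, tiepoint and nodata tags)."""
    try:
        tf = tifffile.TiffFile(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"raster file not found: {path}") from None
    except Exception as exc:  # tifffile raises its own hierarchy on bad files
        raise GridError(f"cannot read {path} as a GeoTIFF: {exc}") from exc
    with tf:
        page = tf.pages[0]
        if len(tf.pages) > 1 or page.samplesperpixel != 1:
            raise GridError(f"{path}: expected a single-band raster")
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise GridError(f"{path}: missing GeoTIFF georeferencing tags")
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise GridError(f"{path}: expected a 2-D single-band raster")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not np.isclose(sx, sy) or sx <= 0:
            raise GridError(f"{path}: unreadable georeferencing (cell {sx}x{sy})")
        _, _, _, x_ul, y_ul, _ = (float(v) for v in tie_tag.value[:6])
        n_rows, n_cols = values.shape
        spec = GridSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            x_min=x_ul,
            y_min=y_ul - n_rows * sy,
            cell_size=sx,
            crs_label=(page.description or "planar-km"),
        )
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        mask = ~np.isfinite(values)
        if nodata_tag is not None:
            nodata = float(str(nodata_tag.value))
            mask |= values == nodata
        return GridRaster(spec, values, mask)


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(src: GridRaster, target: GridSpec, method: str = "bilinear") -> GridRaster:
    """Resample a raster onto a target grid.

    Bilinear output at a target cell centre interpolates the 4 surrounding
    source cell centres; any target cell whose interpolation touches a masked
    source cell is masked (conservative nodata propagation). Nearest assigns
    the value of the source cell containing the target centre.
    """
    if method not in ("bilinear", "nearest"):
        raise GridError(f"unknown resampling method {method!r}")
    if src.spec == target:
        return src.copy()
    if (
        target.x_min >= src.spec.x_max
        or target.x_max <= src.spec.x_min
        or target.y_min >= src.spec.y_max
        or target.y_max <= src.spec.y_min
    ):
        raise GridError("source and target extents do not overlap")

    tx = target.x_centres()
    ty = target.y_centres()
    gx, gy = np.meshgrid(tx, ty)

    if method == "nearest":
        row, col, inside = src.spec.cell_index(gx.ravel(), gy.ravel())
        out = np.full(target.shape, np.nan)
        mask = np.ones(target.shape, dtype=bool)
        r = row[inside]
        c = col[inside]
        flat_idx = np.flatnonzero(inside)
        out.ravel()[flat_idx] = src.values[r, c]
        mask.ravel()[flat_idx] = src.nodata_mask[r, c]
        return GridRaster(target, out, mask)

    # bilinear on the lattice of source cell centres
    sx = src.spec.x_centres()
    sy = src.spec.y_centres()  # descending
    # fractional index along columns / rows of the source centre lattice
    fx = (gx - sx[0]) / src.spec.cell_size
    fy = (sy[0] - gy) / src.spec.cell_size
    j0 = np.floor(fx).astype(int)
    i0 = np.floor(fy).astype(int)
    wx = fx - j0
    wy = fy - i0
    inside = (fx >= 0) & (fx <= src.spec.n_cols - 1) & (fy >= 0) & (fy <= src.spec.n_rows - 1)
    j0c = np.clip(j0, 0, src.spec.n_cols - 2)
    i0c = np.clip(i0, 0, src.spec.n_rows - 2)
    # when fx lands exactly on the last centre, shift the cell and weight
    wx = np.where(j0 > j0c, wx + (j0 - j0c), wx)
    wy = np.where(i0 > i0c, wy + (i0 - i0c), wy)

    v00 = src.values[i0c, j0c]
    v01 = src.values[i0c, j0c + 1]
    v10 = src.values[i0c + 1, j0c]
    v11 = src.values[i0c + 1, j0c + 1]
    out = (
        v00 * (1 - wx) * (1 - wy)
        + v01 * wx * (1 - wy)
        + v10 * (1 - wx) * wy
        + v11 * wx * wy
    )
    touched_nodata = (
        src.nodata_mask[i0c, j0c]
        | src.nodata_mask[i0c, j0c + 1]
        | src.nodata_mask[i0c + 1, j0c]
        | src.nodata_mask[i0c + 1, j0c + 1]
    )
    mask = ~inside | touched_nodata
    out = np.where(mask, np.nan, out)
    return GridRaster(target, out, mask)


# ---------------------------------------------------------------------------
# Distance surfaces


def distance_to_features(feature_mask: GridRaster) -> GridRaster:
    """Euclidean distance (in grid units, km by convention) from each cell
    centre to the nearest feature (value 1) cell centre.

    Feature cells hold 0. Masked cells stay masked in the output, but valid
    feature cells behind them are still usable as distance sources.
    """
    features = (feature_mask.values == 1) & feature_mask.valid_mask
    if not features.any():
        raise GridError("feature mask contains no feature cells")
    cell = feature_mask.spec.cell_size
    dist = ndimage.distance_transform_edt(~features, sampling=cell)
    return GridRaster(feature_mask.spec, dist, feature_mask.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Point extraction


def extract_at_points(
    stack: CovariateStack, points: Sequence[tuple[float, float]] | np.ndarray
) -> pd.DataFrame:
    """Covariate values of the cell containing each point.

    Returns one row per point with one column per covariate plus a boolean
    ``valid`` column; points outside the extent or in stack-invalid cells are
    flagged invalid (their covariate values are NaN).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise GridError("empty point list")
    pts = pts.reshape(-1, 2)
    row, col, inside = stack.spec.cell_index(pts[:, 0], pts[:, 1])
    stack_ok = stack.valid_mask()
    valid = inside.copy()
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    valid &= stack_ok[r, c]
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("extract_at_points: %d of %d points outside extent or in nodata cells",
                       n_bad, len(pts))
    data = {}
    for name, layer in zip(stack.names, stack.layers):
        vals = layer.values[r, c]
        data[name] = np.where(valid, vals, np.nan)
    out = pd.DataFrame(data)
    out["valid"] = valid
    return out
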