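"""Inverse-distance-weighting interpolation and raster surfaces.

Estimates at unsampled locations are the classical Shepard weighted mean

    z_j = sum_i(z_i / d_ij^n) / sum_i(1 / d_ij^n)

with a user-chosen power ``n`` (default 2) over either all sample points
or the k nearest.  IDW is an exact interpolator: a target coinciding
with a sample returns that sample's value.  Distances are planar
Euclidean after a local equirectangular projection of geographic
coordinates — adequate for a river reach of ~100 km, and rejected-input
checks refuse latitude spans over 5 degrees where that approximation
degrades.

Gridded surfaces are stored row-major north-up and written as Esri
ASCII grids (.asc) with NODATA -9999; a GeoTIFF is written additionally
only if rasterio happens to be importable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0
NODATA = -9999.0


@dataclass(frozen=True)
class IdwConfig:
    """Interpolation settings: power n > 0 and neighborhood (None = all)."""

    power: float = 2.0
    k_nearest: int | None = None

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError("IDW power must be > 0")
        if self.k_nearest is not None and self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")


@dataclass
class RasterSurface:
    """Gridded estimates over the corridor, row 0 = northernmost row."""

    origin_x: float  # x of the lower-left corner, metres
    origin_y: float  # y of the lower-left corner, metres
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), NaN where masked
    parameter: str = ""
    season: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, same shape as values."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys_bottom_up = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        ys = ys_bottom_up[::-1]  # row 0 is the top row
        return np.meshgrid(xs, ys)


def merge_duplicates(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average z over exactly coincident sample coordinates.

    Deterministic and order-independent: unique coordinates are sorted
    lexicographically.
    """
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    uniq, inverse = np.unique(xy, axis=0, return_inverse=True)
    if len(uniq) == len(xy):
        order = np.lexsort((xy[:, 1], xy[:, 0]))
        return xy[order], z[order]
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, z)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def idw_batch(
    targets: np.ndarray,
    xy: np.ndarray,
    z: np.ndarray,
    cfg: IdwConfig = IdwConfig(),
    merge: bool = True,
) -> np.ndarray:
    """IDW estimates at an (M, 2) array of target coordinates."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    z = np.asarray(z, dtype=float)
    if len(xy) == 0:
        raise ValueError("IDW needs at least one sample point")
    if merge:
        xy, z = merge_duplicates(xy, z)
    if cfg.k_nearest is not None and cfg.k_nearest > len(xy):
        raise ValueError(
            f"k_nearest={cfg.k_nearest} exceeds the {len(xy)} sample points"
        )
    d = cdist(targets, xy)
    out = np.empty(len(targets))
    for row, dist in enumerate(d):
        zi = z
        if cfg.k_nearest is not None and cfg.k_nearest < len(dist):
            idx = np.argpartition(dist, cfg.k_nearest - 1)[: cfg.k_nearest]
            dist = dist[idx]
            zi = z[idx]
        hit = dist == 0.0
        if hit.any():
            out[row] = zi[hit][0]  # exact interpolator
            continue
        w = dist ** (-cfg.power)
        out[row] = np.dot(w, zi) / w.sum()
    return out


def idw_estimate(
    x: float,
    y: float,
    xy: np.ndarray,
    z: np.ndarray,
    cfg: IdwConfig = IdwConfig(),
) -> float:
    """IDW estimate at a single target location."""
    return float(idw_batch(np.array([[x, y]]), xy, z, cfg)[0])


def interpolate_grid(
    xy: np.ndarray,
    z: np.ndarray,
    cfg: IdwConfig = IdwConfig(),
    extent: tuple[float, float, float, float] | None = None,
    cell_size: float = 100.0,
    mask=None,
    pad: float = 1000.0,
    parameter: str = "",
    season: str = "",
) -> RasterSurface:
    """IDW surface over a regular grid of cell centres.

    ``extent`` is (xmin, xmax, ymin, ymax) in metres; the default is the
    sample bounding box padded by ``pad`` (1 km).  ``mask`` is an
    optional shapely polygon (the river corridor); cells whose centre
    falls outside it hold NODATA.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    z = np.asarray(z, dtype=float)
    if len(xy) == 0:
        raise ValueError("IDW needs at least one sample point")
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if extent is None:
        xmin, ymin = xy.min(axis=0) - pad
        xmax, ymax = xy.max(axis=0) + pad
    else:
        xmin, xmax, ymin, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent: need xmax > xmin and ymax > ymin")
    n_cols = max(1, int(math.ceil((xmax - xmin) / cell_size)))
    n_rows = max(1, int(math.ceil((ymax - ymin) / cell_size)))
    surface = RasterSurface(
        origin_x=xmin,
        origin_y=ymin,
        cell_size=cell_size,
        values=np.full((n_rows, n_cols), np.nan),
        parameter=parameter,
        season=season,
    )
    cx, cy = surface.cell_centers()
    keep = np.ones(cx.shape, dtype=bool)
    if mask is not None:
        import shapely

        keep = shapely.contains_xy(mask, cx.ravel(), cy.ravel()).reshape(cx.shape)
        if not keep.any():
            log.warning("WARN corridor mask is disjoint from the grid extent: "
                        "surface is all NODATA")
    targets = np.column_stack([cx[keep], cy[keep]])
    if len(targets):
        surface.values[keep] = idw_batch(targets, xy, z, cfg)
    return surface


# ---------------------------------------------------------------------------
# Geographic coordinates -> planar metres


def project_coords(
    lons: np.ndarray,
    lats: np.ndarray,
    origin: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection to planar metres.

    x = R * dlon * cos(mean latitude), y = R * dlat, about ``origin``
    (default: mean of the input coordinates).  Refuses latitude spans
    over 5 degrees, where the flat-earth error grows too large; supply
    already-projected coordinates instead.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lats.size and (lats.max() - lats.min()) > 5.0:
        raise ValueError(
            "latitude span exceeds 5 degrees; the local equirectangular "
            "projection is inaccurate — supply projected coordinates"
        )
    if origin is None:
        origin = (float(lons.mean()), float(lats.mean()))
    lon0, lat0 = origin
    x = EARTH_RADIUS_M * np.radians(lons - lon0) * math.cos(math.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lats - lat0)
    return x, y


def to_geographic(
    x: np.ndarray,
    y: np.ndarray,
    origin: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_coords` about the same origin."""
    lon0, lat0 = origin
    lons = lon0 + np.degrees(
        np.asarray(x, dtype=float) / (EARTH_RADIUS_M * math.cos(math.radians(lat0)))
    )
    lats = lat0 + np.degrees(np.asarray(y, dtype=float) / EARTH_RADIUS_M)
    return lons, lats


# ---------------------------------------------------------------------------
# Raster I/O (Esri ASCII grid)


def write_raster(surface: RasterSurface, path: str | Path) -> None:
    """Write an Esri ASCII grid; add a GeoTIFF when rasterio is available.

    Header order is fixed (NCOLS, NROWS, XLLCORNER, YLLCORNER, CELLSIZE,
    NODATA_VALUE); masked cells are written as -9999.
    """
    path = Path(path)
    vals = np.where(np.isnan(surface.values), NODATA, surface.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"NCOLS {surface.n_cols}\n")
        fh.write(f"NROWS {surface.n_rows}\n")
        fh.write(f"XLLCORNER {surface.origin_x:.6f}\n")
        fh.write(f"YLLCORNER {surface.origin_y:.6f}\n")
        fh.write(f"CELLSIZE {surface.cell_size:.6f}\n")
        fh.write(f"NODATA_VALUE {NODATA:.0f}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    try:  # optional georeferenced copy
        import rasterio
        from rasterio.transform import from_origin
    except ImportError:
        return
    transform = from_origin(
        surface.origin_x,
        surface.origin_y + surface.n_rows * surface.cell_size,
        surface.cell_size,
        surface.cell_size,
    )
    with rasterio.open(
        path.with_suffix(".tif"),
        "w",
        driver="GTiff",
        height=surface.n_rows,
        width=surface.n_cols,
        count=1,
        dtype="float64",
        nodata=NODATA,
        transform=transform,
    ) as dst:
        dst.write(vals, 1)


def read_raster(path: str | Path) -> RasterSurface:
    """Read an Esri ASCII grid written by :func:`write_raster`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].upper() in {
                "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE",
                "NODATA_VALUE",
            }:
                header[parts[0].upper()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    nodata = header.get("NODATA_VALUE", NODATA)
    values[values == nodata] = np.nan
    surface = RasterSurface(
        origin_x=header["XLLCORNER"],
        origin_y=header["YLLCORNER"],
        cell_size=header["CELLSIZE"],
        values=values,
    )
    if surface.n_cols != int(header["NCOLS"]) or surface.n_rows != int(header["NROWS"]):
        raise ValueError(f"{path}: grid dimensions disagree with header")
    return surface
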