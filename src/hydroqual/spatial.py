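"""Inverse-distance-weighted interpolation onto planar rasters.

Plain planar coordinates (no CRS handling); grids are written as ESRI ASCII
rasters so any GIS can consume them.  The interpolator uses all sample
points with weights d^-p (default power p = 2) and returns the sample value
exactly when a query coincides with a data point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Grid",
    "idw",
    "rasterize",
    "classify_grid",
    "write_ascii_grid",
    "read_ascii_grid",
    "grid_to_class_csv",
]

NODATA: float = -9999.0
#: Distance below which a query is treated as coinciding with a data point.
COINCIDENCE_EPS: float = 1e-9


@dataclass
class Grid:
    """Planar raster with lower-left origin and square cells.

    ``values`` is (n_rows, n_cols) stored top row first (north-up), matching
    the ESRI ASCII layout.  ``nodata`` cells are never valid values.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, same shape as ``values`` (row 0 = top)."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata


def idw(
    points: Sequence[Sequence[float]] | np.ndarray,
    query: Sequence[float],
    power: float = 2.0,
    eps: float = COINCIDENCE_EPS,
) -> float:
    """IDW estimate at one query location from (x, y, z) sample points.

    z* = sum(z_i * d_i^-p) / sum(d_i^-p) over all points; a query within
    ``eps`` of a sample point returns that sample's value exactly, making
    the surface an exact interpolator for any p > 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 3:
        raise ValueError("points must be a non-empty (n, 3) array of x, y, z")
    if power <= 0:
        raise ValueError("power must be > 0")
    d = np.hypot(pts[:, 0] - query[0], pts[:, 1] - query[1])
    hit = d < eps
    if hit.any():
        return float(pts[hit, 2][0])
    w = d ** (-power)
    return float((w * pts[:, 2]).sum() / w.sum())


def rasterize(
    points: Sequence[Sequence[float]] | np.ndarray,
    bbox: tuple[float, float, float, float],
    cell: float,
    power: float = 2.0,
    eps: float = COINCIDENCE_EPS,
) -> Grid:
    """Evaluate the IDW surface at every cell center of a regular grid.

    ``bbox`` is (xmin, ymin, xmax, ymax); rows/cols are chosen to cover it.
    Deterministic for fixed inputs; the output is a convex combination of
    the data values everywhere.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 3:
        raise ValueError("points must be a non-empty (n, 3) array of x, y, z")
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding box")
    if cell <= 0:
        raise ValueError("cell size must be > 0")
    n_cols = max(1, int(np.ceil((xmax - xmin) / cell)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell)))
    grid = Grid(x0=xmin, y0=ymin, cell=cell, values=np.zeros((n_rows, n_cols)))
    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    d = cdist(centers, pts[:, :2])
    out = np.empty(len(centers))
    hits = d < eps
    any_hit = hits.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    ok = ~any_hit
    out[ok] = (w[ok] @ pts[:, 2]) / w[ok].sum(axis=1)
    for i in np.nonzero(any_hit)[0]:
        out[i] = pts[np.argmax(hits[i]), 2]
    grid.values = out.reshape(n_rows, n_cols)
    return grid


def classify_grid(
    grid: Grid, thresholds: Sequence[float], labels: Sequence[str] | None = None
) -> Grid:
    """Integer class raster with left-closed bins at ``thresholds``.

    A cell with value v gets class k such that thresholds[k-1] <= v <
    thresholds[k] — the same boundary convention as the EWQI ranks and HI
    categories.  Nodata cells stay nodata.
    """
    thr = np.asarray(thresholds, dtype=float)
    if len(thr) == 0 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    if labels is not None and len(labels) != len(thr) + 1:
        raise ValueError("need one label per class (len(thresholds) + 1)")
    classes = np.digitize(grid.values, thr, right=False).astype(float)
    classes[~grid.valid_mask()] = grid.nodata
    return Grid(x0=grid.x0, y0=grid.y0, cell=grid.cell, values=classes, nodata=grid.nodata)


def write_ascii_grid(grid: Grid, path: str | Path, fmt: str = "%.6f") -> None:
    """Write the grid as an ESRI ASCII raster (.asc)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0:.6f}\n"
        f"yllcorner {grid.y0:.6f}\n"
        f"cellsize {grid.cell:.6f}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in grid.values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().strip().splitlines()
    meta = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.array([[float(v) for v in line.split()] for line in lines[i:]])
    if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    return Grid(
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        cell=meta["cellsize"],
        values=values,
        nodata=meta.get("nodata_value", NODATA),
    )


def grid_to_class_csv(grid: Grid, path: str | Path) -> None:
    """Write a classified grid as (row, col, class) CSV, skipping nodata."""
    with open(path, "w") as fh:
        fh.write("row,col,class\n")
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                v = grid.values[r, c]
                if v != grid.nodata:
                    fh.write(f"{r},{c},{int(v)}\n")
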