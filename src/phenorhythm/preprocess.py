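"""Preprocessing chain: clipping, statistical outlier removal, DTM-based
height normalization, and planting-grid plant clustering.

The intended order is clip -> remove_outliers -> normalize_height ->
cluster_plants.  Clipping and outlier removal never alter coordinates;
normalization alters only z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .cloud import UNASSIGNED, PointCloud

__all__ = [
    "GridDTM",
    "clip_box",
    "remove_outliers",
    "build_dtm",
    "normalize_height",
    "cluster_plants",
]


def clip_box(cloud: PointCloud, xmin: float, xmax: float, ymin: float, ymax: float) -> PointCloud:
    """Keep exactly the points with x in [xmin, xmax] and y in [ymin, ymax]."""
    if xmin >= xmax or ymin >= ymax:
        raise ValueError("degenerate clip box")
    m = (cloud.x >= xmin) & (cloud.x <= xmax) & (cloud.y >= ymin) & (cloud.y <= ymax)
    return cloud.select(m)


def remove_outliers(cloud: PointCloud, k_neighbors: int = 20, n_sigma: float = 3.0) -> PointCloud:
    """Statistical outlier removal.

    Each point's mean distance to its ``k_neighbors`` nearest neighbors is
    computed; points whose mean distance exceeds the global mean plus
    ``n_sigma`` standard deviations are dropped.  Point order is preserved.
    """
    n = len(cloud)
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} points, got {n}")
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k_neighbors + 1)  # first neighbor is the point itself
    mean_dist = dist[:, 1:].mean(axis=1)
    threshold = mean_dist.mean() + n_sigma * mean_dist.std()
    return cloud.select(mean_dist <= threshold)


@dataclass
class GridDTM:
    """Gridded ground model: per-cell elevation plus bilinear evaluation.

    ``origin`` is the lower-left corner of cell (0, 0); ``elevation[i, j]``
    is the ground height of the cell with x-index i and y-index j.
    """

    cell_size: float
    elevation: np.ndarray
    origin: Tuple[float, float]

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear ground elevation at horizontal positions ``xy`` (N x 2).

        Queries outside the grid of cell centers are clamped to the border.
        """
        nx, ny = self.elevation.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        if nx == 1 and ny == 1:
            return np.full(len(xy), self.elevation[0, 0])
        q = np.column_stack(
            [np.clip(xy[:, 0], cx[0], cx[-1]), np.clip(xy[:, 1], cy[0], cy[-1])]
        )
        if nx == 1:
            return np.interp(q[:, 1], cy, self.elevation[0, :])
        if ny == 1:
            return np.interp(q[:, 0], cx, self.elevation[:, 0])
        interp = RegularGridInterpolator((cx, cy), self.elevation, method="linear")
        return interp(q)


def build_dtm(cloud: PointCloud, cell_size: float = 0.25) -> GridDTM:
    """Minimum-z grid DTM with nearest-neighbor infilling and 3x3 smoothing."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    x0, y0 = cloud.x.min(), cloud.y.min()
    ix = np.floor((cloud.x - x0) / cell_size).astype(int)
    iy = np.floor((cloud.y - y0) / cell_size).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1

    elev = np.full((nx, ny), np.inf)
    np.minimum.at(elev, (ix, iy), cloud.z)
    filled = np.isfinite(elev)
    if not filled.all():
        # nearest-neighbor infill in cell-index space
        src = np.argwhere(filled)
        dst = np.argwhere(~filled)
        tree = cKDTree(src)
        _, nn = tree.query(dst)
        elev[tuple(dst.T)] = elev[tuple(src[nn].T)]
    elev = ndimage.uniform_filter(elev, size=3, mode="nearest")
    return GridDTM(cell_size=cell_size, elevation=elev, origin=(float(x0), float(y0)))


def normalize_height(cloud: PointCloud, cell_size: float = 0.25) -> PointCloud:
    """Subtract the bilinear DTM elevation so ground returns map to ~0.

    Only z changes; x and y are untouched.
    """
    dtm = build_dtm(cloud, cell_size=cell_size)
    xyz = cloud.xyz.copy()
    xyz[:, 2] -= dtm.evaluate(xyz[:, :2])
    return PointCloud(xyz, cloud.labels, cloud.plant_ids)


def cluster_plants(
    cloud: PointCloud,
    grid_centers: Sequence[Tuple[float, float]],
    max_radius: float = 0.3,
) -> PointCloud:
    """Assign each point to its nearest planting-grid center.

    Points farther than ``max_radius`` (horizontally) from every center get
    plant id -1 (unassigned).  Equidistant points go to the center listed
    first.  The default radius is half the 0.6 m planting interval.
    """
    centers = np.asarray(grid_centers, dtype=float).reshape(-1, 2)
    if len(centers) == 0:
        raise ValueError("grid_centers must be non-empty")
    # pairwise distances; argmin returns the first (earliest-listed) minimum
    d2 = ((cloud.xyz[:, None, :2] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    ids = np.where(d2[np.arange(len(cloud)), nearest] <= max_radius**2, nearest, UNASSIGNED)
    return PointCloud(cloud.xyz, cloud.labels, ids.astype(np.int64))
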