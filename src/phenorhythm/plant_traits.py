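"""Plant-level structural traits from a normalized single-plant cloud.

Nine traits: maximum / mean / 99%-quantile height, crown size (horizontal
diameter), plant azimuth (principal horizontal axis vs. north, mod 180),
projected leaf area (PLA, grid occupancy of leaf points), convex-hull
volume, projected area index (PAI) and a three-dimensional profile index
(3DPI) describing how evenly the canopy fills its vertical extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cloud import PointCloud

__all__ = [
    "PlantTraits",
    "height_metrics",
    "crown_size",
    "plant_azimuth",
    "projected_area",
    "hull_volume",
    "pai",
    "profile_index_3d",
    "plant_traits_all",
]

DEFAULT_QUANTILES = (0.25, 0.5, 0.75, 0.9, 0.95, 0.99)


@dataclass
class PlantTraits:
    """The nine plant-level traits for one plant at one moment."""

    H_max: float
    H_mean: float
    H_99: float
    crown_size: float
    azimuth_deg: float
    PLA: float
    volume: float
    PAI: float
    threeDPI: float
    azimuth_stable: bool = True
    quantiles: Dict[float, float] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        d = {
            "H_max": self.H_max,
            "H_mean": self.H_mean,
            "H_99": self.H_99,
            "crown_size": self.crown_size,
            "azimuth_deg": self.azimuth_deg,
            "PLA": self.PLA,
            "volume": self.volume,
            "PAI": self.PAI,
            "threeDPI": self.threeDPI,
        }
        for q, v in self.quantiles.items():
            d[f"H_{int(round(q * 100)):02d}"] = v
        return d


def height_metrics(
    cloud: PointCloud, quantiles: Tuple[float, ...] = DEFAULT_QUANTILES
) -> Tuple[float, float, Dict[float, float]]:
    """(H_max, H_mean, {q: H_q}) with linearly interpolated quantiles."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    z = cloud.z
    qv = np.quantile(z, quantiles, method="linear")
    return float(z.max()), float(z.mean()), dict(zip(quantiles, map(float, qv)))


def crown_size(cloud: PointCloud) -> float:
    """Maximum pairwise horizontal distance (crown diameter).

    Computed on the 2D convex hull of the horizontal projection, falling
    back to a direct pairwise scan for tiny or degenerate clouds.
    """
    if len(cloud) < 2:
        raise ValueError("need at least 2 points")
    xy = cloud.xyz[:, :2]
    if len(xy) > 4:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass  # collinear projection: brute force below
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def plant_azimuth(cloud: PointCloud, stability_ratio: float = 1.05) -> Tuple[float, bool]:
    """Clockwise angle from north of the principal horizontal axis, mod 180.

    Returns ``(azimuth_deg, stable)``; ``stable`` is False when the two
    horizontal eigenvalues are within ``stability_ratio`` of each other
    (near-isotropic projection, direction poorly defined).
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points")
    xy = cloud.xyz[:, :2]
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0:
        raise ValueError("degenerate horizontal spread")
    v = evecs[:, 1]  # eigenvector of the largest eigenvalue
    azimuth = np.degrees(np.arctan2(v[0], v[1])) % 180.0
    stable = bool(evals[0] == 0 or evals[1] / max(evals[0], 1e-300) >= stability_ratio)
    return float(azimuth), stable


def projected_area(cloud: PointCloud, cell_size: float = 0.005) -> float:
    """Occupied-cell area of the horizontal (downward) projection, m^2."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    ij = np.floor(cloud.xyz[:, :2] / cell_size).astype(np.int64)
    n_cells = len(np.unique(ij, axis=0))
    return float(n_cells) * cell_size**2


def hull_volume(cloud: PointCloud) -> float:
    """Volume of the 3D convex hull; 0 (with a warning) when degenerate."""
    if len(cloud) < 4:
        raise ValueError("need at least 4 points")
    try:
        return float(ConvexHull(cloud.xyz).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) cloud; hull volume set to 0", stacklevel=2)
        return 0.0


def _footprint_area(cloud: PointCloud) -> float:
    xy = cloud.xyz[:, :2]
    try:
        return float(ConvexHull(xy).volume)  # 2D hull "volume" is its area
    except QhullError:
        return 0.0


def pai(cloud: PointCloud, cell_size: float = 0.005) -> float:
    """Projected area index: sum of per-leaf projected areas over the
    footprint area (2D hull of the whole plant's horizontal projection).

    Overlap between leaves counts multiply in the numerator, so PAI can
    exceed the single plant-level projected area ratio.
    """
    if cloud.labels is None:
        raise ValueError("PAI requires leaf labels")
    footprint = _footprint_area(cloud)
    if footprint <= 0:
        raise ValueError("zero horizontal footprint")
    total = 0.0
    for lab in cloud.leaf_labels():
        total += projected_area(cloud.leaf(lab), cell_size=cell_size)
    return total / footprint


def profile_index_3d(cloud: PointCloud, voxel: float = 0.02) -> float:
    """Vertical-profile fullness index in (0, 1].

    Voxelize at ``voxel``; with per-layer filled-voxel counts n_i over the
    L layers spanned by the bounding box, the index is
    sum(n_i) / (L * max(n_i)).  1 means a vertically uniform profile; a
    single dominant layer drives it toward 1/L.
    """
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    rel = cloud.xyz - cloud.xyz.min(axis=0)
    idx = np.floor(rel / voxel).astype(np.int64)
    span = cloud.xyz[:, 2].max() - cloud.xyz[:, 2].min()
    n_layers = max(int(np.ceil(span / voxel)), idx[:, 2].max() + 1, 1)
    vox = np.unique(idx, axis=0)
    counts = np.bincount(vox[:, 2], minlength=n_layers)
    return float(counts.sum() / (n_layers * counts.max()))


def plant_traits_all(
    cloud: PointCloud,
    cell_size: float = 0.005,
    voxel: float = 0.02,
    quantiles: Tuple[float, ...] = DEFAULT_QUANTILES,
) -> PlantTraits:
    """All nine plant traits from a normalized, labeled single-plant cloud.

    Heights, crown size and volume use every point; PLA and PAI use only
    leaf-labeled points (stem excluded).  A stem-only plant yields
    PLA = PAI = 0.
    """
    if cloud.labels is None:
        raise ValueError("plant_traits_all requires a labeled cloud")
    h_max, h_mean, qdict = height_metrics(cloud, quantiles=quantiles)
    h99 = qdict.get(0.99, float(np.quantile(cloud.z, 0.99)))
    azimuth, stable = plant_azimuth(cloud)
    leaf_mask = cloud.labels > 0
    if leaf_mask.any():
        leaves = cloud.select(leaf_mask)
        pla = projected_area(leaves, cell_size=cell_size)
        pai_val = pai(cloud, cell_size=cell_size)
    else:
        pla = 0.0
        pai_val = 0.0
    return PlantTraits(
        H_max=h_max,
        H_mean=h_mean,
        H_99=h99,
        crown_size=crown_size(cloud),
        azimuth_deg=azimuth,
        PLA=pla,
        volume=hull_volume(cloud),
        PAI=pai_val,
        threeDPI=profile_index_3d(cloud, voxel=voxel),
        azimuth_stable=stable,
        quantiles=qdict,
    )
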