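"""Core point-cloud container.

Coordinate convention used throughout the package: z up, +y = geographic
north, +x = east, units in meters.  Azimuths are measured clockwise from
north, i.e. ``azimuth = atan2(east, north)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PointCloud"]

UNASSIGNED = -1


@dataclass
class PointCloud:
    """N x 3 point coordinates with optional per-point labels and plant ids.

    Parameters
    ----------
    xyz
        ``(N, 3)`` float array of coordinates in meters.
    labels
        Optional ``(N,)`` integer array; 0 = stem, k >= 1 = leaf k.
    plant_ids
        Optional ``(N,)`` integer array of plant indices;
        ``-1`` marks unassigned points.
    """

    xyz: np.ndarray
    labels: Optional[np.ndarray] = None
    plant_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        n = len(self.xyz)
        for name in ("labels", "plant_ids"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have shape ({n},)")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return the sub-cloud of points where ``mask`` is true (or indexed)."""
        return PointCloud(
            self.xyz[mask],
            None if self.labels is None else self.labels[mask],
            None if self.plant_ids is None else self.plant_ids[mask],
        )

    def leaf(self, label: int) -> "PointCloud":
        """Points carrying one leaf label (requires labels)."""
        if self.labels is None:
            raise ValueError("cloud has no labels")
        return self.select(self.labels == label)

    def leaf_labels(self) -> np.ndarray:
        """Sorted distinct leaf labels (> 0) present in the cloud."""
        if self.labels is None:
            raise ValueError("cloud has no labels")
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def concat(self, other: "PointCloud") -> "PointCloud":
        def _cat(a, b):
            if a is None and b is None:
                return None
            if a is None:
                a = np.zeros(len(self), dtype=np.int64)
            if b is None:
                b = np.zeros(len(other), dtype=np.int64)
            return np.concatenate([a, b])

        return PointCloud(
            np.vstack([self.xyz, other.xyz]),
            _cat(self.labels, other.labels),
            _cat(self.plant_ids, other.plant_ids),
        )
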