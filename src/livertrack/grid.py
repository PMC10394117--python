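"""Voxel grids and displacement fields.

The shared convention for every module: patient coordinates in mm, axes
(LR, AP, SI), origin at iso-center, arrays indexed ``[i_LR, i_AP, i_SI]``,
0-based, with the voxel value located at the voxel center
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["GridSpec", "VolumetricDVF", "BoundaryDVF", "GridError"]


class GridError(ValueError):
    """Raised on grid mismatches between volumes and fields."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: world position of voxel ``i`` is origin + i*spacing."""

    origin: tuple    # (3,) mm, center of voxel (0, 0, 0)
    spacing: tuple   # (3,) mm / voxel
    shape: tuple     # (3,) voxel counts (LR, AP, SI)

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if any(s <= 0 for s in self.spacing) or any(n <= 0 for n in self.shape):
            raise GridError("spacing and shape must be positive")

    @classmethod
    def centered(cls, shape, spacing) -> "GridSpec":
        """Grid of given shape/spacing centered on the iso-center."""
        shape = tuple(int(v) for v in np.atleast_1d(shape) * np.ones(3, int))
        spacing = tuple(float(v) for v in np.atleast_1d(spacing) * np.ones(3))
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(origin, spacing, shape)

    def axes(self):
        """The three 1-D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of all voxel centers."""
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points (..., 3)."""
        p = np.asarray(points, float)
        return (p - np.array(self.origin)) / np.array(self.spacing)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def bounds(self):
        """World extent covered by voxels, edge to edge: (lo (3,), hi (3,))."""
        o = np.array(self.origin)
        s = np.array(self.spacing)
        n = np.array(self.shape)
        return o - s / 2.0, o + (n - 0.5) * s


def _sample(volume: np.ndarray, idx: np.ndarray, order=1, mode="nearest", cval=0.0):
    """Trilinear sampling at fractional voxel indices (..., 3)."""
    coords = np.moveaxis(idx, -1, 0)
    return map_coordinates(volume, coords, order=order, mode=mode, cval=cval)


@dataclass
class VolumetricDVF:
    """Voxel-grid displacement field D(x) in mm, components (LR, AP, SI).

    ``field`` has shape ``grid.shape + (3,)`` and maps prior voxel positions to
    their target positions: x_target = x + D(x).
    """

    field: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.shape != tuple(self.grid.shape) + (3,):
            raise GridError(
                f"field shape {self.field.shape} does not match grid "
                f"{self.grid.shape} + (3,)"
            )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear sample of the field at world points (..., 3) -> (..., 3)."""
        idx = self.grid.world_to_index(points)
        out = np.empty(points.shape, dtype=np.float64)
        for c in range(3):
            out[..., c] = _sample(self.field[..., c], idx)
        return out

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.field ** 2).sum(axis=-1)).max())


@dataclass
class BoundaryDVF:
    """Per-node displacement vectors d_p (mm) on a boundary mesh."""

    d: np.ndarray            # (N, 3)
    mesh_ref: object = None  # identity of the prior mesh the nodes live on

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 2 or self.d.shape[1] != 3:
            raise GridError(f"boundary DVF must be (N, 3), got {self.d.shape}")
        if not np.all(np.isfinite(self.d)):
            raise GridError("boundary DVF contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]
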