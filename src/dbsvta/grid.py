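"""Regular voxel grids in world millimetre coordinates.

All gridded quantities in this package (tissue labels, binary masks,
potential fields, eigenvalue fields) live on a :class:`VoxelGrid`:
a right-handed world frame in millimetres, voxel-center sampling and
0-based indices.  ``world(i, j, k) = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """A scalar (or integer) field sampled on a regular 3-D grid.

    Parameters
    ----------
    origin:
        World coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    spacing:
        Per-axis voxel edge length in mm; strictly positive.
    values:
        Array of shape ``(nx, ny, nz)`` holding one value per voxel.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return self.origin + index * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for world points (mm)."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) / self.spacing

    def coordinate_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays for all voxel centers."""
        x, y, z = self.axes()
        return (
            x[:, None, None],
            y[None, :, None],
            z[None, None, :],
        )

    def contains_point(self, point: np.ndarray) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))

    # -- construction -------------------------------------------------

    @classmethod
    def from_bounds(
        cls,
        low: np.ndarray,
        high: np.ndarray,
        spacing: float | np.ndarray,
        dtype=np.float64,
        fill=0,
    ) -> "VoxelGrid":
        """Grid of voxels whose centers span ``[low, high]`` inclusive."""
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        if np.any(high <= low):
            raise ValueError("high must exceed low on all axes")
        shape = np.floor((high - low) / spacing + 0.5).astype(int) + 1
        values = np.full(shape, fill, dtype=dtype)
        return cls(origin=low, spacing=spacing, values=values)

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid on the same lattice holding ``values``."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return replace(self, values=values)

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())

    def same_lattice(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    # -- I/O ----------------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        values = self.values
        if values.dtype == bool:
            values = values.astype(np.uint8)
        img = nib.Nifti1Image(values, self.affine())
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelGrid":
        img = nib.load(path)
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        spacing = np.diag(rot).copy()
        origin = aff[:3, 3].copy()
        values = np.asanyarray(img.dataobj)
        # normalize to positive spacing by flipping axes if needed
        for a in range(3):
            if spacing[a] < 0:
                values = np.flip(values, axis=a)
                origin[a] = origin[a] + spacing[a] * (values.shape[a] - 1)
                spacing[a] = -spacing[a]
        return cls(origin=origin, spacing=spacing, values=np.ascontiguousarray(values))
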