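"""Axis-aligned 3D image grids with world (mm) geometry.

The package-wide coordinate convention is right-handed world millimetres:
x = left -> right, y = anterior -> posterior, z = caudal -> cranial
(head--feet axis).  Voxel indices are 0-based and the world position of
voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)``.  Only axis-aligned
grids are supported; oblique acquisitions must be resampled upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ImageVolume:
    """A scalar 3D volume on a regular, axis-aligned grid.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.
    spacing
        Voxel spacing in mm per axis, all strictly positive.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices.

        ``index`` has shape ``(..., 3)``; the result has the same shape.
        """
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world mm coordinates."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge-to-edge world bounding box ``(low, high)`` in mm.

        The box covers the full voxel footprint, i.e. extends half a voxel
        beyond the first/last voxel centres.
        """
        low = self.origin - 0.5 * self.spacing
        high = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return low, high

    def grid_world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre world coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def sample_world(
        self, points: np.ndarray, order: int = 1, fill: float = 0.0,
        mode: str = "constant",
    ) -> np.ndarray:
        """Interpolate the volume at world mm ``points`` of shape ``(..., 3)``.

        ``order=1`` is trilinear, ``order=0`` nearest-neighbour.  With the
        default ``mode="constant"`` points outside the grid return
        ``fill``; ``mode="nearest"`` clamps to the boundary value instead.
        """
        pts = np.asarray(points, dtype=float)
        idx = self.world_to_voxel(pts)
        coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
        out = ndimage.map_coordinates(
            self.data.astype(float, copy=False),
            coords,
            order=order,
            mode=mode,
            cval=fill,
        )
        return out.reshape(pts.shape[:-1])

    # -- NIfTI I/O ---------------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine())

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "ImageVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        spacing = np.diag(rot).copy()
        origin = aff[:3, 3].copy()
        data = np.asanyarray(img.dataobj)
        # flip axes with negative step so spacing is positive
        for a in range(3):
            if spacing[a] < 0:
                data = np.flip(data, axis=a)
                origin[a] = origin[a] + spacing[a] * (data.shape[a] - 1)
                spacing[a] = -spacing[a]
        return cls(np.ascontiguousarray(data), spacing, origin)


def world_meshgrid(volume: ImageVolume) -> np.ndarray:
    """World coordinates of every voxel centre, shape ``shape + (3,)``."""
    xs, ys, zs = volume.grid_world_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)
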