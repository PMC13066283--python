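"""Voxelised image volumes with grid metadata.

An :class:`ImageVolume` is the in-memory container for every image-domain
quantity in the package: activity images, attenuation maps (1/mm), prior
weight maps (kappa), sensitivity images and solver iterates.  Values are
stored as a 2-D ``(nx, ny)`` or 3-D ``(nx, ny, nz)`` float array; the third
axis indexes trans-axial planes.  Binary region masks are plain boolean
arrays of the same shape and are *not* wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageVolume"]


@dataclass(frozen=True)
class ImageVolume:
    """A non-negative-or-signed voxel image with physical voxel sizes.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny)`` or ``(nx, ny, nz)``.  Stored as float64.
    voxel_size
        Physical voxel pitch in mm per axis, same length as ``values.ndim``.
        The first entry is the "horizontal" (in-plane) pitch used by the
        prior's neighbour-weight rule.
    """

    values: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", arr)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "voxel_size", vs)
        if arr.ndim not in (2, 3):
            raise ValueError(f"image must be 2-D or 3-D, got ndim={arr.ndim}")
        if len(vs) != arr.ndim:
            raise ValueError(
                f"voxel_size has {len(vs)} entries for a {arr.ndim}-D image"
            )
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be strictly positive: {vs}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image values must all be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return ImageVolume(values, self.voxel_size)

    def zeros_like(self) -> "ImageVolume":
        return self.with_values(np.zeros(self.shape))

    def copy(self) -> "ImageVolume":
        return self.with_values(self.values.copy())

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and self.voxel_size == other.voxel_size
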