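"""Magnitude-image and region-mask containers with NIfTI input/output.

A :class:`MagnitudeImage` is the object every estimator in this package
consumes: a nonnegative 2D or 3D intensity raster with physical voxel
dimensions and a designated depth axis (distance from the RF coil face),
which is the axis along which transceive surface-coil sensitivity decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GeometryError

__all__ = [
    "MagnitudeImage",
    "RegionMask",
    "load_nifti",
    "save_nifti",
    "load_mask",
]

MASK_ROLES = ("background", "signal", "cross_section")


def _default_axis_labels(ndim: int, depth_axis: int) -> tuple[str, ...]:
    labels = [f"ax{i}" for i in range(ndim)]
    labels[depth_axis] = "depth"
    return tuple(labels)


@dataclass(frozen=True)
class MagnitudeImage:
    """Nonnegative intensity raster with voxel geometry.

    Parameters
    ----------
    values
        2D or 3D array of magnitude intensities, all >= 0.
    voxel_size_mm
        ``(dx, dy, dz)`` voxel edge lengths in mm.  For a 2D slice the third
        entry is the slice thickness.
    depth_axis
        Index of the array axis pointing away from the coil surface.
    axis_labels
        Orientation tag per array axis; the depth axis is tagged ``"depth"``
        by default so profiles can be requested by name.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    depth_axis: int = 0
    axis_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim not in (2, 3):
            raise GeometryError(f"expected a 2D or 3D raster, got ndim={arr.ndim}")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("magnitude values must be finite and >= 0")
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise GeometryError(f"voxel sizes must be three positive lengths, got {vox}")
        if not 0 <= self.depth_axis < arr.ndim:
            raise GeometryError(f"depth_axis {self.depth_axis} out of range for ndim {arr.ndim}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "voxel_size_mm", vox)
        if self.axis_labels is None:
            object.__setattr__(
                self, "axis_labels", _default_axis_labels(arr.ndim, self.depth_axis)
            )
        elif len(self.axis_labels) != arr.ndim:
            raise GeometryError("axis_labels must match raster dimensionality")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def axis_index(self, axis: int | str) -> int:
        """Resolve an axis given either its integer index or its label."""
        if isinstance(axis, str):
            try:
                return self.axis_labels.index(axis)
            except ValueError:
                raise GeometryError(
                    f"unknown axis tag {axis!r}; known: {self.axis_labels}"
                ) from None
        if not 0 <= axis < self.ndim:
            raise GeometryError(f"axis {axis} out of range")
        return int(axis)

    def spacing_along(self, axis: int | str) -> float:
        """Physical sample spacing (mm) along an array axis."""
        ax = self.axis_index(axis)
        # for 2D rasters the in-plane axes map to (dx, dy); dz is thickness
        return self.voxel_size_mm[ax]


@dataclass(frozen=True)
class RegionMask:
    """Boolean raster congruent with a :class:`MagnitudeImage`."""

    mask: np.ndarray
    role: str = "signal"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            uniq = np.unique(m)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask raster must be boolean or 0/1 valued")
            m = m.astype(bool)
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}, got {self.role!r}")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, image: MagnitudeImage) -> None:
        if self.mask.shape != image.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match image shape {image.shape}"
            )


def load_nifti(path, depth_axis: int = 0) -> MagnitudeImage:
    """Read a magnitude volume from NIfTI, taking voxel sizes from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3:
        zooms = tuple(zooms) + (1.0,) * (3 - len(zooms))
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"NIfTI header of {path} lacks positive voxel sizes: {zooms}")
    return MagnitudeImage(np.abs(data), tuple(float(z) for z in zooms), depth_axis=depth_axis)


def save_nifti(image: MagnitudeImage | np.ndarray, path, voxel_size_mm=None) -> None:
    """Write a raster to NIfTI with a diagonal affine built from voxel sizes."""
    if isinstance(image, MagnitudeImage):
        data, vox = image.values, image.voxel_size_mm
    else:
        data = np.asarray(image, dtype=float)
        vox = tuple(voxel_size_mm) if voxel_size_mm is not None else (1.0, 1.0, 1.0)
    affine = np.diag(list(vox[: max(data.ndim, 3)]) + [1.0])[:4, :4]
    out = nib.Nifti1Image(data.astype(np.float32), affine)
    out.header.set_zooms(vox[: data.ndim])
    nib.save(out, str(path))


def load_mask(path, role: str = "signal") -> RegionMask:
    """Read a 0/1 NIfTI volume as a region mask."""
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    return RegionMask(data > 0.5, role=role)
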