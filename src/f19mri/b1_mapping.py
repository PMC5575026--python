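"""Double-angle flip-angle (B1+) mapping and depth-profile extraction.

Transceive surface coils excite with a spatially varying transmit field, so
the actual flip angle (FA) differs from the nominal one and falls off with
distance from the coil.  The double-angle method estimates the local FA
from two fully relaxed acquisitions at nominal angles alpha and 2*alpha:

    FA = acos( SI_2a / (2 * SI_a) )

using sin(2x) = 2 sin(x) cos(x); any receive-sensitivity profile multiplies
both images identically and cancels in the ratio.  Maps are additionally
normalized to a nominal 90 degrees by scaling with 90/alpha, the form in
which transmit calibration is usually reported.

Magnitude inputs fold FA > 90 deg regions (where the true signed 2*alpha
signal is negative) back through the acos branch; rasters carrying signed
values (available from the simulator) invert exactly over (0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError
from .images import MagnitudeImage

__all__ = ["FlipAngleMap", "AxisProfile", "double_angle_fa", "axis_profile"]


@dataclass(frozen=True)
class FlipAngleMap:
    """Per-voxel actual flip angle in degrees with its 90-degree-normalized form."""

    fa_deg: np.ndarray
    normalized_deg: np.ndarray
    nominal_alpha_deg: float
    valid: np.ndarray
    clipped: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    depth_axis: int = 0
    axis_labels: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.valid
        if np.any((self.fa_deg[v] < 0) | (self.fa_deg[v] > 180)):
            raise ValueError("valid flip angles must lie in [0, 180] degrees")
        if self.axis_labels is None:
            labels = [f"ax{i}" for i in range(self.fa_deg.ndim)]
            labels[self.depth_axis] = "depth"
            object.__setattr__(self, "axis_labels", tuple(labels))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fa_deg.shape

    def axis_index(self, axis) -> int:
        if isinstance(axis, str):
            try:
                return self.axis_labels.index(axis)
            except ValueError:
                raise GeometryError(
                    f"unknown axis tag {axis!r}; known: {self.axis_labels}"
                ) from None
        if not 0 <= axis < self.fa_deg.ndim:
            raise GeometryError(f"axis {axis} out of range")
        return int(axis)


@dataclass(frozen=True)
class AxisProfile:
    """1D samples of a raster quantity versus physical position along one axis."""

    positions_mm: np.ndarray
    values: np.ndarray
    source_axis: str = "depth"
    lateral_aggregation: str = "center_line"

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_mm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.shape != v.shape or p.ndim != 1:
            raise GeometryError("positions and values must be 1D arrays of equal length")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise GeometryError("profile positions must be strictly increasing")
        object.__setattr__(self, "positions_mm", p)
        object.__setattr__(self, "values", v)


def double_angle_fa(
    img_alpha: MagnitudeImage,
    img_2alpha,
    nominal_alpha_deg: float,
    signal_floor: float = 0.0,
) -> FlipAngleMap:
    """Map the actual flip angle from acquisitions at alpha and 2*alpha.

    Parameters
    ----------
    img_alpha, img_2alpha
        Congruent fully relaxed (long-TR) acquisitions at nominal angles
        alpha and 2*alpha.  ``img_2alpha`` may also be a plain ndarray
        carrying *signed* intensities, in which case angles beyond 90
        degrees are recovered without folding.
    nominal_alpha_deg
        Nominal excitation angle alpha in degrees, in (0, 180).
    signal_floor
        Voxels with ``SI_alpha`` below this magnitude are marked invalid
        (the angle is meaningless in noise-only voxels).  A practical
        choice is 5x the background sigma of ``img_alpha``.

    The intensity ratio is clipped to [-1, 1] before acos — noise can push
    it outside the domain; clipped voxels stay in the map but are flagged.
    """
    if not 0 < nominal_alpha_deg < 180:
        raise DomainError(f"nominal_alpha_deg must be in (0, 180), got {nominal_alpha_deg}")
    si1 = img_alpha.values
    if isinstance(img_2alpha, MagnitudeImage):
        if img_2alpha.shape != img_alpha.shape or img_2alpha.voxel_size_mm != img_alpha.voxel_size_mm:
            raise GeometryError("the two acquisitions must share shape and voxel geometry")
        si2 = img_2alpha.values
    else:
        si2 = np.asarray(img_2alpha, dtype=float)
        if si2.shape != si1.shape:
            raise GeometryError("the two acquisitions must share shape")

    valid = si1 > max(signal_floor, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, si2 / (2.0 * si1), np.nan)
    clipped = valid & ((ratio < -1.0) | (ratio > 1.0))
    fa = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    fa = np.where(valid, fa, np.nan)
    normalized = fa * (90.0 / nominal_alpha_deg)
    return FlipAngleMap(
        fa_deg=fa,
        normalized_deg=normalized,
        nominal_alpha_deg=float(nominal_alpha_deg),
        valid=valid,
        clipped=clipped,
        voxel_size_mm=img_alpha.voxel_size_mm,
        depth_axis=img_alpha.depth_axis,
        axis_labels=img_alpha.axis_labels,
    )


def _extract(raster, field: str | None):
    """Pull (array, voxel sizes, labels) out of the supported raster types."""
    if isinstance(raster, MagnitudeImage):
        return raster.values, raster.voxel_size_mm, raster.axis_labels, raster.axis_index
    if isinstance(raster, FlipAngleMap):
        arr = raster.normalized_deg if field == "normalized" else raster.fa_deg
        return arr, raster.voxel_size_mm, raster.axis_labels, raster.axis_index
    raise TypeError(f"unsupported raster type {type(raster).__name__}")


def axis_profile(
    raster,
    axis="depth",
    lateral_aggregation: str = "center_line",
    band_halfwidth: int = 1,
    field: str | None = None,
) -> AxisProfile:
    """1D profile of a raster along one axis versus physical position in mm.

    ``center_line`` samples the single line through the centre of the other
    axes; ``mean_band`` averages a band of ``2*band_halfwidth + 1`` lines
    around the centre (NaNs ignored), which suppresses noise at the cost of
    lateral blurring.  For flip-angle maps, ``field="normalized"`` profiles
    the 90-degree-normalized angles instead of the raw ones.
    """
    if lateral_aggregation not in ("center_line", "mean_band"):
        raise ValueError(f"unknown lateral_aggregation {lateral_aggregation!r}")
    arr, vox, labels, axis_index = _extract(raster, field)
    ax = axis_index(axis)
    spacing = vox[ax]

    moved = np.moveaxis(arr, ax, 0)  # (n_along, *lateral)
    lateral_shape = moved.shape[1:]
    if lateral_aggregation == "center_line" or not lateral_shape:
        idx = tuple(s // 2 for s in lateral_shape)
        values = moved[(slice(None),) + idx]
    else:
        sel = tuple(
            slice(max(s // 2 - band_halfwidth, 0), min(s // 2 + band_halfwidth + 1, s))
            for s in lateral_shape
        )
        band = moved[(slice(None),) + sel].reshape(moved.shape[0], -1)
        values = np.nanmean(band, axis=1)
    positions = np.arange(moved.shape[0]) * spacing
    return AxisProfile(
        positions_mm=positions,
        values=np.asarray(values, dtype=float),
        source_axis=str(labels[ax]),
        lateral_aggregation=lateral_aggregation,
    )
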