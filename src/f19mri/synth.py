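"""Synthetic phantom acquisitions for exercising the analysis pipeline.

Emulates the three bench setups used to characterize a transceive cryogenic
fluorine surface probe against a room-temperature volume resonator:

1. a uniform high-concentration cylinder (trifluoroethanol reference) for
   B1+ mapping and SNR depth profiles,
2. a row of NMR tubes holding a PFCE nanoparticle dilution series
   (25-1200 mM) for sensitivity-slope calibration,
3. a "tissue-like" field of ellipsoidal blobs.

The forward model is deliberately minimal — the analysis stages under test
consume magnitude statistics, not k-space physics.  Noise-free voxel signal:

    S = signal_per_atom * N_atoms * B1rx(depth) * sin(FA(depth)),
    FA(depth) = flip_nominal * reference_power_scale * B1tx(depth),

with B1tx = B1rx = 1 for a volume coil and exp(-depth/decay_length) for a
surface coil.  Optional T1/T2 saturation factors are available but off by
default (the bench protocols are fully relaxed).  Channel noise adds
independent zero-mean Gaussians on the real and imaginary part of each
receive channel; the recorded magnitude is the root sum of squares, which
makes the voxel law exactly Rician (1 channel) or 4-DOF noncentral chi
(2 channels).  Identical seeds give bit-identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError
from .images import MagnitudeImage
from .protocol import ScanProtocol
from .quantify import FluorineSample, VoxelGeometry, atoms_per_voxel

__all__ = [
    "CoilModel",
    "SubstanceParams",
    "Primitive",
    "PhantomSpec",
    "Phantom",
    "coil_profile",
    "make_phantom",
    "noise_free_signal",
    "true_flip_angle_deg",
    "simulate_acquisition",
    "uniform_cylinder_spec",
    "dilution_series_spec",
    "tissue_blob_spec",
    "DILUTION_SERIES_MM",
]

#: PFCE nanoparticle dilution series of the tube phantom, in mM.
DILUTION_SERIES_MM = (25.0, 50.0, 100.0, 200.0, 400.0, 600.0)


@dataclass(frozen=True)
class CoilModel:
    """Relative transmit/receive field of a volume or surface coil.

    ``surface_decay`` uses a single-parameter exponential exp(-depth/lambda)
    for both B1+ and B1-; ``reference_power_scale`` multiplies the nominal
    flip angle at the coil face (default 1.69, i.e. a nominal 90 degrees is
    over-flipped to ~152 degrees at the surface so that useful depths are
    not under-excited).
    """

    kind: str = "volume_uniform"
    decay_length_mm: float = 3.3
    reference_power_scale: float = 1.69

    def __post_init__(self) -> None:
        if self.kind not in ("volume_uniform", "surface_decay"):
            raise DomainError(f"unknown coil kind {self.kind!r}")
        if self.kind == "surface_decay" and self.decay_length_mm <= 0:
            raise DomainError("decay_length_mm must be positive for a surface coil")

    def b1_transmit(self, depth_mm):
        if self.kind == "volume_uniform":
            return np.ones_like(np.asarray(depth_mm, dtype=float))
        return np.exp(-np.asarray(depth_mm, dtype=float) / self.decay_length_mm)

    # by default the transceive surface probe receives with the same profile
    b1_receive = b1_transmit


@dataclass(frozen=True)
class SubstanceParams:
    """Relaxation times and an arbitrary-unit signal scale per 19F atom."""

    signal_per_atom: float = 1e-15
    t1_ms: float = 1000.0
    t2_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.signal_per_atom <= 0 or self.t1_ms <= 0 or self.t2_ms <= 0:
            raise DomainError("substance parameters must be positive")


@dataclass(frozen=True)
class Primitive:
    """A phantom building block on the in-plane/depth grid.

    ``kind="tube"``/``"cylinder"``: circular cross-section of ``radius_mm``
    around ``center_mm``, extended along ``axis`` (full grid extent unless
    ``length_mm`` is given).  ``kind="blob"``: an ellipsoid with
    ``semiaxes_mm``.  Coordinates are voxel-center based, in mm from the
    grid corner.
    """

    kind: str
    center_mm: tuple[float, ...]
    radius_mm: float | None = None
    semiaxes_mm: tuple[float, ...] | None = None
    axis: int = 2
    length_mm: float | None = None
    sample: FluorineSample = field(default_factory=lambda: FluorineSample(100.0))

    def __post_init__(self) -> None:
        if self.kind not in ("tube", "cylinder", "blob"):
            raise DomainError(f"unknown primitive kind {self.kind!r}")
        if self.kind in ("tube", "cylinder") and (self.radius_mm is None or self.radius_mm <= 0):
            raise DomainError("tube/cylinder primitives need a positive radius_mm")
        if self.kind == "blob" and (
            self.semiaxes_mm is None or any(s <= 0 for s in self.semiaxes_mm)
        ):
            raise DomainError("blob primitives need positive semiaxes_mm")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus a list of non-overlapping primitives."""

    shape: tuple[int, ...]
    voxel_size_mm: tuple[float, float, float]
    primitives: tuple[Primitive, ...] = ()
    depth_axis: int = 0
    spacer_mm: float = 0.75

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3) or any(s < 1 for s in self.shape):
            raise GeometryError(f"invalid grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError("voxel sizes must be positive")
        if self.spacer_mm < 0:
            raise GeometryError("spacer_mm must be >= 0")
        object.__setattr__(self, "primitives", tuple(self.primitives))

    @property
    def extent_mm(self) -> tuple[float, ...]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_mm))

    @property
    def voxel(self) -> VoxelGeometry:
        return VoxelGeometry(*self.voxel_size_mm)


@dataclass(frozen=True)
class Phantom:
    """Rasterized phantom: concentration and true atoms-per-voxel maps."""

    concentration_mM: np.ndarray
    atoms: np.ndarray
    spec: PhantomSpec

    @property
    def voxel_size_mm(self):
        return self.spec.voxel_size_mm

    @property
    def depth_axis(self):
        return self.spec.depth_axis


def _voxel_center_coords(spec: PhantomSpec) -> list[np.ndarray]:
    """Per-axis voxel-center coordinate grids in mm (index i -> (i+0.5)*dv)."""
    axes = [
        (np.arange(n) + 0.5) * dv
        for n, dv in zip(spec.shape, spec.voxel_size_mm)
    ]
    return list(np.meshgrid(*axes, indexing="ij"))


def depth_coordinate(spec: PhantomSpec) -> np.ndarray:
    """Depth from the coil face (mm) at each voxel center: spacer + position."""
    coords = _voxel_center_coords(spec)
    return spec.spacer_mm + coords[spec.depth_axis]


def _membership(prim: Primitive, spec: PhantomSpec) -> np.ndarray:
    coords = _voxel_center_coords(spec)
    ndim = len(spec.shape)
    if prim.kind in ("tube", "cylinder"):
        plane = [i for i in range(ndim) if i != prim.axis or ndim == 2]
        if ndim == 3:
            plane = [i for i in range(3) if i != prim.axis]
        if len(prim.center_mm) < len(plane):
            raise GeometryError("primitive center has too few coordinates")
        d2 = np.zeros(spec.shape)
        for c_idx, ax in enumerate(plane):
            d2 = d2 + (coords[ax] - prim.center_mm[c_idx]) ** 2
        inside = d2 <= prim.radius_mm**2
        if ndim == 3 and prim.length_mm is not None:
            ax_c = prim.center_mm[-1] if len(prim.center_mm) == 3 else spec.extent_mm[prim.axis] / 2
            inside &= np.abs(coords[prim.axis] - ax_c) <= prim.length_mm / 2
        return inside
    # ellipsoid blob
    if len(prim.center_mm) != ndim or len(prim.semiaxes_mm) != ndim:
        raise GeometryError("blob center/semiaxes must match grid dimensionality")
    q = np.zeros(spec.shape)
    for ax in range(ndim):
        q = q + ((coords[ax] - prim.center_mm[ax]) / prim.semiaxes_mm[ax]) ** 2
    return q <= 1.0


def _check_inside(prim: Primitive, spec: PhantomSpec) -> None:
    ndim = len(spec.shape)
    ext = spec.extent_mm
    if prim.kind in ("tube", "cylinder"):
        plane = [i for i in range(ndim) if i != prim.axis] if ndim == 3 else list(range(2))
        for c, ax in zip(prim.center_mm, plane):
            if c - prim.radius_mm < 0 or c + prim.radius_mm > ext[ax]:
                raise GeometryError(
                    f"primitive {prim.kind} at {prim.center_mm} (r={prim.radius_mm}) "
                    f"extends outside the grid extent {ext}"
                )
    else:
        for c, s, e in zip(prim.center_mm, prim.semiaxes_mm, ext):
            if c - s < 0 or c + s > e:
                raise GeometryError(
                    f"blob at {prim.center_mm} (semiaxes {prim.semiaxes_mm}) "
                    f"extends outside the grid extent {ext}"
                )


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom spec: voxel-center membership, no partial volume.

    Raises on overlapping primitives or primitives outside the grid.
    """
    conc = np.zeros(spec.shape)
    claimed = np.zeros(spec.shape, dtype=bool)
    for prim in spec.primitives:
        _check_inside(prim, spec)
        inside = _membership(prim, spec)
        if np.any(claimed & inside):
            raise GeometryError("phantom primitives overlap")
        claimed |= inside
        conc[inside] = prim.sample.concentration_mM
    atoms = np.zeros(spec.shape)
    for prim in spec.primitives:
        inside = _membership(prim, spec)
        atoms[inside] = atoms_per_voxel(prim.sample, spec.voxel)
    return Phantom(concentration_mM=conc, atoms=atoms, spec=spec)


def true_flip_angle_deg(
    spec: PhantomSpec, coil: CoilModel, flip_nominal_deg: float
) -> np.ndarray:
    """Ground-truth local flip angle raster (degrees)."""
    depth = depth_coordinate(spec)
    return flip_nominal_deg * coil.reference_power_scale * coil.b1_transmit(depth)


def _sequence_response(fa_rad: np.ndarray, protocol: ScanProtocol,
                       substance: SubstanceParams, include_saturation: bool) -> np.ndarray:
    """Relative sequence response at local flip angle.

    Fully relaxed (default): sin(FA) for both RARE (first-echo
    approximation, echo-train modulation not modeled) and spoiled FLASH.
    With saturation: FLASH uses the spoiled steady state
    sin(a)(1-E1)/(1-E1 cos(a)); RARE applies a (1-E1) saturation factor and
    exp(-TE/T2) echo decay.
    """
    if not include_saturation:
        return np.sin(fa_rad)
    e1 = math.exp(-protocol.tr_ms / substance.t1_ms)
    if protocol.sequence == "FLASH":
        return np.sin(fa_rad) * (1 - e1) / (1 - e1 * np.cos(fa_rad))
    return np.sin(fa_rad) * (1 - e1) * math.exp(-protocol.te_ms / substance.t2_ms)


def coil_profile(coil: CoilModel, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Relative B1+ (transmit) and B1- (receive) rasters on the phantom grid."""
    depth = depth_coordinate(spec)
    return coil.b1_transmit(depth), coil.b1_receive(depth)


def noise_free_signal(
    phantom: Phantom,
    coil: CoilModel,
    protocol: ScanProtocol,
    flip_nominal_deg: float,
    substance: SubstanceParams = SubstanceParams(),
    include_saturation: bool = False,
    signed: bool = False,
) -> np.ndarray:
    """Deterministic forward signal raster (arbitrary units).

    ``signed=True`` keeps the sign of sin(FA) (negative beyond 180 deg of
    the doubled angle), which the double-angle mapper can consume to avoid
    magnitude folding in simulations.
    """
    fa = np.radians(true_flip_angle_deg(phantom.spec, coil, flip_nominal_deg))
    _, rx = coil_profile(coil, phantom.spec)
    resp = _sequence_response(fa, protocol, substance, include_saturation)
    sig = substance.signal_per_atom * phantom.atoms * rx * resp
    return sig if signed else np.abs(sig)


def simulate_acquisition(
    phantom: Phantom,
    coil: CoilModel,
    protocol: ScanProtocol,
    flip_nominal_deg: float,
    noise_sigma: float,
    channels: int = 1,
    seed: int = 0,
    substance: SubstanceParams = SubstanceParams(),
    include_saturation: bool = False,
) -> MagnitudeImage:
    """Seeded magnitude acquisition of a phantom.

    The noise-free signal sits on the real part of channel 1; each of the
    ``channels`` receive channels adds independent Gaussian noise of std
    ``noise_sigma`` on its real and imaginary parts, and the recorded voxel
    value is the root sum of squares over all components.  ``noise_sigma=0``
    returns the noise-free raster exactly.
    """
    if channels not in (1, 2):
        raise DomainError("only 1-channel (Rician) or 2-channel (chi) acquisitions are supported")
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    sig = noise_free_signal(
        phantom, coil, protocol, flip_nominal_deg, substance, include_saturation
    )
    if noise_sigma == 0:
        mag = sig
    else:
        rng = np.random.default_rng(seed)
        comps = rng.normal(0.0, noise_sigma, size=(2 * channels,) + sig.shape)
        comps[0] += sig
        mag = np.sqrt(np.sum(comps**2, axis=0))
    return MagnitudeImage(mag, phantom.voxel_size_mm, depth_axis=phantom.depth_axis)


# ---------------------------------------------------------------------------
# Bench-setup factory specs


def uniform_cylinder_spec(
    concentration_mM: float = 2280.0,
    radius_mm: float = 7.75,
    shape: tuple[int, int] = (128, 128),
    voxel_mm: float = 0.2,
    slice_thickness_mm: float = 4.0,
    spacer_mm: float = 0.75,
    atoms_per_molecule: int = 3,
) -> PhantomSpec:
    """Uniform high-concentration reference cylinder (2D cross-section).

    Defaults approximate a 33% v/v trifluoroethanol solution (~2.28 M, three
    19F atoms per molecule) in a syringe of 15.5 mm diameter.
    """
    extent = shape[0] * voxel_mm
    center = extent / 2
    prim = Primitive(
        kind="tube",
        center_mm=(center, center),
        radius_mm=radius_mm,
        sample=FluorineSample(concentration_mM, atoms_per_molecule, label="reference"),
    )
    return PhantomSpec(
        shape=shape,
        voxel_size_mm=(voxel_mm, voxel_mm, slice_thickness_mm),
        primitives=(prim,),
        depth_axis=0,
        spacer_mm=spacer_mm,
    )


def dilution_series_spec(
    concentrations_mM=DILUTION_SERIES_MM,
    tube_radius_mm: float = 2.0,
    voxel_mm: float = 0.25,
    slice_thickness_mm: float = 1.2,
    depth_rows: int = 1,
    spacer_mm: float = 0.75,
) -> PhantomSpec:
    """Row of NMR tubes (inner diameter 4 mm) holding a PFCE dilution series.

    All tubes sit at the same depth below the coil face so that a single
    sensitivity slope applies across the series.
    """
    n = len(concentrations_mM)
    pitch = 2 * tube_radius_mm + 1.5
    width = n * pitch + 1.0
    depth_extent = 2 * tube_radius_mm + 3.0
    shape = (int(round(depth_extent / voxel_mm)), int(round(width / voxel_mm)))
    tube_depth = depth_extent / 2
    prims = []
    for i, conc in enumerate(concentrations_mM):
        prims.append(
            Primitive(
                kind="tube",
                center_mm=(tube_depth, 0.5 + pitch * i + pitch / 2),
                radius_mm=tube_radius_mm,
                sample=FluorineSample(float(conc), label=f"{conc:g} mM"),
            )
        )
    return PhantomSpec(
        shape=shape,
        voxel_size_mm=(voxel_mm, voxel_mm, slice_thickness_mm),
        primitives=tuple(prims),
        depth_axis=0,
        spacer_mm=spacer_mm,
    )


def tissue_blob_spec(
    seed: int = 0,
    n_blobs: int = 5,
    shape: tuple[int, int] = (96, 96),
    voxel_mm: float = 0.2,
    slice_thickness_mm: float = 1.2,
    concentration_range_mM: tuple[float, float] = (50.0, 400.0),
    spacer_mm: float = 0.75,
) -> PhantomSpec:
    """Tissue-like field of non-overlapping ellipsoidal blobs (seeded)."""
    rng = np.random.default_rng(seed)
    extent = (shape[0] * voxel_mm, shape[1] * voxel_mm)
    prims: list[Primitive] = []
    attempts = 0
    while len(prims) < n_blobs and attempts < 500:
        attempts += 1
        semi = tuple(rng.uniform(0.8, 2.2, size=2))
        center = tuple(
            rng.uniform(s + 0.2, e - s - 0.2) for s, e in zip(semi, extent)
        )
        clear = all(
            math.hypot(center[0] - p.center_mm[0], center[1] - p.center_mm[1])
            > max(semi) + max(p.semiaxes_mm) + 0.4
            for p in prims
        )
        if not clear:
            continue
        conc = float(rng.uniform(*concentration_range_mM))
        prims.append(
            Primitive(
                kind="blob", center_mm=center, semiaxes_mm=semi,
                sample=FluorineSample(conc, label=f"blob{len(prims)}"),
            )
        )
    return PhantomSpec(
        shape=shape,
        voxel_size_mm=(voxel_mm, voxel_mm, slice_thickness_mm),
        primitives=tuple(prims),
        depth_axis=0,
        spacer_mm=spacer_mm,
    )
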