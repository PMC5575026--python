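"""Fluorine-spins-per-voxel quantification and sensitivity calibration.

The sensitivity of a coil/sequence combination for fluorine imaging is
summarized by the proportional model

    SNR = k * N,

where N is the number of 19F atoms in a voxel and k the sensitivity slope
(SNR per atom).  N follows from dimensional analysis alone:

    N = c [mol/L] * V_voxel [L] * n_F * N_A

with c the tracer concentration, n_F the number of equivalent fluorine
atoms per molecule (20 for perfluoro-15-crown-5-ether) and N_A Avogadro's
number.  Dividing two slopes gives the SNR gain of one coil over another;
dividing an SNR cutoff by a slope gives the detection limit in atoms per
voxel.  Depth profiles of two coils are compared by their pointwise SNR
ratio: its maximum (peak gain and depth) and the depth at which the gain
first falls to 1 (crossover — beyond it the second coil is no worse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants, optimize

from .b1_mapping import AxisProfile
from .errors import DomainError, GeometryError

__all__ = [
    "VoxelGeometry",
    "FluorineSample",
    "SensitivityFit",
    "ProfileComparison",
    "atoms_per_voxel",
    "fit_sensitivity",
    "fit_power_law",
    "snr_gain",
    "detection_limit",
    "compare_profiles",
    "PFCE_ATOMS_PER_MOLECULE",
    "REPORTED_ATOM_COUNTS",
]

AVOGADRO = constants.Avogadro

#: Perfluoro-15-crown-5-ether carries 20 chemically equivalent 19F atoms.
PFCE_ATOMS_PER_MOLECULE = 20

#: Atom-per-voxel counts quoted in the original cryoprobe sensitivity study
#: for two acquisition conditions.  They exceed the dimensional formula
#: below by a consistent factor of ~4.3 (the convention behind them was not
#: stated); kept strictly as reference metadata, never used in computation.
REPORTED_ATOM_COUNTS = {
    (25.0, (0.1, 0.1, 0.4)): 5.2e15,
    (100.0, (0.1, 0.1, 1.2)): 6.2e16,
}


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel edge lengths in mm (dz is the slice thickness for 2D scans)."""

    dx_mm: float
    dy_mm: float
    dz_mm: float

    def __post_init__(self) -> None:
        if min(self.dx_mm, self.dy_mm, self.dz_mm) <= 0:
            raise DomainError("voxel dimensions must be positive")

    @property
    def volume_l(self) -> float:
        """Voxel volume in liters (1 mm^3 = 1e-6 L)."""
        return self.dx_mm * self.dy_mm * self.dz_mm * 1e-6


@dataclass(frozen=True)
class FluorineSample:
    """A fluorinated preparation: molar concentration and 19F atoms per molecule."""

    concentration_mM: float
    atoms_per_molecule: int = PFCE_ATOMS_PER_MOLECULE
    label: str = ""

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise DomainError("concentration must be >= 0")
        if self.atoms_per_molecule < 1:
            raise DomainError("atoms_per_molecule must be >= 1")


@dataclass(frozen=True)
class SensitivityFit:
    """Fitted proportional sensitivity model SNR = k * N."""

    slope_k: float
    n_points: int
    residual_spread: float  # geometric std of SNR / (k*N)
    fit_space: str = "log_proportional"

    def __post_init__(self) -> None:
        if self.slope_k <= 0:
            raise DomainError("sensitivity slope must be positive")


@dataclass(frozen=True)
class ProfileComparison:
    """Pointwise-ratio summary of two depth profiles (A relative to B)."""

    peak_gain: float
    peak_depth_mm: float
    crossover_depth_mm: float | None


def atoms_per_voxel(sample: FluorineSample, voxel: VoxelGeometry) -> float:
    """Number of 19F atoms contained in one voxel.

    N = c * 1e-3 [mol/L] * V [L] * atoms_per_molecule * N_A.  25 mM PFCE in
    a 0.1 x 0.1 x 0.4 mm^3 voxel gives 1.204e15 atoms.
    """
    moles = sample.concentration_mM * 1e-3 * voxel.volume_l
    return moles * sample.atoms_per_molecule * AVOGADRO


def fit_sensitivity(points, fit_space: str = "log_proportional") -> SensitivityFit:
    """Fit SNR = k * N to (atoms, corrected SNR) pairs.

    ``log_proportional`` (default) fixes the exponent at one and estimates
    log k as the mean of log(SNR/N) — each point contributes equally on the
    log scale, matching a straight unit-slope fit on a log-log plot that
    spans decades in N.  ``linear_origin`` is ordinary least squares through
    the origin, which weights the largest N most heavily.
    """
    pts = [(float(n), float(s)) for n, s in points]
    if not pts:
        raise DomainError("need at least one calibration point")
    n = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    if np.any(n <= 0) or np.any(s <= 0):
        raise DomainError("atom counts and SNR values must be positive for fitting")
    if fit_space == "log_proportional":
        logk = np.mean(np.log(s) - np.log(n))
        k = float(np.exp(logk))
    elif fit_space == "linear_origin":
        k = float(np.dot(n, s) / np.dot(n, n))
    else:
        raise ValueError(f"unknown fit_space {fit_space!r}")
    resid = np.log(s / (k * n))
    spread = float(np.exp(np.std(resid))) if len(pts) > 1 else 1.0
    return SensitivityFit(slope_k=k, n_points=len(pts), residual_spread=spread, fit_space=fit_space)


def fit_power_law(points) -> tuple[float, float]:
    """Diagnostic free-exponent fit SNR = A * N**p (log-log least squares).

    Useful for checking that a calibration series is actually proportional
    (p close to 1); the proportional slope from :func:`fit_sensitivity`,
    not this fit, feeds gain and detection-limit computation.
    """
    pts = [(float(n), float(s)) for n, s in points]
    if len(pts) < 2:
        raise DomainError("need at least two points for a power-law fit")
    n = np.log([p[0] for p in pts])
    s = np.log([p[1] for p in pts])
    p, loga = np.polyfit(n, s, 1)
    return float(np.exp(loga)), float(p)


def snr_gain(fit_a: SensitivityFit, fit_b: SensitivityFit) -> float:
    """SNR gain of coil A over coil B: the ratio of sensitivity slopes."""
    if fit_a.slope_k <= 0 or fit_b.slope_k <= 0:
        raise DomainError("both slopes must be positive")
    return fit_a.slope_k / fit_b.slope_k


def detection_limit(fit: SensitivityFit, snr_cutoff: float = 2.0) -> float:
    """Atoms per voxel needed to reach the SNR cutoff: N_min = cutoff / k."""
    if snr_cutoff < 0:
        raise DomainError("snr_cutoff must be >= 0")
    return snr_cutoff / fit.slope_k


def compare_profiles(profile_a: AxisProfile, profile_b: AxisProfile) -> ProfileComparison:
    """Peak gain, its depth, and the gain-1 crossover of two depth profiles.

    The profiles are resampled onto the finer of the two position grids over
    their overlapping range (linear interpolation); the ratio A/B is
    evaluated where B > 0.  The crossover is the first depth at which the
    ratio, coming from above, reaches 1 (linearly interpolated between
    samples); it is absent when the ratio never comes down to 1.
    """
    lo = max(profile_a.positions_mm[0], profile_b.positions_mm[0])
    hi = min(profile_a.positions_mm[-1], profile_b.positions_mm[-1])
    if lo >= hi:
        raise GeometryError("profiles have no overlapping position range")

    def spacing(p):
        return np.median(np.diff(p.positions_mm))

    finer = profile_a if spacing(profile_a) <= spacing(profile_b) else profile_b
    grid = finer.positions_mm
    grid = grid[(grid >= lo) & (grid <= hi)]
    a = np.interp(grid, profile_a.positions_mm, profile_a.values)
    b = np.interp(grid, profile_b.positions_mm, profile_b.values)
    ok = b > 0
    if not np.any(ok):
        raise DomainError("reference profile is nonpositive over the whole overlap")
    grid, a, b = grid[ok], a[ok], b[ok]
    ratio = a / b

    i_peak = int(np.argmax(ratio))
    peak_gain = float(ratio[i_peak])
    peak_depth = float(grid[i_peak])

    crossover = None
    if math.isclose(ratio[0], 1.0, rel_tol=0.0, abs_tol=1e-12):
        crossover = float(grid[0])
    else:
        for i in range(1, len(ratio)):
            if ratio[i - 1] > 1.0 >= ratio[i]:
                # linear interpolation of the downward crossing
                t = (ratio[i - 1] - 1.0) / (ratio[i - 1] - ratio[i])
                crossover = float(grid[i - 1] + t * (grid[i] - grid[i - 1]))
                break
    return ProfileComparison(peak_gain=peak_gain, peak_depth_mm=peak_depth, crossover_depth_mm=crossover)
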