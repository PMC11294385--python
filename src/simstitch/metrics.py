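"""Mobility metrics: CCS conversion, ΔCCS%, resolution, separation classes.

The separation capacity of a trapped ion mobility (TIMS) device is expressed
here with two figures of merit:

* ``ΔCCS% = 2·(CCS_B − CCS_A)/(CCS_B + CCS_A)·100`` — the percent collision
  cross-section difference between two peaks relative to their mean.  On a
  high-resolution TIMS instrument, |ΔCCS%| > 1.0 gives baseline separation,
  0.5–1.0 only partial separation, and < 0.5 effectively none.
* resolution ``R = apex/FWHM`` evaluated on the measured 1/K0 axis.

CCS values are obtained from reduced mobilities through the single-field
Mason–Schamp relation with nitrogen as drift gas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants, stats

from .errors import DomainError

__all__ = [
    "N2_MASS",
    "CalibrationModel",
    "SeparationResult",
    "delta_ccs_percent",
    "resolution",
    "classify_separation",
    "ccs_from_reduced_mobility",
    "inv_k0_from_ccs",
    "fit_calibration",
]

N2_MASS = 28.00615  # Da, monoisotopic N2 drift gas

_E = constants.elementary_charge            # C
_KB = constants.Boltzmann                   # J/K
_U = constants.atomic_mass                  # kg
_ME_DA = constants.electron_mass / constants.atomic_mass
_N0 = constants.atm / (_KB * 273.15)        # Loschmidt number density, m^-3

# classification thresholds on |ΔCCS%|; ties assigned upward
BASELINE_THRESHOLD = 1.0
PARTIAL_THRESHOLD = 0.5


@dataclass
class CalibrationModel:
    """Linear map from the instrument elution coordinate to 1/K0.

    TIMS instruments are calibrated daily against reference ions of known
    reduced mobility; in linear mode ``1/K0 = slope·x + intercept`` where x is
    the measured elution coordinate.  The model also carries the drift-gas
    parameters needed for the Mason–Schamp conversion: ``gas_mass`` (Da,
    default N2) and ``temperature`` (K, default 305 — a typical TIMS cell
    operating temperature; CCS scales with √T, so it is configurable).
    """

    slope: float
    intercept: float = 0.0
    gas_mass: float = N2_MASS
    temperature: float = 305.0
    charge_default: int = 1

    def __post_init__(self):
        if self.slope == 0:
            raise DomainError("calibration slope must be nonzero")
        if self.gas_mass <= 0 or self.temperature <= 0:
            raise DomainError("gas mass and temperature must be positive")

    def to_inv_k0(self, measured):
        """Map a measured elution coordinate to 1/K0 (V·s·cm⁻²)."""
        return self.slope * np.asarray(measured, dtype=float) + self.intercept

    def from_inv_k0(self, inv_k0):
        """Inverse map: 1/K0 back to the measured coordinate."""
        return (np.asarray(inv_k0, dtype=float) - self.intercept) / self.slope


#: convenience model for data already expressed on the 1/K0 axis
IDENTITY_CALIBRATION = CalibrationModel(slope=1.0, intercept=0.0)


def delta_ccs_percent(ccs_a: float, ccs_b: float) -> float:
    """Signed percent CCS difference, ``2·(B − A)/(B + A)·100``.

    Antisymmetric under swapping A and B and invariant under a common scale
    factor.  Callers classify on the absolute value; the sign carries the
    elution-order information.
    """
    a = np.asarray(ccs_a, dtype=float)
    b = np.asarray(ccs_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("CCS values must be positive")
    out = 2.0 * (b - a) / (b + a) * 100.0
    return float(out) if out.ndim == 0 else out


def resolution(apex_inv_k0: float, fwhm_inv_k0: float) -> float:
    """Mobility resolving power, apex/FWHM on the 1/K0 axis."""
    if apex_inv_k0 <= 0:
        raise DomainError("peak apex must be positive")
    if fwhm_inv_k0 <= 0:
        raise DomainError("FWHM must be positive (zero width gives undefined R)")
    return apex_inv_k0 / fwhm_inv_k0


def classify_separation(abs_delta_ccs_pct: float, both_detected: bool = True) -> str:
    """Classify an enantioseparation from |ΔCCS%|.

    ≥ 1.0 → ``baseline``; 0.5 ≤ |ΔCCS%| < 1.0 → ``partial``; < 0.5 → ``none``.
    Ties sit exactly on the published thresholds and are assigned upward.
    When one or both peaks are missing, ``not_detected`` is returned instead.
    """
    if abs_delta_ccs_pct < 0:
        raise DomainError("classification takes the absolute ΔCCS%")
    if not both_detected:
        return "not_detected"
    if abs_delta_ccs_pct >= BASELINE_THRESHOLD:
        return "baseline"
    if abs_delta_ccs_pct >= PARTIAL_THRESHOLD:
        return "partial"
    return "none"


def _ccs_per_inv_k0(mz: float, z: int, gas_mass: float, temperature: float) -> float:
    """Mason–Schamp coefficient: CCS (Å²) per unit 1/K0 (V·s·cm⁻²)."""
    if mz <= 0:
        raise DomainError("m/z must be positive")
    if z < 1:
        raise DomainError("charge must be >= 1")
    if gas_mass <= 0 or temperature <= 0:
        raise DomainError("gas mass and temperature must be positive")
    m_ion = (z * mz - z * _ME_DA) * _U
    m_gas = gas_mass * _U
    mu = m_ion * m_gas / (m_ion + m_gas)
    coeff_si = (3.0 * z * _E) / (16.0 * _N0) * math.sqrt(
        2.0 * math.pi / (mu * _KB * temperature))
    # 1/K0 in V·s·cm⁻² is 1e4 × SI; CCS in Å² is 1e20 × m².
    return coeff_si * 1e4 * 1e20


def ccs_from_reduced_mobility(inv_k0, mz: float, z: int = 1, *,
                              model: CalibrationModel | None = None,
                              gas_mass: float | None = None,
                              temperature: float | None = None):
    """Collision cross section (Å²) from inverse reduced mobility.

    Single-field Mason–Schamp relation::

        CCS = (3·z·e / 16·N0) · sqrt(2π / (μ·kB·T)) · (1/K0)

    with μ the ion/drift-gas reduced mass (ion mass taken as z·(mz − m_e))
    and N0 the gas number density at 273.15 K and 1013.25 hPa.  Linear in
    1/K0 at fixed m/z and charge.
    """
    gas = gas_mass if gas_mass is not None else (model.gas_mass if model else N2_MASS)
    temp = temperature if temperature is not None else (model.temperature if model else 305.0)
    x = np.asarray(inv_k0, dtype=float)
    if np.any(x <= 0):
        raise DomainError("1/K0 must be positive")
    out = _ccs_per_inv_k0(mz, z, gas, temp) * x
    return float(out) if out.ndim == 0 else out


def inv_k0_from_ccs(ccs, mz: float, z: int = 1, *,
                    model: CalibrationModel | None = None,
                    gas_mass: float | None = None,
                    temperature: float | None = None):
    """Inverse of :func:`ccs_from_reduced_mobility` (exact, the map is linear)."""
    gas = gas_mass if gas_mass is not None else (model.gas_mass if model else N2_MASS)
    temp = temperature if temperature is not None else (model.temperature if model else 305.0)
    c = np.asarray(ccs, dtype=float)
    if np.any(c <= 0):
        raise DomainError("CCS must be positive")
    out = c / _ccs_per_inv_k0(mz, z, gas, temp)
    return float(out) if out.ndim == 0 else out


def fit_calibration(pairs: Sequence[tuple[float, float]], *,
                    gas_mass: float = N2_MASS, temperature: float = 305.0,
                    charge_default: int = 1) -> CalibrationModel:
    """Ordinary least-squares line through (measured coordinate, 1/K0) pairs.

    Mirrors the instrument's daily "linear mode" mobility calibration against
    a tuning-mix standard.  Requires at least two points with distinct
    abscissae; exactly collinear input is recovered to machine precision.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DomainError("calibration needs at least two (measured, 1/K0) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DomainError("calibration abscissae are all identical")
    fit = stats.linregress(x, y)
    return CalibrationModel(slope=float(fit.slope), intercept=float(fit.intercept),
                            gas_mass=gas_mass, temperature=temperature,
                            charge_default=charge_default)


@dataclass
class SeparationResult:
    """Chiral-separation verdict for one complex channel.

    ``ccs_A`` is the first-eluting (lower 1/K0) peak.  ``delta_ccs_pct`` is
    signed: positive when the L-assigned peak elutes first, negative when D
    does — mirroring the observation that enantiomer elution order is not
    systematic.  ``classification`` is one of baseline / partial / none /
    not_detected / single_signal.
    """

    complex_label: str
    ccs_A: float | None = None
    ccs_B: float | None = None
    delta_ccs_pct: float | None = None
    resolution_A: float | None = None
    resolution_B: float | None = None
    classification: str = "not_detected"
    annotations: tuple[str, ...] = ()

    def __post_init__(self):
        if None not in (self.ccs_A, self.ccs_B, self.delta_ccs_pct):
            expected = abs(delta_ccs_percent(self.ccs_A, self.ccs_B))
            if not math.isclose(abs(self.delta_ccs_pct), expected,
                                rel_tol=1e-9, abs_tol=1e-9):
                raise DomainError(
                    f"{self.complex_label}: ΔCCS% {self.delta_ccs_pct} inconsistent "
                    f"with CCS pair ({self.ccs_A}, {self.ccs_B})"
                )
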