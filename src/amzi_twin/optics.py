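"""Interferometer physics and performance figures of an aMZI refractometric sensor.

An asymmetric Mach-Zehnder interferometer (aMZI) splits guided light into a
sensing arm and a reference arm of unequal optical path length.  The exposed
sensing window sees the analyte through the evanescent field of the guided
mode: binding raises the local refractive index, raises the effective index
``n_eff`` of the mode, and shifts the wavelength-periodic transmission fringes.

This module implements the closed-form relations of that physics:

* the two-beam transfer function ``T = (1 + cos(dphi)) / 2``,
* group index ``n_g = n_eff - lambda0 * dn_eff/dlambda``,
* free spectral range ``FSR = lambda0**2 / (n_g * L_asym)``,
* fringe sensitivity ``S = L * FSR / lambda_res``,
* the three-component noise budget ``3*sigma = 3*sqrt(sa**2 + ss**2 + st**2)``,
* limit of detection ``LoD = R / S``.

Unit discipline (applied throughout the package): wavelengths in nm, fringe
shifts and FSR in pm, arm lengths in mm, index changes in RIU (refractive
index units, dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModeDispersion",
    "AMZIDesign",
    "NoiseBudget",
    "PerformanceFigure",
    "transfer_phase",
    "transfer_wavelength",
    "group_index",
    "free_spectral_range",
    "sensitivity",
    "measurement_noise_3sigma",
    "limit_of_detection",
    "phase_to_wavelength_shift",
    "wavelength_shift_to_phase",
    "optical_path_difference",
]

NM_PER_MM = 1.0e6
PM_PER_NM = 1.0e3


class OpticsDomainError(ValueError):
    """Raised when a physical quantity is outside its valid domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeDispersion:
    """First-order dispersion of the guided mode at a reference wavelength.

    Parameters
    ----------
    n_eff:
        Effective (phase) index of the guided mode at ``lambda0``.  Must
        exceed 1 for a guided mode in a dielectric stack.
    dneff_dlambda:
        Wavelength derivative of the effective index, per nm.  Normal
        waveguide dispersion is negative, which makes the group index
        exceed the effective index.
    lambda0:
        Reference wavelength in nm.
    """

    n_eff: float
    dneff_dlambda: float
    lambda0: float

    def __post_init__(self) -> None:
        if not (self.n_eff > 1.0):
            raise OpticsDomainError(f"n_eff must exceed 1, got {self.n_eff}")
        if not (self.lambda0 > 0.0):
            raise OpticsDomainError(f"lambda0 must be positive, got {self.lambda0}")

    @property
    def group_index(self) -> float:
        """Group index ``n_g = n_eff - lambda0 * dn_eff/dlambda``."""
        return group_index(self)


@dataclass(frozen=True)
class AMZIDesign:
    """Geometry and operating point of one asymmetric interferometer.

    Parameters
    ----------
    arm_length_L:
        Physical length of each spiral sensing arm in mm; enters the
        fringe sensitivity ``S = L * FSR / lambda_res``.
    asym_length:
        Effective optical asymmetry length in mm; sets the free spectral
        range ``FSR = lambda0**2 / (n_g * asym_length)``.  Kept separate
        from ``arm_length_L`` because a long sensing arm with a short
        asymmetry is exactly what makes the design sensitive.
    lambda_res:
        Resonance operating wavelength in nm.
    sensitivity_override:
        Optional sensitivity in nm/RIU.  When set it supersedes the
        closed-form fringe sensitivity; used to pin the bulk-cladding
        sensitivity (which folds in the evanescent-field confinement of
        the mode and is therefore smaller than the effective-index
        sensitivity by an unknown confinement factor).
    """

    arm_length_L: float
    asym_length: float
    lambda_res: float
    sensitivity_override: float | None = None

    def __post_init__(self) -> None:
        for name in ("arm_length_L", "asym_length", "lambda_res"):
            if not (getattr(self, name) > 0.0):
                raise OpticsDomainError(f"{name} must be positive, got {getattr(self, name)}")
        if self.sensitivity_override is not None and not (self.sensitivity_override > 0.0):
            raise OpticsDomainError("sensitivity_override must be positive when given")

    def fsr_pm(self, mode: ModeDispersion) -> float:
        """Free spectral range in pm for the given mode dispersion."""
        return free_spectral_range(self.lambda_res, group_index(mode), self.asym_length)

    def sensitivity_nm_per_riu(self, mode: ModeDispersion) -> float:
        """Sensitivity in nm/RIU: the override when pinned, else ``L*FSR/lambda_res``."""
        if self.sensitivity_override is not None:
            return self.sensitivity_override
        return sensitivity(self.arm_length_L, self.fsr_pm(mode), self.lambda_res)


@dataclass(frozen=True)
class NoiseBudget:
    """Wavelength-equivalent measurement-noise components, each a 1-sigma in pm.

    ``sigma_ampl`` is detection amplitude noise, ``sigma_spect`` laser
    spectral (tuning) noise, ``sigma_temp`` thermal drift of the chip.  They
    compose in quadrature into the total measurement noise; the sensor
    resolution is taken as that composed 3-sigma.
    """

    sigma_ampl: float
    sigma_spect: float
    sigma_temp: float

    def __post_init__(self) -> None:
        for name in ("sigma_ampl", "sigma_spect", "sigma_temp"):
            if getattr(self, name) < 0.0:
                raise OpticsDomainError(f"{name} must be non-negative")

    @property
    def three_sigma_pm(self) -> float:
        return measurement_noise_3sigma(self)


@dataclass(frozen=True)
class PerformanceFigure:
    """Sensitivity (nm/RIU), resolution (pm) and limit of detection (RIU)."""

    sensitivity_S: float
    resolution_R: float
    lod: float

    def __post_init__(self) -> None:
        if not (self.sensitivity_S > 0.0 and self.resolution_R > 0.0 and self.lod > 0.0):
            raise OpticsDomainError("performance figures must all be positive")
        expected = limit_of_detection(self.resolution_R, self.sensitivity_S)
        if not math.isclose(self.lod, expected, rel_tol=1e-9):
            raise OpticsDomainError(
                f"lod={self.lod} inconsistent with R/S={expected} (unit-normalized)"
            )

    @classmethod
    def from_resolution(cls, resolution_R: float, sensitivity_S: float) -> "PerformanceFigure":
        return cls(
            sensitivity_S=sensitivity_S,
            resolution_R=resolution_R,
            lod=limit_of_detection(resolution_R, sensitivity_S),
        )


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------


def transfer_phase(delta_phi):
    """Two-beam interference transmission ``(1 + cos(delta_phi)) / 2``.

    Accepts scalars or arrays; output lies in [0, 1] and is 2*pi-periodic.
    Constructive interference (T = 1) at multiples of 2*pi, destructive
    (T = 0) at odd multiples of pi.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if not np.all(np.isfinite(delta_phi)):
        raise OpticsDomainError("delta_phi must be finite")
    out = 0.5 * (1.0 + np.cos(delta_phi))
    return float(out) if out.ndim == 0 else out


def transfer_wavelength(lambda_nm, opd_nm):
    """Transmission at wavelength ``lambda_nm`` for optical path difference ``opd_nm``.

    Equivalent to ``transfer_phase(2*pi*opd/lambda)`` by construction; the
    opd carries both the geometric asymmetry term ``n_eff*dL`` and the
    sensing term ``dn_eff*L``.
    """
    lambda_nm = np.asarray(lambda_nm, dtype=float)
    if not np.all(lambda_nm > 0.0):
        raise OpticsDomainError("wavelength must be positive")
    return transfer_phase(2.0 * np.pi * np.asarray(opd_nm, dtype=float) / lambda_nm)


def optical_path_difference(
    mode: ModeDispersion,
    design: AMZIDesign,
    dneff_sense: float = 0.0,
) -> float:
    """Optical path difference in nm between the two arms.

    ``opd = n_g * dL_asym + dn_eff_sense * L``: the static asymmetry uses the
    group index (which is what sets the fringe spacing of a dispersive
    interferometer) and the analyte adds ``dn_eff * L`` over the sensing
    window.  An index increase in the sensing window therefore lengthens the
    opd and red-shifts the fringes.
    """
    return (
        group_index(mode) * design.asym_length * NM_PER_MM
        + dneff_sense * design.arm_length_L * NM_PER_MM
    )


# ---------------------------------------------------------------------------
# Dispersion, FSR, sensitivity
# ---------------------------------------------------------------------------


def group_index(mode: ModeDispersion) -> float:
    """Group index ``n_g = n_eff - lambda0 * dn_eff/dlambda``."""
    return mode.n_eff - mode.lambda0 * mode.dneff_dlambda


def free_spectral_range(lambda0_nm: float, n_g: float, asym_length_mm: float) -> float:
    """Free spectral range ``lambda0**2 / (n_g * L_asym)`` in pm.

    The FSR is the wavelength spacing of successive fringe maxima near
    ``lambda0``; it is set by the arm-length asymmetry, not the full arm
    length.
    """
    if not (lambda0_nm > 0.0 and n_g > 0.0 and asym_length_mm > 0.0):
        raise OpticsDomainError("lambda0, n_g and asym_length must all be positive")
    fsr_nm = lambda0_nm**2 / (n_g * asym_length_mm * NM_PER_MM)
    return fsr_nm * PM_PER_NM


def sensitivity(arm_length_mm: float, fsr_pm: float, lambda_res_nm: float) -> float:
    """Fringe sensitivity ``S = L * FSR / lambda_res`` in nm per RIU.

    Expresses the fringe shift per unit change of the sensing-arm effective
    index.  Bulk-cladding sensitivity is smaller by the mode-confinement
    factor ``dn_eff/dn_bulk`` and is handled by pinning an override on the
    design rather than guessing that factor.
    """
    if not (arm_length_mm > 0.0 and fsr_pm > 0.0 and lambda_res_nm > 0.0):
        raise OpticsDomainError("arm length, FSR and lambda_res must all be positive")
    arm_nm = arm_length_mm * NM_PER_MM
    fsr_nm = fsr_pm / PM_PER_NM
    return arm_nm * fsr_nm / lambda_res_nm


# ---------------------------------------------------------------------------
# Noise, resolution, LoD
# ---------------------------------------------------------------------------


def measurement_noise_3sigma(budget: NoiseBudget) -> float:
    """Composed measurement noise ``3*sqrt(sa**2 + ss**2 + st**2)`` in pm."""
    return 3.0 * math.sqrt(
        budget.sigma_ampl**2 + budget.sigma_spect**2 + budget.sigma_temp**2
    )


def limit_of_detection(resolution_R_pm: float, sensitivity_S_nm_per_riu: float) -> float:
    """Limit of detection ``LoD = R / S`` in RIU.

    ``R`` in pm is converted to nm so the ratio with ``S`` in nm/RIU yields
    refractive index units directly.
    """
    if not (sensitivity_S_nm_per_riu > 0.0):
        raise OpticsDomainError("sensitivity must be positive")
    if resolution_R_pm < 0.0:
        raise OpticsDomainError("resolution must be non-negative")
    return (resolution_R_pm / PM_PER_NM) / sensitivity_S_nm_per_riu


# ---------------------------------------------------------------------------
# Phase <-> wavelength-shift conversion
# ---------------------------------------------------------------------------


def phase_to_wavelength_shift(delta_phi, fsr_pm: float):
    """Convert an interferometric phase change to a fringe shift in pm.

    One full fringe of phase (2*pi) corresponds to one FSR of wavelength
    shift: ``d_lambda = d_phi * FSR / (2*pi)``.
    """
    if not (fsr_pm > 0.0):
        raise OpticsDomainError("FSR must be positive")
    out = np.asarray(delta_phi, dtype=float) * fsr_pm / (2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def wavelength_shift_to_phase(delta_lambda_pm, fsr_pm: float):
    """Inverse of :func:`phase_to_wavelength_shift`; round-trips exactly."""
    if not (fsr_pm > 0.0):
        raise OpticsDomainError("FSR must be positive")
    out = np.asarray(delta_lambda_pm, dtype=float) * (2.0 * np.pi) / fsr_pm
    return float(out) if out.ndim == 0 else out
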