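"""Förster resonance energy transfer calculations.

The donor-acceptor spectral overlap integral is

    J = ∫ F(λ) ε(λ) λ⁴ dλ / ∫ F(λ) dλ        [M⁻¹ cm³, λ in cm]

with F the donor emission (arbitrary units; the normalization cancels any
scale) and ε the acceptor molar extinction (M⁻¹ cm⁻¹). The Förster critical
radius follows from R₀⁶ = 8.79e-25 · κ² · n⁻⁴ · Φ · J (cm⁶), and the
transfer efficiency E = R₀⁶/(R₀⁶ + r⁶) = 1 − F/F₀ links the measured
quenching at equimolar donor/acceptor to the donor-acceptor distance r.
Distances are reported in nm; Förster theory is considered reliable in the
window 0.5·R₀ < r < 1.5·R₀, which is checked and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import RunConfig, Spectrum, SpectrumKind, ValidationError

__all__ = [
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "efficiency_from_quenching",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "fret_analysis",
]

#: Förster-radius prefactor: R0^6 in cm^6 for J in M^-1 cm^3.
FORSTER_PREFACTOR = 8.79e-25
_NM_PER_CM = 1e7


@dataclass(frozen=True)
class FretResult:
    """Overlap integral J, Förster radius R0, efficiency E, distance r, the
    photophysical constants used, and the 0.5 R0 < r < 1.5 R0 validity flag."""

    J_M1cm3: float
    R0_nm: float
    E: float
    r_nm: float
    quantum_yield: float
    kappa2: float
    refractive_index: float
    window_ok: bool

    def __post_init__(self) -> None:
        if self.J_M1cm3 < 0:
            raise ValidationError("J must be >= 0")
        if self.J_M1cm3 > 0 and self.R0_nm <= 0:
            raise ValidationError("R0 must be > 0 when J > 0")
        if not (0.0 <= self.E <= 1.0):
            raise ValidationError("E must lie in [0, 1]")


def overlap_integral(donor_emission: Spectrum,
                     acceptor_extinction: Spectrum) -> float:
    """Spectral overlap J = ∫F ε λ⁴ dλ / ∫F dλ in M⁻¹ cm³.

    The acceptor extinction is linearly interpolated onto the donor grid
    restricted to the overlap region and the integrals evaluated by the
    trapezoid rule (λ in cm). The denominator runs over the full donor
    support. Disjoint supports give J = 0.
    """
    if donor_emission.kind is not SpectrumKind.emission_au:
        raise ValidationError("donor spectrum must have kind emission_au")
    if acceptor_extinction.kind is not SpectrumKind.molar_extinction_M1cm1:
        raise ValidationError(
            "acceptor spectrum must have kind molar_extinction_M1cm1"
        )
    lam_nm = donor_emission.wavelengths_nm
    F = donor_emission.values
    if np.any(F < 0):
        raise ValidationError("donor emission must be >= 0")
    lam_cm = lam_nm / _NM_PER_CM
    denom = np.trapezoid(F, lam_cm)
    if denom <= 0:
        raise ValidationError("donor spectrum integrates to zero")

    lo = max(lam_nm[0], acceptor_extinction.wavelengths_nm[0])
    hi = min(lam_nm[-1], acceptor_extinction.wavelengths_nm[-1])
    mask = (lam_nm >= lo) & (lam_nm <= hi)
    if hi <= lo or np.count_nonzero(mask) < 2:
        return 0.0
    eps = np.interp(lam_nm[mask], acceptor_extinction.wavelengths_nm,
                    acceptor_extinction.values)
    lam_ov = lam_cm[mask]
    numer = np.trapezoid(F[mask] * eps * lam_ov ** 4, lam_ov)
    return float(numer / denom)


def forster_radius(J_M1cm3: float, config: RunConfig | None = None) -> float:
    """Förster critical radius R0 in nm from the overlap integral.

    R0^6 = 8.79e-25 * kappa2 * n^-4 * Phi * J gives cm^6; the sixth root is
    converted to nm. J = 0 gives R0 = 0.
    """
    config = config or RunConfig()
    if J_M1cm3 < 0:
        raise ValidationError("J must be >= 0")
    r0_6_cm6 = (FORSTER_PREFACTOR * config.kappa2
                * config.refractive_index ** -4
                * config.quantum_yield * J_M1cm3)
    return float(r0_6_cm6 ** (1.0 / 6.0) * _NM_PER_CM)


def efficiency_from_quenching(F: float, F0: float) -> float:
    """Transfer efficiency E = 1 - F/F0 from donor intensities with and
    without the acceptor."""
    if F0 <= 0:
        raise ValidationError("F0 must be > 0")
    if F < 0 or F > F0:
        raise ValidationError("F must satisfy 0 <= F <= F0")
    return 1.0 - F / F0


def distance_from_efficiency(E: float, R0_nm: float) -> float:
    """Donor-acceptor distance r = R0 * ((1-E)/E)^(1/6) in nm."""
    if not (0.0 < E < 1.0):
        raise ValidationError("E must lie strictly in (0, 1)")
    if R0_nm <= 0:
        raise ValidationError("R0 must be > 0")
    return R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


def efficiency_from_distance(R0_nm: float, r_nm: float) -> float:
    """Transfer efficiency E = R0^6 / (R0^6 + r^6)."""
    if R0_nm <= 0 or r_nm <= 0:
        raise ValidationError("R0 and r must be > 0")
    ratio6 = (r_nm / R0_nm) ** 6
    return 1.0 / (1.0 + ratio6)


def forster_window_ok(R0_nm: float, r_nm: float) -> bool:
    """True when 0.5 R0 < r < 1.5 R0 (Förster-theory validity window)."""
    return 0.5 * R0_nm < r_nm < 1.5 * R0_nm


def fret_analysis(donor_emission: Spectrum, acceptor_extinction: Spectrum,
                  F: float, F0: float,
                  config: RunConfig | None = None) -> FretResult:
    """Full chain: J → R0 → E (from quenching) → r, with the window check."""
    config = config or RunConfig()
    J = overlap_integral(donor_emission, acceptor_extinction)
    R0 = forster_radius(J, config)
    E = efficiency_from_quenching(F, F0)
    r = distance_from_efficiency(E, R0)
    return FretResult(
        J_M1cm3=J,
        R0_nm=R0,
        E=E,
        r_nm=r,
        quantum_yield=config.quantum_yield,
        kappa2=config.kappa2,
        refractive_index=config.refractive_index,
        window_ok=forster_window_ok(R0, r),
    )
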