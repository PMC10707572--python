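"""Structural-spectroscopy summaries.

Covers four read-outs of ligand-induced conformational change:

* far-UV CD: mean-residue ellipticity [θ]λ = θλ·M0/(10·l·c) and the
  single-wavelength helix estimate %α = (−[θ]222 − 2340)/30300 · 100;
* UV-Vis: molar absorptivity ε = A/(c·l) and hyperchromicity at a chosen
  wavelength across a titration;
* synchronous fluorescence: the constant-offset diagonal λ_em = λ_ex + Δλ
  through an excitation-emission matrix (Δλ = 15 nm probes tyrosine,
  Δλ = 60 nm tryptophan);
* 3D fluorescence: strict local-maximum peak picking on the EEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .spectra_io import EEM, Spectrum, SpectrumKind, TitrationSeries, ValidationError

__all__ = [
    "CDResult",
    "EEMPeak",
    "EEMPeaks",
    "mean_residue_ellipticity",
    "helix_percent",
    "cd_analysis",
    "molar_absorptivity",
    "hyperchromicity",
    "synchronous_trace",
    "eem_peaks",
]

# Eq. constants of the single-wavelength helix estimate:
# fully helical [θ]222 = -32640, fully disordered -2340 deg cm^2 dmol^-1.
_HELIX_INTERCEPT = 2340.0
_HELIX_SLOPE = 30300.0


@dataclass(frozen=True)
class CDResult:
    """MRE spectrum, the MRE at (the grid point nearest) 222 nm, and the
    derived helix percentage; out-of-[0,100] values are flagged, not
    clamped."""

    mre_spectrum: Spectrum
    mre_222: float
    mre_222_wavelength_nm: float
    helix_percent: float
    helix_in_range: bool
    protein_conc_mg_ml: float
    path_length_cm: float
    mean_residue_weight_Da: float


@dataclass(frozen=True)
class EEMPeak:
    ex_nm: float
    em_nm: float
    intensity: float


@dataclass(frozen=True)
class EEMPeaks:
    peaks: tuple[EEMPeak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))


def mean_residue_ellipticity(theta_mdeg: Spectrum, conc_mg_ml: float,
                             path_cm: float, M0_Da: float) -> Spectrum:
    """Pointwise MRE [θ]λ = θλ·M0/(10·l·c) in deg·cm²·dmol⁻¹.

    θ is the observed ellipticity in mdeg, c the protein concentration in
    mg/cm³ (= mg/mL), l the cuvette path in cm, M0 the mean residue weight.
    """
    if theta_mdeg.kind is not SpectrumKind.ellipticity_mdeg:
        raise ValidationError("input spectrum must have kind ellipticity_mdeg")
    if conc_mg_ml <= 0 or path_cm <= 0 or M0_Da <= 0:
        raise ValidationError("c, l and M0 must all be > 0")
    mre = theta_mdeg.values * M0_Da / (10.0 * path_cm * conc_mg_ml)
    return theta_mdeg.with_values(mre, kind=SpectrumKind.mre_deg_cm2_dmol,
                                  label=theta_mdeg.label + " MRE")


def helix_percent(mre_222: float) -> float:
    """α-helix content (%) from the 222 nm MRE: (−[θ]222 − 2340)/30300·100.

    Values outside [0, 100] are returned unclamped; callers that need the
    in-range flag should use :func:`cd_analysis`.
    """
    return (-mre_222 - _HELIX_INTERCEPT) / _HELIX_SLOPE * 100.0


def cd_analysis(theta_mdeg: Spectrum, conc_mg_ml: float, path_cm: float,
                M0_Da: float) -> CDResult:
    """MRE conversion plus the 222 nm helix estimate in one pass.

    The 222 nm MRE is read at the nearest grid point (no interpolation); the
    wavelength actually used is recorded on the result.
    """
    mre = mean_residue_ellipticity(theta_mdeg, conc_mg_ml, path_cm, M0_Da)
    idx = int(np.argmin(np.abs(mre.wavelengths_nm - 222.0)))
    mre_222 = float(mre.values[idx])
    helix = helix_percent(mre_222)
    return CDResult(
        mre_spectrum=mre,
        mre_222=mre_222,
        mre_222_wavelength_nm=float(mre.wavelengths_nm[idx]),
        helix_percent=helix,
        helix_in_range=0.0 <= helix <= 100.0,
        protein_conc_mg_ml=conc_mg_ml,
        path_length_cm=path_cm,
        mean_residue_weight_Da=M0_Da,
    )


def molar_absorptivity(absorbance: Spectrum, conc_M: float,
                       path_cm: float) -> Spectrum:
    """Pointwise molar absorptivity ε = A/(c·l) in M⁻¹cm⁻¹."""
    if absorbance.kind is not SpectrumKind.absorbance:
        raise ValidationError("input spectrum must have kind absorbance")
    if conc_M <= 0 or path_cm <= 0:
        raise ValidationError("concentration and path length must be > 0")
    eps = absorbance.values / (conc_M * path_cm)
    return absorbance.with_values(eps, kind=SpectrumKind.molar_extinction_M1cm1,
                                  label=absorbance.label + " epsilon")


def hyperchromicity(series: TitrationSeries, lambda_nm: float) -> float:
    """Percent change of absorbance at λ between the first and last titration
    points: 100·(A_last − A_first)/A_first."""
    if series.spectra[0].kind is not SpectrumKind.absorbance:
        raise ValidationError("hyperchromicity needs absorbance spectra")
    wl = series.wavelengths_nm
    if not (wl[0] <= lambda_nm <= wl[-1]):
        raise ValidationError(f"{lambda_nm} nm outside the spectral grid")
    a_first = series.spectra[0].value_at(lambda_nm)
    a_last = series.spectra[-1].value_at(lambda_nm)
    if a_first == 0:
        raise ValidationError("reference absorbance is zero at the chosen λ")
    return 100.0 * (a_last - a_first) / a_first


def synchronous_trace(eem: EEM, delta_nm: float) -> Spectrum:
    """Constant-offset trace I(λ_ex, λ_ex + Δλ) through an EEM.

    The matrix is sampled by bilinear interpolation along the diagonal
    λ_em = λ_ex + Δλ; the trace is returned indexed by excitation wavelength.
    """
    if delta_nm <= 0:
        raise ValidationError("delta_nm must be > 0")
    ex = eem.excitation_nm
    valid = (ex + delta_nm >= eem.emission_nm[0]) \
        & (ex + delta_nm <= eem.emission_nm[-1])
    if np.count_nonzero(valid) < 2:
        raise ValidationError(
            f"diagonal λ_em = λ_ex + {delta_nm:g} nm misses the EEM domain"
        )
    interp = RegularGridInterpolator(
        (eem.excitation_nm, eem.emission_nm), eem.intensities,
        method="linear", bounds_error=True,
    )
    ex_used = ex[valid]
    pts = np.column_stack([ex_used, ex_used + delta_nm])
    return Spectrum(ex_used, interp(pts), SpectrumKind.emission_au,
                    label=f"synchronous Δλ={delta_nm:g} nm")


def eem_peaks(eem: EEM, min_separation_nm: float = 0.0) -> EEMPeaks:
    """Strict 8-neighbourhood local maxima of the EEM, intensity-descending.

    Peaks closer than ``min_separation_nm`` in both axes to a stronger peak
    are dropped (greedy non-maximum suppression). Edge cells qualify when
    they exceed all existing neighbours. An empty peak list is valid.
    """
    z = eem.intensities
    padded = np.full((z.shape[0] + 2, z.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = z
    centre = padded[1:-1, 1:-1]
    is_max = np.ones_like(z, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = padded[1 + di: padded.shape[0] - 1 + di,
                           1 + dj: padded.shape[1] - 1 + dj]
            is_max &= centre > neigh
    cand = [
        EEMPeak(float(eem.excitation_nm[i]), float(eem.emission_nm[j]),
                float(z[i, j]))
        for i, j in zip(*np.nonzero(is_max))
    ]
    cand.sort(key=lambda p: (-p.intensity, p.ex_nm, p.em_nm))
    kept: list[EEMPeak] = []
    for p in cand:
        clash = any(
            abs(p.ex_nm - k.ex_nm) < min_separation_nm
            and abs(p.em_nm - k.em_nm) < min_separation_nm
            for k in kept
        )
        if not clash:
            kept.append(p)
    return EEMPeaks(peaks=tuple(kept))
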