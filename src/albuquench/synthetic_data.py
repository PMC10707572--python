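"""Seeded generators for every input the analysis pipeline consumes.

Ground truth is known by construction, so every stage (quenching fits,
Van 't Hoff regression, overlap integrals, CD helix estimation, EEM peak
picking) can be validated with no instrument data:

* titrations follow the static-quenching law (F0−F)/F = Kb·[Q]^n, with the
  temperature dependence of Kb generated from fixed ΔH°, ΔS° via
  ln Kb = −ΔH°/RT + ΔS°/R, and a saturation-coupled blue shift of the
  emission band centre;
* donor-emission / acceptor-extinction Gaussian band pairs come with a
  dense-grid overlap-integral oracle (:func:`dense_overlap_oracle`);
* EEMs are sums of separable Gaussians at specified peak positions;
* CD spectra are built by inverting the mean-residue-ellipticity and helix
  formulas so the pipeline must recover the programmed helix fraction.

Noise is multiplicative Gaussian on intensities (``noise_cv`` = coefficient
of variation, 0 = noiseless); absorbance noise is additive with a floor at
zero. One global seed drives an independent counter-based stream per output
object, so adding outputs never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra_io import (
    EEM,
    GAS_CONSTANT_KCAL,
    Spectrum,
    SpectrumKind,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "Band",
    "EEMPeakSpec",
    "GeneratorSpec",
    "paper_preset",
    "kb_from_thermo",
    "make_titration",
    "make_fret_pair",
    "make_eem",
    "make_cd",
    "make_absorbance_titration",
    "dense_overlap_oracle",
]

# stream tags for the per-object counter-based RNG streams
_STREAM_TITRATION = 1
_STREAM_FRET = 2
_STREAM_EEM = 3
_STREAM_CD = 4
_STREAM_ABSORBANCE = 5


@dataclass(frozen=True)
class Band:
    """A Gaussian spectral band."""

    centre_nm: float
    sigma_nm: float
    eps_max_M1cm1: float = 1.0


@dataclass(frozen=True)
class EEMPeakSpec:
    ex_nm: float
    em_nm: float
    height: float
    sigma_nm: float = 12.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic experiment.

    Defaults mirror the serum-albumin/amiloride titration: four temperatures
    298–315 K, ΔH° = −6.80 kcal/mol, ΔS° = −3.30 cal/mol/K, a 1:1 complex,
    quencher 0–25 µM in 5 µM steps over a 4 µM protein, tryptophan emission
    band blue-shifting 339 → 329 nm at full saturation, and the two
    3D-fluorescence peaks at 280/335 and 230/330 nm.
    """

    seed: int = 0
    temperatures_K: tuple[float, ...] = (298.0, 303.0, 310.0, 315.0)
    dH_kcal_mol: float = -6.80
    dS_cal_mol_K: float = -3.30
    n_sites: float = 1.0
    protein_conc_M: float = 4e-6
    band_centre_start_nm: float = 339.0
    band_centre_end_nm: float = 329.0
    band_sigma_nm: float = 25.0
    F0_peak: float = 1000.0
    quencher_concs_M: tuple[float, ...] = (0.0, 5e-6, 10e-6, 15e-6, 20e-6, 25e-6)
    noise_cv: float = 0.0
    emission_grid_nm: tuple[float, float, float] = (300.0, 400.0, 0.5)
    acceptor_band: Band = field(
        default_factory=lambda: Band(centre_nm=362.0, sigma_nm=25.0,
                                     eps_max_M1cm1=1.0e4)
    )
    cd_helix_percent: float = 62.0
    cd_conc_mg_ml: float = 0.264  # 4 µM of a 66 kDa protein
    cd_path_cm: float = 0.1
    mean_residue_weight_Da: float = 112.8
    eem_peaks: tuple[EEMPeakSpec, ...] = (
        EEMPeakSpec(ex_nm=280.0, em_nm=335.0, height=3736.0),
        EEMPeakSpec(ex_nm=230.0, em_nm=330.0, height=1097.0),
    )
    #: Optional explicit Kb per temperature, overriding the ΔH°/ΔS° law.
    kb_by_temperature: Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.band_sigma_nm <= 0:
            raise ValidationError("band_sigma_nm must be > 0")
        if len(set(self.temperatures_K)) != len(self.temperatures_K):
            raise ValidationError("temperatures must be distinct")


def paper_preset(seed: int = 0, noise_cv: float = 0.0) -> GeneratorSpec:
    """Conditions with the published per-temperature binding constants as
    generating truth (instead of the smooth Van 't Hoff law)."""
    return GeneratorSpec(
        seed=seed,
        noise_cv=noise_cv,
        kb_by_temperature={298.0: 1.89e4, 303.0: 1.46e4,
                           310.0: 1.20e4, 315.0: 0.99e4},
    )


def _rng(spec: GeneratorSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed,
                                                        spawn_key=tuple(key)))


def kb_from_thermo(dH_kcal_mol: float, dS_cal_mol_K: float,
                   temperature_K: float) -> float:
    """Kb(T) = exp(−ΔH°/RT + ΔS°/R) with R in kcal/mol/K."""
    return float(np.exp(-dH_kcal_mol / (GAS_CONSTANT_KCAL * temperature_K)
                        + (dS_cal_mol_K / 1000.0) / GAS_CONSTANT_KCAL))


def _grid(spec: GeneratorSpec) -> np.ndarray:
    lo, hi, step = spec.emission_grid_nm
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _snap(grid: np.ndarray, x: float) -> float:
    return float(grid[int(np.argmin(np.abs(grid - x)))])


def make_titration(spec: GeneratorSpec, temperature_K: float) -> TitrationSeries:
    """Synthetic emission titration at one temperature.

    Intensities follow F = F0/(1 + Kb·[Q]^n) (so (F0−F)/F = Kb·[Q]^n, which
    reduces to the Stern-Volmer form F0/F = 1 + Kb[Q] at n = 1). The band
    centre interpolates linearly in the fractional quench — normalized to the
    final titration point — from the start to the end centre, and is snapped
    to the wavelength grid so the grid maximum is the true peak amplitude.
    """
    if temperature_K not in spec.temperatures_K:
        raise ValidationError(f"unknown temperature {temperature_K} K")
    if spec.kb_by_temperature is not None:
        kb = float(spec.kb_by_temperature[temperature_K])
    else:
        kb = kb_from_thermo(spec.dH_kcal_mol, spec.dS_cal_mol_K, temperature_K)
    q = np.asarray(spec.quencher_concs_M, dtype=float)
    F = spec.F0_peak / (1.0 + kb * q ** spec.n_sites)
    quench = 1.0 - F / spec.F0_peak
    full = quench[-1] if quench[-1] > 0 else 1.0
    frac = quench / full
    grid = _grid(spec)
    t_index = spec.temperatures_K.index(temperature_K)
    rng = _rng(spec, _STREAM_TITRATION, t_index)
    spectra = []
    for amp, f in zip(F, frac):
        centre = _snap(grid, spec.band_centre_start_nm
                       + f * (spec.band_centre_end_nm
                              - spec.band_centre_start_nm))
        vals = amp * np.exp(-((grid - centre) ** 2)
                            / (2.0 * spec.band_sigma_nm ** 2))
        if spec.noise_cv > 0:
            vals = vals * (1.0 + spec.noise_cv
                           * rng.standard_normal(vals.shape))
            vals = np.maximum(vals, 0.0)
        spectra.append(Spectrum(grid, vals, SpectrumKind.emission_au,
                                label=f"T={temperature_K:g}K Q={q[len(spectra)]:g}M"))
    return TitrationSeries(
        temperature_K=temperature_K,
        protein_conc_M=spec.protein_conc_M,
        quencher_concs_M=q,
        spectra=tuple(spectra),
    )


def make_fret_pair(spec: GeneratorSpec,
                   grid_step_nm: float = 0.5) -> tuple[Spectrum, Spectrum]:
    """Gaussian donor-emission and acceptor-extinction band pair.

    The donor band uses the titration's unquenched emission band; the
    acceptor band is ``spec.acceptor_band``. Both sit on ``grid_step_nm``
    grids spanning ±5σ around their centres. The matching analytic overlap
    integral is available from :func:`dense_overlap_oracle` evaluated over
    the donor grid's range.
    """
    dc, ds = spec.band_centre_start_nm, spec.band_sigma_nm
    donor_grid = np.arange(dc - 5 * ds, dc + 5 * ds + grid_step_nm / 2,
                           grid_step_nm)
    donor = Spectrum(
        donor_grid,
        spec.F0_peak * np.exp(-((donor_grid - dc) ** 2) / (2 * ds ** 2)),
        SpectrumKind.emission_au,
        label="synthetic donor emission",
    )
    ab = spec.acceptor_band
    acc_grid = np.arange(ab.centre_nm - 5 * ab.sigma_nm,
                         ab.centre_nm + 5 * ab.sigma_nm + grid_step_nm / 2,
                         grid_step_nm)
    acc_grid = acc_grid[acc_grid > 0]
    acceptor = Spectrum(
        acc_grid,
        ab.eps_max_M1cm1 * np.exp(-((acc_grid - ab.centre_nm) ** 2)
                                  / (2 * ab.sigma_nm ** 2)),
        SpectrumKind.molar_extinction_M1cm1,
        label="synthetic acceptor extinction",
    )
    return donor, acceptor


def dense_overlap_oracle(donor_centre_nm: float, donor_sigma_nm: float,
                         acceptor_centre_nm: float, acceptor_sigma_nm: float,
                         eps_max_M1cm1: float, lo_nm: float, hi_nm: float,
                         n_points: int = 1_000_000) -> float:
    """Brute-force midpoint-rule overlap integral for analytic Gaussian bands.

    Integrates J = ∫F ε λ⁴ dλ / ∫F dλ (λ in cm) over [lo_nm, hi_nm] on an
    ``n_points`` midpoint grid. Independent of the trapezoid implementation;
    used as the numerical oracle in tests.
    """
    edges = np.linspace(lo_nm, hi_nm, n_points + 1)
    lam_nm = 0.5 * (edges[:-1] + edges[1:])
    h_cm = (edges[1] - edges[0]) * 1e-7
    lam_cm = lam_nm * 1e-7
    F = np.exp(-((lam_nm - donor_centre_nm) ** 2) / (2 * donor_sigma_nm ** 2))
    eps = eps_max_M1cm1 * np.exp(-((lam_nm - acceptor_centre_nm) ** 2)
                                 / (2 * acceptor_sigma_nm ** 2))
    numer = np.sum(F * eps * lam_cm ** 4) * h_cm
    denom = np.sum(F) * h_cm
    return float(numer / denom)


def make_eem(spec: GeneratorSpec, ex_step_nm: float = 5.0,
             em_step_nm: float = 1.0) -> EEM:
    """Sum of separable Gaussians at the specified (ex, em, height) peaks.

    Excitation runs 230–400 nm in 5 nm steps (the instrument's increment);
    emission 280–450 nm.
    """
    if not spec.eem_peaks:
        raise ValidationError("at least one EEM peak required")
    ex = np.arange(230.0, 400.0 + ex_step_nm / 2, ex_step_nm)
    em = np.arange(280.0, 450.0 + em_step_nm / 2, em_step_nm)
    z = np.zeros((ex.size, em.size))
    for p in spec.eem_peaks:
        gx = np.exp(-((ex - p.ex_nm) ** 2) / (2 * p.sigma_nm ** 2))
        gy = np.exp(-((em - p.em_nm) ** 2) / (2 * p.sigma_nm ** 2))
        z += p.height * np.outer(gx, gy)
    if spec.noise_cv > 0:
        rng = _rng(spec, _STREAM_EEM)
        z = np.maximum(z * (1.0 + spec.noise_cv
                            * rng.standard_normal(z.shape)), 0.0)
    return EEM(excitation_nm=ex, emission_nm=em, intensities=z)


def make_cd(spec: GeneratorSpec) -> Spectrum:
    """Far-UV CD spectrum (observed ellipticity, mdeg) of known helix content.

    The mean-residue-ellipticity spectrum is shaped as two negative Gaussian
    bands near 209 and 222 nm and scaled so that MRE(222) equals
    −(2340 + 303·helix_percent) exactly; it is then converted to observed
    mdeg by inverting [θ] = θ·M0/(10·l·c) for the spec's c, l and M0, so the
    CD pipeline must recover the programmed helix percentage.
    """
    h = spec.cd_helix_percent
    if not (0.0 <= h <= 100.0):
        raise ValidationError("cd_helix_percent must lie in [0, 100]")
    grid = np.arange(190.0, 260.0 + 0.25, 0.5)
    shape = (np.exp(-((grid - 209.0) ** 2) / (2 * 7.0 ** 2))
             + 0.9 * np.exp(-((grid - 222.0) ** 2) / (2 * 8.0 ** 2)))
    i222 = int(np.argmin(np.abs(grid - 222.0)))
    target_mre_222 = -(2340.0 + 303.0 * h)
    mre = target_mre_222 * shape / shape[i222]
    theta_mdeg = mre * (10.0 * spec.cd_path_cm * spec.cd_conc_mg_ml) \
        / spec.mean_residue_weight_Da
    if spec.noise_cv > 0:
        rng = _rng(spec, _STREAM_CD)
        theta_mdeg = theta_mdeg * (1.0 + spec.noise_cv
                                   * rng.standard_normal(theta_mdeg.shape))
    return Spectrum(grid, theta_mdeg, SpectrumKind.ellipticity_mdeg,
                    label=f"synthetic CD, {h:g}% helix")


def make_absorbance_titration(spec: GeneratorSpec, lambda_peak_nm: float = 278.0,
                              rise_percent: float = 35.0,
                              a_peak_start: float = 0.365) -> TitrationSeries:
    """Absorbance titration with a programmed hyperchromic rise at a peak.

    The peak absorbance grows linearly with titration index from
    ``a_peak_start`` to ``a_peak_start * (1 + rise_percent/100)``; band shape
    is a Gaussian of 18 nm width on a 240–340 nm grid. Additive Gaussian
    noise (sd = noise_cv * a_peak_start) floored at zero when noisy.
    """
    grid = np.arange(240.0, 340.0 + 0.25, 0.5)
    q = np.asarray(spec.quencher_concs_M, dtype=float)
    n = q.size
    scales = np.linspace(1.0, 1.0 + rise_percent / 100.0, n)
    rng = _rng(spec, _STREAM_ABSORBANCE)
    spectra = []
    for j, s in enumerate(scales):
        vals = a_peak_start * s * np.exp(-((grid - lambda_peak_nm) ** 2)
                                         / (2 * 18.0 ** 2))
        if spec.noise_cv > 0:
            vals = vals + spec.noise_cv * a_peak_start \
                * rng.standard_normal(vals.shape)
            vals = np.maximum(vals, 0.0)
        spectra.append(Spectrum(grid, vals, SpectrumKind.absorbance,
                                label=f"A Q={q[j]:g}M"))
    return TitrationSeries(
        temperature_K=298.0,
        protein_conc_M=spec.protein_conc_M,
        quencher_concs_M=q,
        spectra=tuple(spectra),
    )
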