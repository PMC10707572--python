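"""Fluorescence-quenching analysis.

Static quenching of a single-tryptophan protein by a bound ligand is
quantified in three steps: (1) correct observed intensities for the inner
filter effect, F_corr = F_obs * exp((A_ex + A_em)/2); (2) fit the
Stern-Volmer law F0/F = 1 + K_SV [Q] by ordinary least squares to obtain the
quenching constant K_SV (and k_q = K_SV / tau0); (3) fit the double-log
binding law log10((F0-F)/F) = log10 Kb + n log10 [Q] to obtain the binding
constant Kb and stoichiometry n. The emission-maximum shift across the
titration (blue shift = more hydrophobic fluorophore environment) is also
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import RunConfig, TitrationSeries, ValidationError

__all__ = [
    "QuenchingResult",
    "BindingResult",
    "ShiftResult",
    "correct_inner_filter",
    "intensity_at_readout",
    "stern_volmer_fit",
    "bimolecular_rate",
    "double_log_fit",
    "emission_shift",
]


@dataclass(frozen=True)
class QuenchingResult:
    """Stern-Volmer fit: K_SV (M^-1), k_q = K_SV/tau0 (M^-1 s^-1), the fitted
    intercept (a linearity diagnostic, expected ~1), r^2 and point count."""

    temperature_K: float
    Ksv_M1: float
    kq_M1s1: float
    intercept: float
    r_squared: float
    n_points: int
    tau0_s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.Ksv_M1):
            raise ValidationError("Ksv_M1 must be finite")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class BindingResult:
    """Double-log binding fit: Kb (M^-1), stoichiometry n, diagnostics, and
    the number of titration points excluded because F >= F0."""

    temperature_K: float
    Kb_M1: float
    n_sites: float
    r_squared: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.Kb_M1 <= 0:
            raise ValidationError("Kb_M1 must be > 0")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")


@dataclass(frozen=True)
class ShiftResult:
    """Emission-maximum displacement; negative shift_nm is a blue shift."""

    lambda_max_start_nm: float
    lambda_max_end_nm: float
    shift_nm: float
    flat_tie: bool = False

    def __post_init__(self) -> None:
        if abs(self.shift_nm - (self.lambda_max_end_nm
                                - self.lambda_max_start_nm)) > 1e-9:
            raise ValidationError("shift_nm must equal end - start")


def correct_inner_filter(F_obs, A_ex, A_em):
    """Inner-filter-corrected intensity F_obs * exp((A_ex + A_em)/2).

    Accepts scalars or arrays (applied pointwise). Absorbances must be
    non-negative; the correction is the identity when both are zero.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be >= 0")
    if np.any(F_obs < 0):
        raise ValidationError("observed intensity must be >= 0")
    out = F_obs * np.exp((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def intensity_at_readout(series: TitrationSeries,
                         config: RunConfig | None = None) -> np.ndarray:
    """One intensity per titration point.

    Under ``fixed_at_reference_peak`` every spectrum is read at the emission
    maximum of the [Q]=0 spectrum; under ``per_spectrum_max`` each spectrum is
    read at its own maximum. When per-point excitation/emission absorbances
    are recorded on the series, the inner-filter correction is applied first.
    """
    config = config or RunConfig()
    mat = np.stack([s.values for s in series.spectra])
    if series.excitation_absorbances is not None \
            and series.emission_absorbances is not None:
        factor = np.exp((series.excitation_absorbances
                         + series.emission_absorbances) / 2.0)
        mat = mat * factor[:, None]
    if config.intensity_readout == "fixed_at_reference_peak":
        ref_idx = int(np.argmax(mat[0]))
        return mat[:, ref_idx].copy()
    return mat.max(axis=1)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted OLS returning (slope, intercept, r_squared)."""
    if np.ptp(x) == 0:
        raise ValidationError("degenerate fit: all abscissae identical")
    res = stats.linregress(x, y)
    # constant y gives r = nan in linregress; a flat line is a perfect fit
    r2 = 1.0 if np.ptp(y) == 0 else float(res.rvalue) ** 2
    return float(res.slope), float(res.intercept), r2


def stern_volmer_fit(series: TitrationSeries,
                     config: RunConfig | None = None) -> QuenchingResult:
    """OLS fit of F0/F versus [Q]; slope = K_SV, intercept reported (not
    forced to 1), k_q = K_SV / tau0 with the configured lifetime."""
    config = config or RunConfig()
    if len(series) < 3:
        raise ValidationError("Stern-Volmer fit needs >= 3 titration points")
    F = intensity_at_readout(series, config)
    if np.any(F <= 0):
        raise ValidationError("non-positive fluorescence intensity")
    y = F[0] / F
    slope, intercept, r2 = _ols(series.quencher_concs_M, y)
    return QuenchingResult(
        temperature_K=series.temperature_K,
        Ksv_M1=slope,
        kq_M1s1=bimolecular_rate(slope, config.tau0_s),
        intercept=intercept,
        r_squared=r2,
        n_points=len(series),
        tau0_s=config.tau0_s,
    )


def bimolecular_rate(Ksv_M1: float, tau0_s: float) -> float:
    """Bimolecular quenching rate constant k_q = K_SV / tau0 (M^-1 s^-1).

    Values far above the diffusion limit (~1e10 M^-1 s^-1) indicate static
    quenching.
    """
    if tau0_s <= 0:
        raise ValidationError("tau0_s must be > 0")
    return Ksv_M1 / tau0_s


def double_log_fit(series: TitrationSeries,
                   config: RunConfig | None = None) -> BindingResult:
    """OLS of log10((F0-F)/F) versus log10[Q] over points with [Q] > 0.

    Kb = 10**intercept, n = slope. Points with F >= F0 (no measurable
    quenching; log undefined) are excluded and counted in ``n_excluded``.
    """
    config = config or RunConfig()
    F = intensity_at_readout(series, config)
    if np.any(F <= 0):
        raise ValidationError("non-positive fluorescence intensity")
    F0 = F[0]
    q = series.quencher_concs_M
    usable = (q > 0) & (F < F0)
    n_excluded = int(np.count_nonzero((q > 0) & (F >= F0)))
    if np.count_nonzero(usable) < 3:
        raise ValidationError(
            "double-log fit needs >= 3 points with [Q] > 0 and F < F0"
        )
    x = np.log10(q[usable])
    y = np.log10((F0 - F[usable]) / F[usable])
    slope, intercept, r2 = _ols(x, y)
    return BindingResult(
        temperature_K=series.temperature_K,
        Kb_M1=10.0 ** intercept,
        n_sites=slope,
        r_squared=r2,
        n_points=int(np.count_nonzero(usable)),
        n_excluded=n_excluded,
    )


def emission_shift(series: TitrationSeries, refine: bool = False) -> ShiftResult:
    """Emission-maximum shift between the first and last titration spectra.

    The maximum is located by grid argmax; with ``refine=True`` a 3-point
    parabolic interpolation around the argmax is applied. Ties on a flat
    spectrum are broken toward the shorter wavelength and flagged.
    """
    if len(series) < 2:
        raise ValidationError("emission shift needs >= 2 spectra")

    def _peak(spec) -> tuple[float, bool]:
        v = spec.values
        i = int(np.argmax(v))
        tie = np.count_nonzero(v == v[i]) > 1
        lam = float(spec.wavelengths_nm[i])
        if refine and 0 < i < v.size - 1 and not tie:
            y0, y1, y2 = v[i - 1], v[i], v[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                x = spec.wavelengths_nm
                lam = lam - 0.5 * (y2 - y0) / denom * (x[i + 1] - x[i])
        return lam, tie

    start, tie0 = _peak(series.spectra[0])
    end, tie1 = _peak(series.spectra[-1])
    return ShiftResult(
        lambda_max_start_nm=start,
        lambda_max_end_nm=end,
        shift_nm=end - start,
        flat_tie=tie0 or tie1,
    )
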