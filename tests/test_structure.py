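"""CD helix estimation, molar absorptivity, synchronous traces, EEM peaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from albuquench import (
    EEM,
    Spectrum,
    SpectrumKind,
    TitrationSeries,
    ValidationError,
    cd_analysis,
    eem_peaks,
    helix_percent,
    hyperchromicity,
    mean_residue_ellipticity,
    molar_absorptivity,
    synchronous_trace,
)


def flat_spectrum(value, kind, lo=200.0, hi=260.0, step=1.0):
    grid = np.arange(lo, hi + step / 2, step)
    return Spectrum(grid, np.full(grid.size, value), kind)


# ------------------------------------------------------------------ CD / MRE

def test_mre_zero_in_zero_out():
    mre = mean_residue_ellipticity(
        flat_spectrum(0.0, SpectrumKind.ellipticity_mdeg), 0.264, 0.1, 112.8)
    assert np.all(mre.values == 0.0)
    assert mre.kind is SpectrumKind.mre_deg_cm2_dmol


def test_mre_hand_computed_value():
    """-10 mdeg at 0.264 mg/mL (4 µM of a 66 kDa protein), 1 mm path,
    M0 = 112.8 Da -> -10*112.8/(10*0.1*0.264) = -4272.7 deg cm^2/dmol."""
    mre = mean_residue_ellipticity(
        flat_spectrum(-10.0, SpectrumKind.ellipticity_mdeg), 0.264, 0.1, 112.8)
    assert mre.values[0] == pytest.approx(-4272.7273, rel=1e-6)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(scale=st.floats(0.1, 10), c=st.floats(0.05, 5))
def test_mre_linear_in_signal_inverse_in_concentration(scale, c):
    base = flat_spectrum(-10.0, SpectrumKind.ellipticity_mdeg)
    m1 = mean_residue_ellipticity(base, c, 0.1, 112.8).values[0]
    m2 = mean_residue_ellipticity(base.with_values(base.values * scale),
                                  c, 0.1, 112.8).values[0]
    m3 = mean_residue_ellipticity(base, 2 * c, 0.1, 112.8).values[0]
    assert m2 == pytest.approx(m1 * scale, rel=1e-12)
    assert m3 == pytest.approx(m1 / 2, rel=1e-12)


def test_mre_validates_inputs():
    with pytest.raises(ValidationError):
        mean_residue_ellipticity(
            flat_spectrum(1.0, SpectrumKind.absorbance), 0.264, 0.1, 112.8)
    with pytest.raises(ValidationError):
        mean_residue_ellipticity(
            flat_spectrum(1.0, SpectrumKind.ellipticity_mdeg), 0.0, 0.1, 112.8)


@pytest.mark.parametrize(
    "mre222, expected",
    [(-32640.0, 100.0), (-2340.0, 0.0), (-17490.0, 50.0)],
)
def test_helix_percent_endpoints_and_midpoint(mre222, expected):
    assert helix_percent(mre222) == pytest.approx(expected, abs=1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(frac=st.floats(0, 1))
def test_helix_percent_linear_between_endpoints(frac):
    mre = -2340.0 + frac * (-32640.0 + 2340.0)
    assert helix_percent(mre) == pytest.approx(100 * frac, abs=1e-9)


def test_cd_analysis_flags_out_of_range_and_records_wavelength():
    res = cd_analysis(flat_spectrum(-100.0, SpectrumKind.ellipticity_mdeg),
                      0.264, 0.1, 112.8)
    assert res.mre_222_wavelength_nm == 222.0
    assert not res.helix_in_range  # -42727 MRE implies >100% helix
    assert res.helix_percent > 100


# ------------------------------------------------------------------ UV-Vis

def test_molar_absorptivity_published_extinction():
    """A(280) = 0.365 at 10 µM, 1 cm path -> 36,500 M^-1 cm^-1."""
    grid = np.arange(240.0, 341.0, 1.0)
    a = Spectrum(grid, np.full(grid.size, 0.365), SpectrumKind.absorbance)
    eps = molar_absorptivity(a, 1e-5, 1.0)
    assert eps.value_at(280) == pytest.approx(36500.0, rel=1e-9)
    assert eps.kind is SpectrumKind.molar_extinction_M1cm1


def test_molar_absorptivity_zero_and_path_scaling():
    grid = np.arange(240.0, 341.0, 1.0)
    zero = Spectrum(grid, np.zeros(grid.size), SpectrumKind.absorbance)
    assert np.all(molar_absorptivity(zero, 1e-5, 1.0).values == 0)
    a = Spectrum(grid, np.full(grid.size, 0.2), SpectrumKind.absorbance)
    full = molar_absorptivity(a, 1e-5, 1.0).values[0]
    half = molar_absorptivity(a, 1e-5, 0.5).values[0]
    assert half == pytest.approx(2 * full, rel=1e-12)


def absorbance_series(scales, peak=278.0):
    grid = np.arange(240.0, 341.0, 1.0)
    q = np.arange(len(scales), dtype=float) * 5e-6
    spectra = tuple(
        Spectrum(grid, s * np.exp(-((grid - peak) ** 2) / (2 * 18 ** 2)),
                 SpectrumKind.absorbance)
        for s in scales
    )
    return TitrationSeries(298.0, 1e-5, q, spectra)


@pytest.mark.parametrize(
    "last_scale, expected",
    [(1.35, 35.0), (1.0, 0.0), (0.8, -20.0)],
)
def test_hyperchromicity_programmed_changes(last_scale, expected):
    series = absorbance_series(list(np.linspace(1.0, last_scale, 6)))
    assert hyperchromicity(series, 278.0) == pytest.approx(expected, rel=1e-9,
                                                           abs=1e-9)


def test_hyperchromicity_rejects_zero_reference_and_off_grid():
    series = absorbance_series([0.0, 1.0])
    with pytest.raises(ValidationError):
        hyperchromicity(series, 278.0)
    with pytest.raises(ValidationError):
        hyperchromicity(absorbance_series([1.0, 1.2]), 500.0)


# ------------------------------------------------------------------ EEM

def make_eem_matrix(peaks, ex=None, em=None):
    ex = np.arange(230.0, 401.0, 5.0) if ex is None else ex
    em = np.arange(280.0, 451.0, 1.0) if em is None else em
    z = np.zeros((ex.size, em.size))
    for x0, y0, h, s in peaks:
        z += h * np.outer(np.exp(-((ex - x0) ** 2) / (2 * s ** 2)),
                          np.exp(-((em - y0) ** 2) / (2 * s ** 2)))
    return EEM(ex, em, z)


def test_synchronous_trace_flat_eem_is_flat():
    eem = EEM(np.arange(230.0, 301.0, 5.0), np.arange(280.0, 401.0, 2.0),
              np.ones((15, 61)))
    trace = synchronous_trace(eem, 60.0)
    np.testing.assert_allclose(trace.values, 1.0)


def test_synchronous_trace_recovers_offset_ridge():
    """A ridge along em = ex + 60 appears in the Δλ=60 trace and is absent
    from the Δλ=15 trace."""
    ex = np.arange(230.0, 351.0, 2.0)
    em = np.arange(250.0, 451.0, 2.0)
    z = np.exp(-((em[None, :] - ex[:, None] - 60.0) ** 2) / (2 * 4.0 ** 2)) \
        * np.exp(-((ex[:, None] - 290.0) ** 2) / (2 * 20.0 ** 2))
    eem = EEM(ex, em, z)
    on_ridge = synchronous_trace(eem, 60.0)
    off_ridge = synchronous_trace(eem, 15.0)
    assert on_ridge.argmax_nm() == pytest.approx(290.0, abs=2.0)
    assert np.max(on_ridge.values) == pytest.approx(1.0, rel=1e-6)
    assert np.max(off_ridge.values) < 0.01


def test_synchronous_trace_peak_position_stable_across_titration():
    """A band that only loses amplitude does not shift the trace maximum."""
    positions = []
    for height in (3000.0, 2000.0, 1000.0):
        eem = make_eem_matrix([(280.0, 295.0, height, 15.0)])
        positions.append(synchronous_trace(eem, 15.0).argmax_nm())
    assert len(set(positions)) == 1


def test_synchronous_trace_validates_delta_and_domain():
    eem = make_eem_matrix([(280.0, 335.0, 1.0, 10.0)])
    with pytest.raises(ValidationError):
        synchronous_trace(eem, -5.0)
    with pytest.raises(ValidationError):
        synchronous_trace(eem, 5000.0)


def test_eem_peaks_recovers_two_programmed_peaks():
    eem = make_eem_matrix([(280.0, 335.0, 3736.0, 12.0),
                           (230.0, 330.0, 1097.0, 12.0)])
    peaks = eem_peaks(eem, min_separation_nm=20.0).peaks
    assert len(peaks) == 2
    assert (peaks[0].ex_nm, peaks[0].em_nm) == (280.0, 335.0)
    assert peaks[0].intensity == pytest.approx(3736.0, rel=0.01)
    assert (peaks[1].ex_nm, peaks[1].em_nm) == (230.0, 330.0)
    assert peaks[1].intensity == pytest.approx(1097.0, rel=0.01)


def test_eem_peaks_constant_matrix_has_none():
    eem = EEM(np.arange(230.0, 301.0, 5.0), np.arange(280.0, 401.0, 2.0),
              np.ones((15, 61)))
    assert eem_peaks(eem).peaks == ()


def test_eem_peaks_single_gaussian_single_peak():
    eem = make_eem_matrix([(300.0, 360.0, 500.0, 15.0)])
    peaks = eem_peaks(eem, min_separation_nm=10.0).peaks
    assert len(peaks) == 1
    assert (peaks[0].ex_nm, peaks[0].em_nm) == (300.0, 360.0)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    centres=st.lists(
        st.tuples(st.sampled_from([240.0, 280.0, 320.0, 360.0]),
                  st.sampled_from([300.0, 350.0, 400.0])),
        min_size=1, max_size=3, unique=True,
    )
)
def test_eem_peaks_well_separated_gaussians_in_height_order(centres):
    # drop conflicting centres that share an axis (merged maxima otherwise)
    kept = []
    for c in centres:
        if all(abs(c[0] - k[0]) >= 40 or abs(c[1] - k[1]) >= 50 for k in kept):
            kept.append(c)
    peaks_in = [(x, y, 1000.0 - 100.0 * i, 8.0)
                for i, (x, y) in enumerate(kept)]
    found = eem_peaks(make_eem_matrix(peaks_in), min_separation_nm=15.0).peaks
    assert len(found) == len(peaks_in)
    heights = [p.intensity for p in found]
    assert heights == sorted(heights, reverse=True)
    for (x, y, h, _), p in zip(
            sorted(peaks_in, key=lambda t: -t[2]), found):
        assert abs(p.ex_nm - x) <= 5.0 and abs(p.em_nm - y) <= 1.0
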