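"""Parsing, validation and round-trip behaviour of the spectral I/O layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from albuquench import (
    ParseError,
    RunConfig,
    Spectrum,
    SpectrumKind,
    TitrationSeries,
    ValidationError,
    read_eem,
    read_spectrum,
    read_titration,
)
from albuquench.quenching import stern_volmer_fit
from albuquench.spectra_io import (
    read_result_table,
    write_result_table,
    write_spectrum,
    write_titration,
)
from albuquench.thermodynamics import vant_hoff_fit


# ---------------------------------------------------------------------- types

class TestSpectrumInvariants:
    def test_rejects_non_increasing_wavelengths(self):
        with pytest.raises(ValidationError):
            Spectrum([340, 340, 350], [1, 2, 3], SpectrumKind.emission_au)
        with pytest.raises(ValidationError):
            Spectrum([350, 340], [1, 2], SpectrumKind.emission_au)

    def test_rejects_nonpositive_wavelengths(self):
        with pytest.raises(ValidationError):
            Spectrum([-1, 340], [1, 2], SpectrumKind.emission_au)

    def test_rejects_length_mismatch_and_too_short(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 310], [1], SpectrumKind.emission_au)
        with pytest.raises(ValidationError):
            Spectrum([300], [1], SpectrumKind.emission_au)

    def test_absorbance_must_be_nonnegative(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 310], [0.1, -0.1], SpectrumKind.absorbance)
        # emission may legitimately dip below zero after baseline subtraction
        Spectrum([300, 310], [0.1, -0.1], SpectrumKind.emission_au)


class TestTitrationInvariants:
    def _spec(self, grid=None):
        g = np.array([300.0, 340.0, 400.0]) if grid is None else grid
        return Spectrum(g, np.ones_like(g), SpectrumKind.emission_au)

    def test_first_concentration_must_be_zero(self):
        with pytest.raises(ValidationError):
            TitrationSeries(298, 4e-6, [1e-6, 2e-6],
                            (self._spec(), self._spec()))

    def test_concentrations_must_increase(self):
        with pytest.raises(ValidationError):
            TitrationSeries(298, 4e-6, [0, 10e-6, 5e-6],
                            (self._spec(), self._spec(), self._spec()))

    def test_spectra_must_share_grid(self):
        other = self._spec(np.array([300.0, 341.0, 400.0]))
        with pytest.raises(ValidationError):
            TitrationSeries(298, 4e-6, [0, 1e-6], (self._spec(), other))

    def test_single_point_baseline_series_is_valid(self):
        series = TitrationSeries(298, 4e-6, [0.0], (self._spec(),))
        assert len(series) == 1


# -------------------------------------------------------------------- parsing

def test_read_spectrum_simple(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text("300\t0.0\n340\t1.0\n400\t0.1\n")
    s = read_spectrum(p, "emission_au")
    assert len(s) == 3
    assert s.argmax_nm() == 340.0


def test_read_spectrum_sort_invariance(tmp_path):
    asc = tmp_path / "a.csv"
    desc = tmp_path / "d.csv"
    asc.write_text("300,0.0\n340,1.0\n400,0.1\n")
    desc.write_text("400,0.1\n340,1.0\n300,0.0\n")
    a, d = read_spectrum(asc, "emission_au"), read_spectrum(desc, "emission_au")
    np.testing.assert_array_equal(a.wavelengths_nm, d.wavelengths_nm)
    np.testing.assert_array_equal(a.values, d.values)


def test_read_spectrum_duplicate_wavelength_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("300\t0.0\n340\t1.0\n340\t0.9\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_spectrum(p, "emission_au")


def test_read_spectrum_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("# only a comment\n")
    with pytest.raises(ValidationError):
        read_spectrum(p, "emission_au")


def test_read_spectrum_malformed_row_names_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("wavelength\tvalue\n300\t0.0\n340\toops\n")
    with pytest.raises(ParseError, match="line 3"):
        read_spectrum(p, "emission_au")


def test_read_spectrum_comments_header_and_semicolons(tmp_path):
    p = tmp_path / "s.txt"
    p.write_text("# instrument export\nlambda;signal\n300;1.0\n310;2.0 # peak\n")
    s = read_spectrum(p, "emission_au")
    assert list(s.values) == [1.0, 2.0]


def test_read_titration_six_columns(tmp_path):
    concs = [0, 5e-6, 10e-6, 15e-6, 20e-6, 25e-6]
    p = tmp_path / "t.tsv"
    rows = ["\t".join(["340"] + [f"{100 - 10 * j}" for j in range(6)]),
            "\t".join(["350"] + [f"{90 - 10 * j}" for j in range(6)])]
    p.write_text("\n".join(rows) + "\n")
    series = read_titration(p, {"temperature_K": 298, "protein_conc_M": 4e-6,
                                "quencher_concs_M": concs})
    assert len(series) == 6
    assert series.spectra[0].value_at(340) == 100.0


def test_read_titration_column_count_mismatch(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("340\t1\t2\n350\t1\t2\n")
    with pytest.raises(ValidationError, match="declared"):
        read_titration(p, {"temperature_K": 298, "protein_conc_M": 4e-6,
                           "quencher_concs_M": [0, 5e-6, 10e-6]})


def test_read_titration_unordered_concentrations_rejected(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("340\t1\t2\t3\n350\t1\t2\t3\n")
    with pytest.raises(ValidationError):
        read_titration(p, {"temperature_K": 298, "protein_conc_M": 4e-6,
                           "quencher_concs_M": [0, 10e-6, 5e-6]})


def test_read_eem_matrix(tmp_path):
    p = tmp_path / "eem.tsv"
    p.write_text("0\t300\t310\n230\t1\t2\n235\t3\t4\n")
    eem = read_eem(p)
    assert eem.intensities.shape == (2, 2)
    assert list(eem.emission_nm) == [300.0, 310.0]


# --------------------------------------------------------------- round trips

@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, width=32),
                min_size=2, max_size=40))
def test_spectrum_roundtrip_preserves_values(tmp_path_factory, values):
    tmp = tmp_path_factory.mktemp("rt")
    grid = 300.0 + np.arange(len(values))
    s = Spectrum(grid, values, SpectrumKind.emission_au)
    path = tmp / "s.tsv"
    write_spectrum(s, path)
    back = read_spectrum(path, "emission_au")
    np.testing.assert_allclose(back.wavelengths_nm, s.wavelengths_nm, rtol=1e-6)
    np.testing.assert_allclose(back.values, s.values, rtol=1e-6, atol=1e-300)


def test_titration_roundtrip_preserves_fit(tmp_path):
    from conftest import gaussian_series

    series = gaussian_series(3.82e4)
    path = tmp_path / "t.tsv"
    write_titration(series, path)
    back = read_titration(path, {
        "temperature_K": series.temperature_K,
        "protein_conc_M": series.protein_conc_M,
        "quencher_concs_M": series.quencher_concs_M,
    })
    fit0 = stern_volmer_fit(series, RunConfig())
    fit1 = stern_volmer_fit(back, RunConfig())
    assert fit1.Ksv_M1 == pytest.approx(fit0.Ksv_M1, rel=1e-6)


def test_result_table_roundtrip_six_sig_figs(tmp_path):
    result = vant_hoff_fit([(298, 1.89e4), (303, 1.46e4),
                            (310, 1.20e4), (315, 0.99e4)])
    path = tmp_path / "r.tsv"
    write_result_table(result, path)
    frame = read_result_table(path)
    dh = float(frame.loc[frame.parameter == "dH_kcal_mol", "value"].iloc[0])
    assert dh == pytest.approx(result.dH_kcal_mol, rel=1e-6)
    rows = frame[frame.parameter == "dG_kcal_mol"]
    assert len(rows) == 4


def test_result_table_empty_set_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_result_table([], path)
    frame = read_result_table(path)
    assert len(frame) == 0
    assert list(frame.columns) == ["parameter", "temperature_K", "value"]


# ---------------------------------------------------------------------- config

def test_runconfig_defaults_and_yaml_roundtrip(tmp_path):
    cfg = RunConfig()
    assert cfg.tau0_s == 1e-8
    assert cfg.quantum_yield == 0.118
    assert cfg.kappa2 == pytest.approx(2 / 3)
    assert cfg.refractive_index == 1.33
    p = tmp_path / "cfg.yaml"
    RunConfig(tau0_s=5.79e-9).to_yaml(p)
    assert RunConfig.from_yaml(p).tau0_s == 5.79e-9


def test_runconfig_rejects_bad_values():
    with pytest.raises(ValidationError):
        RunConfig(kappa2=5.0)
    with pytest.raises(ValidationError):
        RunConfig(tau0_s=0.0)
    with pytest.raises(ValidationError):
        RunConfig(intensity_readout="nonsense")
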