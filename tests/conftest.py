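import numpy as np
import pytest

from albuquench import GeneratorSpec, RunConfig, Spectrum, SpectrumKind, TitrationSeries


@pytest.fixture
def default_spec() -> GeneratorSpec:
    return GeneratorSpec()


@pytest.fixture
def peak_config() -> RunConfig:
    """Readout at each spectrum's own maximum (exact for shifted bands)."""
    return RunConfig(intensity_readout="per_spectrum_max")


def gaussian_series(ksv: float, n: float = 1.0, *, centres=None,
                    sigma: float = 15.0, f0: float = 1000.0,
                    concs=None, temperature: float = 298.0) -> TitrationSeries:
    """Hand-rolled titration obeying (F0-F)/F = ksv*[Q]^n, independent of the
    package's generator (used as an oracle for the fitting code)."""
    q = np.asarray(concs if concs is not None
                   else [0, 5e-6, 10e-6, 15e-6, 20e-6, 25e-6], dtype=float)
    amps = f0 / (1.0 + ksv * q ** n)
    grid = np.arange(300.0, 400.5, 0.5)
    if centres is None:
        centres = [340.0] * q.size
    spectra = tuple(
        Spectrum(grid, a * np.exp(-((grid - c) ** 2) / (2 * sigma ** 2)),
                 SpectrumKind.emission_au)
        for a, c in zip(amps, centres)
    )
    return TitrationSeries(temperature_K=temperature, protein_conc_M=4e-6,
                           quencher_concs_M=q, spectra=spectra)
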