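"""Spectral data containers, validation, and delimited-text I/O.

All wavelengths are nanometres on disk and in memory; all concentrations in
the data model are molar. Files are UTF-8 delimited text (tab, comma or
semicolon, auto-detected), ``#`` starts a comment, and one non-numeric header
row is tolerated. No vendor binary formats are parsed.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "TitrationSeries",
    "EEM",
    "RunConfig",
    "ValidationError",
    "ParseError",
    "GAS_CONSTANT_KCAL",
    "read_spectrum",
    "read_titration",
    "read_eem",
    "write_spectrum",
    "write_result_table",
    "read_result_table",
    "results_to_frame",
]

#: Universal gas constant in kcal mol^-1 K^-1 (CODATA), fixed package-wide.
GAS_CONSTANT_KCAL = 1.987204e-3


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class SpectrumKind(str, enum.Enum):
    """Physical meaning (and units) of a spectrum's ordinate."""

    emission_au = "emission_au"
    absorbance = "absorbance"
    molar_extinction_M1cm1 = "molar_extinction_M1cm1"
    ellipticity_mdeg = "ellipticity_mdeg"
    mre_deg_cm2_dmol = "mre_deg_cm2_dmol"


_NONNEGATIVE_KINDS = frozenset(
    {SpectrumKind.absorbance, SpectrumKind.molar_extinction_M1cm1}
)


@dataclass(frozen=True)
class Spectrum:
    """A single wavelength-indexed signal trace.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, positive wavelengths in nanometres.
    values
        Signal values, one per wavelength; units set by ``kind``.
    kind
        What the ordinate physically is (emission intensity, absorbance,
        molar extinction, ellipticity, or mean-residue ellipticity).
    label
        Free-text tag carried through analyses and reports.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValidationError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite wavelength or value")
        if np.any(wl <= 0):
            raise ValidationError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.kind in _NONNEGATIVE_KINDS and np.any(vals < 0):
            raise ValidationError(f"{self.kind.value} values must be >= 0")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def value_at(self, wavelength_nm: float) -> float:
        """Signal at the grid point nearest ``wavelength_nm``."""
        i = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        return float(self.values[i])

    def argmax_nm(self) -> float:
        """Wavelength of the grid maximum (ties broken toward shorter λ)."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None,
                    label: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths_nm.copy(),
            np.asarray(values, dtype=float),
            self.kind if kind is None else kind,
            self.label if label is None else label,
        )


@dataclass(frozen=True)
class TitrationSeries:
    """Emission (or absorbance) spectra at increasing quencher concentrations.

    The first concentration must be 0 (the ligand-free reference); all spectra
    share one wavelength grid. Optional per-point absorbances at the
    excitation and emission wavelengths enable inner-filter correction.
    """

    temperature_K: float
    protein_conc_M: float
    quencher_concs_M: np.ndarray
    spectra: tuple[Spectrum, ...]
    path_length_cm: float = 1.0
    excitation_absorbances: np.ndarray | None = None
    emission_absorbances: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_concs_M, dtype=float)
        object.__setattr__(self, "quencher_concs_M", q)
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be > 0")
        if self.protein_conc_M <= 0:
            raise ValidationError("protein_conc_M must be > 0")
        if self.path_length_cm <= 0:
            raise ValidationError("path_length_cm must be > 0")
        if q.ndim != 1 or q.size == 0:
            raise ValidationError("quencher_concs_M must be a non-empty 1-D sequence")
        if q[0] != 0.0:
            raise ValidationError("first quencher concentration must be 0")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if len(self.spectra) != q.size:
            raise ValidationError("one spectrum per quencher concentration required")
        kinds = {s.kind for s in self.spectra}
        if not kinds <= {SpectrumKind.emission_au, SpectrumKind.absorbance}:
            raise ValidationError("titration spectra must be emission_au or absorbance")
        if len(kinds) > 1:
            raise ValidationError("titration spectra must share one kind")
        grid = self.spectra[0].wavelengths_nm
        for s in self.spectra[1:]:
            if s.wavelengths_nm.shape != grid.shape or not np.array_equal(
                s.wavelengths_nm, grid
            ):
                raise ValidationError("all spectra must share one wavelength grid")
        for name in ("excitation_absorbances", "emission_absorbances"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                object.__setattr__(self, name, a)
                if a.shape != q.shape:
                    raise ValidationError(f"{name} must match quencher_concs_M length")
                if np.any(a < 0):
                    raise ValidationError(f"{name} must be >= 0")

    def __len__(self) -> int:
        return int(self.quencher_concs_M.size)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix (3D fluorescence landscape)."""

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensities: np.ndarray  # shape (n_excitation, n_emission)

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation_nm, dtype=float)
        em = np.asarray(self.emission_nm, dtype=float)
        z = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "excitation_nm", ex)
        object.__setattr__(self, "emission_nm", em)
        object.__setattr__(self, "intensities", z)
        for name, ax in (("excitation_nm", ex), ("emission_nm", em)):
            if ax.ndim != 1 or ax.size < 1:
                raise ValidationError(f"{name} must be a non-empty 1-D sequence")
            if np.any(np.diff(ax) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise ValidationError("intensity matrix shape must be (n_ex, n_em)")
        if not np.all(np.isfinite(z)):
            raise ValidationError("non-finite EEM intensity")


@dataclass(frozen=True)
class RunConfig:
    """Photophysical constants and analysis switches.

    tau0_s is the unquenched donor fluorescence lifetime; quantum_yield,
    kappa2 and refractive_index feed the Förster-radius formula;
    mean_residue_weight_Da feeds mean-residue ellipticity. All are
    overridable — none is hard-coded at a call site.
    """

    tau0_s: float = 1e-8
    quantum_yield: float = 0.118
    kappa2: float = 2.0 / 3.0
    refractive_index: float = 1.33
    mean_residue_weight_Da: float = 112.8
    intensity_readout: str = "fixed_at_reference_peak"

    #: The gas constant is fixed, not configurable.
    gas_constant_kcal: float = field(default=GAS_CONSTANT_KCAL, init=False)

    def __post_init__(self) -> None:
        for name in ("tau0_s", "quantum_yield", "refractive_index",
                     "mean_residue_weight_Da"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 < self.kappa2 <= 4):
            raise ValidationError("kappa2 must be in (0, 4]")
        if self.intensity_readout not in ("fixed_at_reference_peak",
                                          "per_spectrum_max"):
            raise ValidationError(
                "intensity_readout must be 'fixed_at_reference_peak' or "
                "'per_spectrum_max'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a flat key-value mapping")
        data.pop("gas_constant_kcal", None)
        allowed = {"tau0_s", "quantum_yield", "kappa2", "refractive_index",
                   "mean_residue_weight_Da", "intensity_readout"}
        unknown = set(data) - allowed
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "tau0_s": self.tau0_s,
            "quantum_yield": self.quantum_yield,
            "kappa2": self.kappa2,
            "refractive_index": self.refractive_index,
            "mean_residue_weight_Da": self.mean_residue_weight_Da,
            "intensity_readout": self.intensity_readout,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# delimited-text parsing

_DELIMITERS = ("\t", ",", ";")


def _raw_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-empty, non-comment lines with their 1-based line numbers."""
    out = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            out.append((i, stripped))
    return out


def _sniff_delimiter(lines: Sequence[tuple[int, str]]) -> str:
    counts = {d: sum(l.count(d) for _, l in lines) for d in _DELIMITERS}
    best = max(counts, key=lambda d: counts[d])
    if counts[best] == 0:
        # fall back to whitespace-delimited
        return ""
    return best


def _split(line: str, delim: str) -> list[str]:
    return [f.strip() for f in (line.split(delim) if delim else line.split())]


def _parse_table(path: str | Path) -> tuple[list[int], list[list[float]], list[str] | None]:
    """Parse a delimited numeric table.

    Returns (line numbers, rows of floats, optional header fields). A single
    leading non-numeric row is treated as a header.
    """
    lines = _raw_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty file")
    delim = _sniff_delimiter(lines)
    header: list[str] | None = None
    rows: list[list[float]] = []
    nums: list[int] = []
    for idx, (lineno, text) in enumerate(lines):
        fields = _split(text, delim)
        try:
            row = [float(f) for f in fields]
        except ValueError:
            if idx == 0 and header is None:
                header = fields
                continue
            raise ParseError(f"{path}: malformed row at line {lineno}: {text!r}")
        rows.append(row)
        nums.append(lineno)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    width = len(rows[0])
    for lineno, row in zip(nums, rows):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
    return nums, rows, header


def read_spectrum(path: str | Path, kind: SpectrumKind | str,
                  label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength_nm, value) file as a :class:`Spectrum`.

    Rows may appear in any wavelength order; they are sorted. Duplicate
    wavelengths are rejected.
    """
    nums, rows, _ = _parse_table(path)
    if any(len(r) != 2 for r in rows):
        bad = next(n for n, r in zip(nums, rows) if len(r) != 2)
        raise ParseError(f"{path}: line {bad}: expected 2 columns")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise ValidationError(f"{path}: duplicate wavelength {dup:g} nm")
    return Spectrum(arr[:, 0], arr[:, 1], SpectrumKind(kind),
                    label if label is not None else Path(path).stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column TSV (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {spectrum.kind.value}  label: {spectrum.label}\n")
        fh.write("wavelength_nm\tvalue\n")
        for wl, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{wl:.10g}\t{v:.10g}\n")


def read_titration(path: str | Path, meta: Mapping[str, object]) -> TitrationSeries:
    """Read a wide-format titration table.

    First column is wavelength (nm); remaining columns are one emission
    spectrum per quencher concentration. ``meta`` supplies (at least)
    ``temperature_K``, ``protein_conc_M`` and ``quencher_concs_M``; optional
    keys: ``path_length_cm``, ``excitation_absorbances``,
    ``emission_absorbances``, ``kind``.
    """
    nums, rows, _ = _parse_table(path)
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValidationError(f"{path}: duplicate wavelength rows")
    concs = np.asarray(meta["quencher_concs_M"], dtype=float)
    n_spec = arr.shape[1] - 1
    if n_spec != concs.size:
        raise ValidationError(
            f"{path}: {n_spec} spectrum columns but {concs.size} declared "
            "concentrations"
        )
    kind = SpectrumKind(meta.get("kind", SpectrumKind.emission_au))
    spectra = tuple(
        Spectrum(arr[:, 0], arr[:, j + 1], kind, label=f"Q={concs[j]:g} M")
        for j in range(n_spec)
    )
    return TitrationSeries(
        temperature_K=float(meta["temperature_K"]),
        protein_conc_M=float(meta["protein_conc_M"]),
        quencher_concs_M=concs,
        spectra=spectra,
        path_length_cm=float(meta.get("path_length_cm", 1.0)),
        excitation_absorbances=meta.get("excitation_absorbances"),
        emission_absorbances=meta.get("emission_absorbances"),
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    """Write a titration series as a wide TSV (wavelength + one col per [Q])."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# temperature_K: {series.temperature_K:.10g}\n")
        fh.write(f"# protein_conc_M: {series.protein_conc_M:.10g}\n")
        fh.write("# quencher_concs_M: "
                 + ",".join(f"{q:.10g}" for q in series.quencher_concs_M) + "\n")
        header = ["wavelength_nm"] + [f"Q{j}" for j in range(len(series))]
        fh.write("\t".join(header) + "\n")
        mat = np.column_stack([series.wavelengths_nm]
                              + [s.values for s in series.spectra])
        for row in mat:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_eem(path: str | Path) -> EEM:
    """Read a matrix TSV: first row emission wavelengths, first column
    excitation wavelengths, body intensities."""
    nums, rows, header = _parse_table(path)
    if header is not None:
        raise ParseError(f"{path}: EEM files must be fully numeric")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"{path}: EEM matrix needs >= 1 excitation row "
                              "and >= 1 emission column")
    return EEM(excitation_nm=arr[1:, 0], emission_nm=arr[0, 1:],
               intensities=arr[1:, 1:])


def write_eem(eem: EEM, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("0\t" + "\t".join(f"{v:.10g}" for v in eem.emission_nm) + "\n")
        for ex, row in zip(eem.excitation_nm, eem.intensities):
            fh.write(f"{ex:.10g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# result tables

def _record_rows(result: object) -> list[dict[str, object]]:
    """Flatten a result dataclass into parameter/temperature/value rows."""
    from . import quenching, thermodynamics, fret, structure  # local: avoid cycle

    rows: list[dict[str, object]] = []
    if isinstance(result, quenching.QuenchingResult):
        t = result.temperature_K
        rows += [
            {"parameter": "KSV_M1", "temperature_K": t, "value": result.Ksv_M1},
            {"parameter": "kq_M1s1", "temperature_K": t, "value": result.kq_M1s1},
            {"parameter": "SV_intercept", "temperature_K": t, "value": result.intercept},
            {"parameter": "SV_r_squared", "temperature_K": t, "value": result.r_squared},
        ]
    elif isinstance(result, quenching.BindingResult):
        t = result.temperature_K
        rows += [
            {"parameter": "Kb_M1", "temperature_K": t, "value": result.Kb_M1},
            {"parameter": "n_sites", "temperature_K": t, "value": result.n_sites},
            {"parameter": "loglog_r_squared", "temperature_K": t,
             "value": result.r_squared},
        ]
    elif isinstance(result, thermodynamics.ThermoResult):
        rows.append({"parameter": "dH_kcal_mol", "temperature_K": float("nan"),
                     "value": result.dH_kcal_mol})
        rows.append({"parameter": "dS_cal_mol_K", "temperature_K": float("nan"),
                     "value": result.dS_cal_mol_K})
        for rec in result.per_temperature:
            rows.append({"parameter": "TdS_kcal_mol",
                         "temperature_K": rec.temperature_K,
                         "value": rec.TdS_kcal_mol})
            rows.append({"parameter": "dG_kcal_mol",
                         "temperature_K": rec.temperature_K,
                         "value": rec.dG_kcal_mol})
    elif isinstance(result, fret.FretResult):
        for name, v in (("J_M1cm3", result.J_M1cm3), ("R0_nm", result.R0_nm),
                        ("E", result.E), ("r_nm", result.r_nm),
                        ("window_ok", float(result.window_ok))):
            rows.append({"parameter": name, "temperature_K": float("nan"),
                         "value": v})
    elif isinstance(result, structure.CDResult):
        for name, v in (("mre_222", result.mre_222),
                        ("helix_percent", result.helix_percent)):
            rows.append({"parameter": name, "temperature_K": float("nan"),
                         "value": v})
    elif isinstance(result, structure.EEMPeaks):
        for i, p in enumerate(result.peaks, 1):
            rows.append({"parameter": f"peak{i}_ex_nm",
                         "temperature_K": float("nan"), "value": p.ex_nm})
            rows.append({"parameter": f"peak{i}_em_nm",
                         "temperature_K": float("nan"), "value": p.em_nm})
            rows.append({"parameter": f"peak{i}_intensity",
                         "temperature_K": float("nan"), "value": p.intensity})
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")
    return rows


def results_to_frame(results: object | Iterable[object]) -> pd.DataFrame:
    """Flatten one result object (or an iterable of them) into a long table."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    rows: list[dict[str, object]] = []
    for r in results:
        rows.extend(_record_rows(r))
    return pd.DataFrame(rows, columns=["parameter", "temperature_K", "value"])


def write_result_table(results: object | Iterable[object], path: str | Path) -> None:
    """Write fitted results as a flat TSV (parameter, temperature_K, value).

    Values are written with enough digits to round-trip to at least six
    significant figures.
    """
    frame = results_to_frame(results) if not isinstance(results, pd.DataFrame) \
        else results
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
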