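"""End-to-end pipeline: titrations → quenching/binding fits → Van 't Hoff →
FRET → structural summaries, collected into a deterministic run report.

The input manifest is a plain mapping (usually loaded from YAML):

.. code-block:: yaml

    titrations:
      - path: titration_298K.tsv
        temperature_K: 298
        protein_conc_M: 4.0e-6
        quencher_concs_M: [0, 5.0e-6, 10.0e-6, 15.0e-6, 20.0e-6, 25.0e-6]
    fret:                 # optional
      donor: donor.tsv
      acceptor: acceptor.tsv
      f_ratio: 0.55       # F/F0 at equimolar donor/acceptor
    cd:                   # optional
      path: cd.tsv
      conc_mg_ml: 0.264
      path_cm: 0.1
    eem:                  # optional
      path: eem.tsv
      min_separation_nm: 20
      sync_deltas_nm: [15, 60]

At least one titration is required; the thermodynamic block is produced only
when two or more temperatures are present, otherwise it is marked
insufficient. A stage that raises produces a failed-stage marker rather than
aborting the report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .spectra_io import (
    RunConfig,
    ValidationError,
    read_eem,
    read_spectrum,
    read_titration,
    results_to_frame,
    write_result_table,
)
from .quenching import (
    BindingResult,
    QuenchingResult,
    ShiftResult,
    double_log_fit,
    emission_shift,
    stern_volmer_fit,
)
from .thermodynamics import ThermoResult, binding_force_classification, vant_hoff_fit
from .fret import FretResult, fret_analysis
from .structure import CDResult, EEMPeaks, cd_analysis, eem_peaks, synchronous_trace

__all__ = ["RunReport", "run_pipeline", "load_manifest"]


@dataclass
class RunReport:
    """All stage outputs plus provenance; rendering is deterministic."""

    quenching: list[QuenchingResult] = field(default_factory=list)
    binding: list[BindingResult] = field(default_factory=list)
    shifts: list[ShiftResult] = field(default_factory=list)
    thermo: ThermoResult | None = None
    thermo_note: str = ""
    binding_force: str = ""
    fret: FretResult | None = None
    cd: CDResult | None = None
    eem: EEMPeaks | None = None
    failed_stages: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_text(self) -> str:
        """Human-readable summary; byte-identical for identical inputs."""
        lines: list[str] = []
        add = lines.append
        add(f"albuquench run report (version {self.provenance.get('version', '?')})")
        add("")
        add("== Quenching / binding per temperature ==")
        add("T_K\tKSV_M1\tkq_M1s1\tSV_intercept\tSV_r2\tKb_M1\tn\tloglog_r2"
            "\tshift_nm")
        for q, b, s in zip(self.quenching, self.binding, self.shifts):
            add(f"{q.temperature_K:g}\t{q.Ksv_M1:.6g}\t{q.kq_M1s1:.6g}"
                f"\t{q.intercept:.6g}\t{q.r_squared:.6g}"
                f"\t{b.Kb_M1:.6g}\t{b.n_sites:.6g}\t{b.r_squared:.6g}"
                f"\t{s.shift_nm:.6g}")
        add("")
        add("== Thermodynamics ==")
        if self.thermo is not None:
            t = self.thermo
            add(f"dH_kcal_mol\t{t.dH_kcal_mol:.6g}")
            add(f"dS_cal_mol_K\t{t.dS_cal_mol_K:.6g}")
            for rec in t.per_temperature:
                add(f"T={rec.temperature_K:g}\tTdS_kcal_mol={rec.TdS_kcal_mol:.6g}"
                    f"\tdG_kcal_mol={rec.dG_kcal_mol:.6g}")
            add(f"binding_force\t{self.binding_force}")
        else:
            add(f"(skipped: {self.thermo_note})")
        add("")
        add("== FRET ==")
        if self.fret is not None:
            f = self.fret
            add(f"J_M1cm3\t{f.J_M1cm3:.6g}")
            add(f"R0_nm\t{f.R0_nm:.6g}")
            add(f"E\t{f.E:.6g}")
            add(f"r_nm\t{f.r_nm:.6g}")
            add(f"window_0.5R0<r<1.5R0\t{'ok' if f.window_ok else 'VIOLATED'}")
            add(f"constants\tPhi={f.quantum_yield:g} kappa2={f.kappa2:g}"
                f" n={f.refractive_index:g}")
        else:
            add("(not requested)")
        add("")
        add("== CD ==")
        if self.cd is not None:
            add(f"MRE_222 ({self.cd.mre_222_wavelength_nm:g} nm)"
                f"\t{self.cd.mre_222:.6g}")
            add(f"helix_percent\t{self.cd.helix_percent:.6g}"
                + ("" if self.cd.helix_in_range else "  (OUT OF [0,100] RANGE)"))
        else:
            add("(not requested)")
        add("")
        add("== EEM peaks ==")
        if self.eem is not None:
            add("ex_nm/em_nm\tintensity")
            for p in self.eem.peaks:
                add(f"{p.ex_nm:g}/{p.em_nm:g}\t{p.intensity:.6g}")
        else:
            add("(not requested)")
        if self.failed_stages:
            add("")
            add("== FAILED STAGES ==")
            for name in sorted(self.failed_stages):
                add(f"{name}\t{self.failed_stages[name]}")
        if self.warnings:
            add("")
            add("== Warnings ==")
            for w in self.warnings:
                add(w)
        add("")
        add("== Provenance ==")
        for key in sorted(self.provenance):
            add(f"{key}\t{self.provenance[key]}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.txt").write_text(self.to_text())
        results: list[object] = list(self.quenching) + list(self.binding)
        if self.thermo is not None:
            results.append(self.thermo)
        if self.fret is not None:
            results.append(self.fret)
        if self.cd is not None:
            results.append(self.cd)
        if self.eem is not None:
            results.append(self.eem)
        if results:
            write_result_table(results_to_frame(results), outdir / "results.tsv")


def load_manifest(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: manifest must be a mapping")
    return data


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, manifest: Mapping[str, Any],
                 base_dir: str | Path = ".") -> RunReport:
    """Execute every requested stage and collect a :class:`RunReport`."""
    base = Path(base_dir)
    report = RunReport()
    prov: dict[str, Any] = {"version": __version__}
    prov["config"] = (f"tau0_s={config.tau0_s:g} Phi={config.quantum_yield:g} "
                      f"kappa2={config.kappa2:g} n={config.refractive_index:g} "
                      f"M0={config.mean_residue_weight_Da:g} "
                      f"readout={config.intensity_readout}")

    tit_entries = manifest.get("titrations") or []
    if not tit_entries:
        raise ValidationError("manifest must reference at least one titration")

    series_list = []
    for entry in tit_entries:
        p = base / entry["path"]
        series = read_titration(p, entry)
        series_list.append(series)
        prov[f"input:{entry['path']}"] = _digest(p)
    series_list.sort(key=lambda s: s.temperature_K)

    kb_pairs: list[tuple[float, float]] = []
    for series in series_list:
        q = stern_volmer_fit(series, config)
        b = double_log_fit(series, config)
        s = emission_shift(series)
        report.quenching.append(q)
        report.binding.append(b)
        report.shifts.append(s)
        if b.n_excluded:
            report.warnings.append(
                f"T={series.temperature_K:g} K: {b.n_excluded} point(s) with "
                "F >= F0 excluded from the double-log fit"
            )
        if s.flat_tie:
            report.warnings.append(
                f"T={series.temperature_K:g} K: flat emission maximum; tie "
                "broken toward shorter wavelength"
            )
        kb_pairs.append((series.temperature_K, b.Kb_M1))

    if len(kb_pairs) >= 2:
        try:
            report.thermo = vant_hoff_fit(kb_pairs)
            report.binding_force = binding_force_classification(
                report.thermo.dH_kcal_mol, report.thermo.dS_cal_mol_K
            ).value
        except Exception as exc:  # stage failure -> marker, not abort
            report.failed_stages["thermodynamics"] = str(exc)
    else:
        report.thermo_note = "insufficient temperatures (need >= 2)"

    fret_spec = manifest.get("fret")
    if fret_spec:
        try:
            donor = read_spectrum(base / fret_spec["donor"], "emission_au")
            acceptor = read_spectrum(base / fret_spec["acceptor"],
                                     "molar_extinction_M1cm1")
            prov[f"input:{fret_spec['donor']}"] = _digest(base / fret_spec["donor"])
            prov[f"input:{fret_spec['acceptor']}"] = _digest(
                base / fret_spec["acceptor"])
            f_ratio = float(fret_spec["f_ratio"])
            report.fret = fret_analysis(donor, acceptor, F=f_ratio, F0=1.0,
                                        config=config)
            if not report.fret.window_ok:
                report.warnings.append(
                    "FRET distance outside the 0.5 R0 < r < 1.5 R0 window"
                )
        except Exception as exc:
            report.failed_stages["fret"] = str(exc)

    cd_spec = manifest.get("cd")
    if cd_spec:
        try:
            theta = read_spectrum(base / cd_spec["path"], "ellipticity_mdeg")
            prov[f"input:{cd_spec['path']}"] = _digest(base / cd_spec["path"])
            report.cd = cd_analysis(
                theta,
                conc_mg_ml=float(cd_spec["conc_mg_ml"]),
                path_cm=float(cd_spec["path_cm"]),
                M0_Da=float(cd_spec.get("mean_residue_weight_Da",
                                        config.mean_residue_weight_Da)),
            )
            if not report.cd.helix_in_range:
                report.warnings.append("helix percentage outside [0, 100]")
        except Exception as exc:
            report.failed_stages["cd"] = str(exc)

    eem_spec = manifest.get("eem")
    if eem_spec:
        try:
            eem = read_eem(base / eem_spec["path"])
            prov[f"input:{eem_spec['path']}"] = _digest(base / eem_spec["path"])
            report.eem = eem_peaks(
                eem, float(eem_spec.get("min_separation_nm", 20.0)))
            for delta in eem_spec.get("sync_deltas_nm", []):
                trace = synchronous_trace(eem, float(delta))
                report.warnings.append(
                    f"synchronous Δλ={delta:g} nm maximum at "
                    f"{trace.argmax_nm():g} nm excitation"
                )
        except Exception as exc:
            report.failed_stages["eem"] = str(exc)

    report.provenance = prov
    return report
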