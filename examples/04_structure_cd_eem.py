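"""Structural spectroscopy: CD helix content and 3D-fluorescence peaks.

Generates a far-UV CD spectrum of known helix fraction and an
excitation-emission matrix with two programmed peaks, then recovers both
with the analysis functions. Also shows a synchronous-fluorescence slice.
"""

from albuquench import (
    GeneratorSpec,
    cd_analysis,
    eem_peaks,
    make_cd,
    make_eem,
    synchronous_trace,
)

spec = GeneratorSpec(cd_helix_percent=62.0)

theta = make_cd(spec)
cd = cd_analysis(theta, spec.cd_conc_mg_ml, spec.cd_path_cm,
                 spec.mean_residue_weight_Da)
print(f"MRE at {cd.mre_222_wavelength_nm:g} nm = {cd.mre_222:.1f} deg cm^2/dmol")
print(f"alpha-helix = {cd.helix_percent:.2f}%  "
      f"(programmed: {spec.cd_helix_percent}%)")

eem = make_eem(spec)
peaks = eem_peaks(eem, min_separation_nm=20.0)
print("\n3D-fluorescence peaks (descending intensity):")
for p in peaks.peaks:
    print(f"  ex/em = {p.ex_nm:g}/{p.em_nm:g} nm   intensity = {p.intensity:.0f}")

trace = synchronous_trace(eem, delta_nm=60.0)
print(f"\nsynchronous Δλ=60 nm trace peaks at {trace.argmax_nm():g} nm excitation")
print()
print("The two EEM peaks report the polypeptide backbone (lower-excitation)")
print("and the aromatic-residue microenvironment; intensity drops and peak")
print("shifts across a titration indicate ligand-induced perturbation.")
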