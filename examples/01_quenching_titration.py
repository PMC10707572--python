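"""Stern-Volmer and double-log binding fits on one synthetic titration.

Builds a noiseless emission titration (0-25 µM quencher over a 4 µM protein
at 298 K), then fits the quenching and binding laws. On noiseless data the
fits must return the generating constants exactly, with r² = 1.
"""

from albuquench import (
    GeneratorSpec,
    RunConfig,
    double_log_fit,
    emission_shift,
    kb_from_thermo,
    make_titration,
    stern_volmer_fit,
)

spec = GeneratorSpec()
config = RunConfig(intensity_readout="per_spectrum_max")

series = make_titration(spec, 298.0)
sv = stern_volmer_fit(series, config)
dl = double_log_fit(series, config)
shift = emission_shift(series)
kb_true = kb_from_thermo(spec.dH_kcal_mol, spec.dS_cal_mol_K, 298.0)

print(f"generating Kb(298 K)      = {kb_true:.4g} M^-1")
print(f"Stern-Volmer K_SV         = {sv.Ksv_M1:.4g} M^-1   (r^2 = {sv.r_squared:.6f})")
print(f"bimolecular k_q           = {sv.kq_M1s1:.4g} M^-1 s^-1 (tau0 = {sv.tau0_s:g} s)")
print(f"double-log Kb             = {dl.Kb_M1:.4g} M^-1,  n = {dl.n_sites:.4f}")
print(f"emission shift            = {shift.shift_nm:+.1f} nm "
      f"({shift.lambda_max_start_nm:.0f} -> {shift.lambda_max_end_nm:.0f})")
print()
print("K_SV matches Kb because a 1:1 static complex makes the Stern-Volmer")
print("slope the association constant; the -10 nm blue shift signals a more")
print("hydrophobic tryptophan environment on binding.")
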