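# albuquench

Analysis toolkit for protein–ligand binding characterized by solution
spectroscopy: fluorescence-quenching titrations, Van 't Hoff thermodynamics,
Förster-resonance-energy-transfer (FRET) distance estimation, and structural
read-outs (far-UV CD, UV-Vis, synchronous and 3D fluorescence). The library
targets the classic tryptophan-quenching workflow used to characterize drug
binding to serum albumin and similar single-fluorophore proteins, and ships a
seeded synthetic-spectra generator so every stage can be validated against
known ground truth without instrument data.

## The model

A ligand Q that forms a non-fluorescent ground-state complex with a protein P
quenches the protein's intrinsic (tryptophan) emission. The analysis chain is:

1. **Inner-filter correction** — F_corr = F_obs · exp((A_ex + A_em)/2),
   applied when excitation/emission absorbances are recorded.
2. **Stern–Volmer** — F₀/F = 1 + K_SV[Q] = 1 + k_q τ₀ [Q]; the slope K_SV
   (M⁻¹) is fitted by OLS, and k_q = K_SV/τ₀ ≫ 10¹⁰ M⁻¹s⁻¹ diagnoses static
   quenching. For a 1:1 static complex the Stern–Volmer slope is the
   association constant.
3. **Double-log binding fit** — log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q]
   gives the binding constant K_b and stoichiometry n.
4. **Van 't Hoff** — ln K_b = −ΔH°/RT + ΔS°/R over ≥ 2 temperatures gives
   ΔH°, ΔS° (R = 1.987204×10⁻³ kcal mol⁻¹K⁻¹), and ΔG° = ΔH° − TΔS°; the
   signs classify the dominant force (Ross–Subramanian rules).
5. **FRET** — J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ (λ in cm),
   R₀⁶ = 8.79×10⁻²⁵ κ² n⁻⁴ Φ J, E = 1 − F/F₀ = R₀⁶/(R₀⁶ + r⁶) yields the
   donor–acceptor distance r, with the 0.5R₀ < r < 1.5R₀ validity check.
6. **Structure** — mean-residue ellipticity [θ]λ = θλM₀/(10·l·c) and
   %α-helix = (−[θ]₂₂₂ − 2340)/30300 × 100; molar absorptivity ε = A/(c·l)
   and hyperchromicity; synchronous traces (Δλ = 15 nm tyrosine, 60 nm
   tryptophan); EEM local-maximum peak picking.

## Worked example

```python
from albuquench import (GeneratorSpec, RunConfig, make_titration,
                        stern_volmer_fit, double_log_fit, vant_hoff_fit)

spec = GeneratorSpec()                       # 4 µM protein, 0-25 µM ligand
config = RunConfig(intensity_readout="per_spectrum_max")

kb_pairs = []
for T in spec.temperatures_K:                # 298, 303, 310, 315 K
    series = make_titration(spec, T)
    fit = double_log_fit(series, config)
    kb_pairs.append((T, fit.Kb_M1))

thermo = vant_hoff_fit(kb_pairs)
print(f"dH = {thermo.dH_kcal_mol:+.2f} kcal/mol, "
      f"dS = {thermo.dS_cal_mol_K:+.2f} cal/mol/K")
```

prints

```
dH = -6.80 kcal/mol, dS = -3.30 cal/mol/K
```

— the titrations were generated from exactly these thermodynamic parameters,
so the noiseless pipeline recovers them to machine precision. Negative ΔH°
and ΔS° indicate binding through van der Waals contacts and hydrogen bonds;
ΔG° ≈ −5.8 kcal/mol at 298 K means spontaneous complex formation. The
`examples/` directory has one narrative script per capability (quenching,
thermodynamics, FRET, structure, full report); each prints its numbers with
a line on what they mean. A thin `albuquench` CLI wraps the same functions
(`albuquench simulate | quench | thermo | fret | cd | uvvis | sync |
eem-peaks | report`).

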