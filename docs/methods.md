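# Methods

## Scope and model assumptions

The package analyses steady-state spectroscopic titrations of a
single-fluorophore protein with a quenching ligand under the static-quenching
model: the ligand forms a non-fluorescent 1:1 ground-state complex, so the
observed emission is proportional to the unbound protein fraction. No
excited-state kinetics (time-resolved decays, Smoluchowski diffusion models)
are modelled; the only lifetime dependence is the ratio k_q = K_SV/τ₀.
The free-ligand approximation is used throughout: [Q] in the fitting laws is
the *total* added quencher, with no depletion correction. This is the
convention of the underlying plot-based methods; at protein concentrations
(4 µM) comparable to the lowest quencher points it slightly biases constants,
identically in the generator and the fits, so recovery tests are exact.

## Fitting conventions

* All straight-line fits are unweighted ordinary least squares
  (`scipy.stats.linregress`). r² is reported; a perfectly flat response is
  treated as r² = 1 (a flat line is an exact linear fit).
* The Stern–Volmer intercept is *estimated*, not constrained to 1; its
  deviation from 1 is a linearity diagnostic.
* The double-log binding fit uses base-10 logarithms (the field's
  convention), K_b = 10^intercept. The [Q] = 0 point is excluded (log
  undefined), and any point with F ≥ F₀ is excluded and tallied in
  `n_excluded`.
* Van 't Hoff: ln K_b vs 1/T, ΔH° = −slope·R, ΔS° = intercept·R with
  R = 1.987204×10⁻³ kcal mol⁻¹K⁻¹; ΔH° is assumed temperature-independent
  over the fitted range. The reported per-temperature TΔS° uses the single
  fitted ΔS°, and ΔG° = ΔH° − TΔS° (an arithmetic identity of the linear
  model, equal to −RT·lnK_b on the fitted line).
* Energy unit is kcal/mol everywhere; entropy is reported in cal mol⁻¹K⁻¹.

## Intensity readout

Published protocols rarely state whether F₀ and F are read at a fixed
wavelength or at each spectrum's own emission maximum, and the two differ
once the band blue-shifts. Both are supported via
`RunConfig.intensity_readout`:

* `fixed_at_reference_peak` (default): every spectrum is read at the λ_max
  of the [Q] = 0 spectrum — the common bench practice;
* `per_spectrum_max`: each spectrum at its own maximum — exact for
  amplitude recovery when the band centre moves.

When a titration carries per-point excitation/emission absorbances the
inner-filter correction F·exp((A_ex+A_em)/2) is applied before readout;
otherwise intensities are used as given.

## FRET numerics

The overlap integral includes the λ⁴ factor with λ in cm,
J = ∫F ε λ⁴ dλ / ∫F dλ (M⁻¹cm³): this is the standard Förster definition and
the only one dimensionally consistent with the 8.79×10⁻²⁵ prefactor
producing R₀⁶ in cm⁶ from J in M⁻¹cm³. (Condensed write-ups often omit the
λ⁴ from the formula while using it in the computation.) The acceptor
extinction is linearly interpolated onto the donor grid restricted to the
overlap region — the donor grid is typically the denser one — and both
integrals use the trapezoid rule; the normalization integral runs over the
full donor support. Convergence is O(h²) in the grid spacing and is checked
in the tests against a 10⁶-point midpoint-rule oracle
(`synthetic_data.dense_overlap_oracle`) and the narrow-band closed form
J → ε₀λ⁴. Default photophysical constants (Φ = 0.118, κ² = 2/3, n = 1.33,
τ₀ = 10⁻⁸ s) are the literature values for tryptophan donors in aqueous
protein media; all are configurable and never hard-coded at call sites.

Note on τ₀: published k_q tables for this system are internally consistent
with τ₀ ≈ 5.8 ns rather than the nominal 10 ns quoted alongside them.
k_q here is always K_SV/τ₀ for the τ₀ actually configured (recorded on the
result); no value is silently chosen to match any table.

## Structure read-outs

* CD: [θ]λ = θλ·M₀/(10·l·c) with c in mg/cm³; the helix estimate uses the
  222 nm MRE read at the *nearest grid point* (recorded on the result, never
  silently interpolated). Out-of-[0,100] helix percentages are returned
  unclamped with a flag — clamping would hide calibration errors. The mean
  residue weight default (112.8 Da) is 66 kDa / 585 residues.
* EEM peaks are strict 8-neighbourhood local maxima (edges may qualify),
  greedily filtered so that no kept peak is within `min_separation_nm` of a
  stronger one in *both* axes, sorted by descending intensity.
* Synchronous traces sample the matrix along λ_em = λ_ex + Δλ by bilinear
  interpolation and are indexed by excitation wavelength.

## Synthetic-data generator

`GeneratorSpec` defaults encode the study conditions: four temperatures
(298/303/310/315 K), ΔH° = −6.80 kcal/mol, ΔS° = −3.30 cal mol⁻¹K⁻¹
(equivalently K_b ≈ 1.8×10⁴ M⁻¹ at 298 K), a 1:1 complex (n = 1), 4 µM
protein titrated with 0–25 µM ligand in 5 µM steps, and a tryptophan
emission band blue-shifting 339 → 329 nm at full saturation.
`paper_preset()` instead pins the per-temperature binding constants
(1.89/1.46/1.20/0.99 ×10⁴ M⁻¹) directly as generating truth. The emission
band is Gaussian with σ = 25 nm (a realistic tryptophan bandwidth; the
linewidth is not critical to any fitted quantity), its centre interpolating
linearly in fractional quench and snapped to the wavelength grid so the grid
maximum equals the true amplitude. The acceptor band (362 nm, σ = 25 nm,
ε_max = 10⁴ M⁻¹cm⁻¹) is a realistic ligand π→π* absorption overlapping the
donor emission. Noise is multiplicative Gaussian on emission intensities
(`noise_cv`), additive with a zero floor on absorbances; one global seed
drives an independent `SeedSequence` stream per output object, so adding
outputs never perturbs existing ones and identical seeds reproduce identical
bytes.

What the generator does **not** emulate: Rayleigh/Raman scatter ridges in
EEMs, photobleaching, instrument response functions, baseline drift, or
correlated (non-white) noise. Passing recovery tests therefore demonstrates
the correctness of the estimators under the stated generative model, not
robustness to every artefact of real instrument data.

## Estimator behaviour under noise

With 1 % multiplicative intensity noise on 6-point titrations, the
Stern–Volmer slope recovers the generating constant with ≈ 1–2 % median
relative error. The double-log intercept estimator is far less robust: its
intercept extrapolates from log₁₀[Q] ≈ −4.9 to 0, amplifying the same noise
~40-fold (tens of percent median error in 10^intercept). This is an
intrinsic property of the double-logarithmic method at micromolar
concentrations, not an implementation defect; noiseless data are still
recovered to machine precision. Consequently, when a single binding constant
must be estimated from noisy data under the 1:1 static model, the
Stern–Volmer slope is the estimator of choice (the two parameters coincide
when n = 1), and the stochastic recovery tests use it. The double-log fit
remains the route to the stoichiometry n.

## Problem sizes

Tests and recovery studies use 6-point titrations on 201-point wavelength
grids, 200-replicate noise ensembles, and a 10⁶-point integration oracle —
sizes chosen to make Monte-Carlo medians stable while keeping the whole
suite interactive.

## Known limitations

* Single-site (1:1) model only; no multi-site or cooperative binding.
* Linear Van 't Hoff only (ΔCp = 0); curved fits are out of scope.
* No CD secondary-structure deconvolution beyond the 222 nm formula.
* No automatic baseline/scatter correction; inputs are assumed
  instrument-corrected except for the inner filter effect.
* The free-ligand approximation biases constants when binding approaches
  stoichiometric depletion of the ligand.
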