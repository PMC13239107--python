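# Methods

This note documents the models, the synthetic data they run on, the
numerical choices, and the limits of what the package's tests demonstrate.

## Track physics

Mass stopping power of ions (Z = 1–6) in water is an analytic Bethe formula
with a Barkas-type effective charge, Z_eff = Z(1 − exp(−125β/Z^{2/3})), and
mean excitation energies I = 78 eV for Z ≤ 2 and I = 75 eV for heavier
ions. No shell, density or higher-order corrections are applied; the model
is valid for 0.1–450 MeV/u. CSDA ranges come from cumulative quadrature of
A·dE/S on a 4000-point log grid (relative error < 2×10⁻³ against adaptive
quadrature). A fitted power law R = aE^p (p ≈ 1.72 for carbon) is exposed
for fast inversion; the engine itself uses monotone table interpolation.

Computed anchors: R(carbon, 430 MeV/u) = 30.90 cm, R(290) = 16.29 cm —
both within ~3% of measured clinical beams — and R(100) = 2.59 cm. The
often-quoted "2 cm" for the bottom of the clinical energy window is a loose
rounding; the physical value obtained by any consistent stopping-power
integration (equivalently, one third of the 100 MeV proton CSDA range) is
2.5–2.6 cm.

## Microdosimetry

Tracks are amorphous Kiefer–Chatterjee cylinders: a constant-dose core of
radius r_c = 0.0116·β µm inside a 1/r² penumbra out to
r_p = 0.0616·E^{1.7} µm, continuous at r_c and normalized so the planar
energy integral equals the LET (verified to 1% for every supported
species/energy). All secondary-electron energy deposits locally; there is
no electron transport.

Single-event spectra for the cylindrical domain (length = diameter) sweep
the impact parameter b of an axis-parallel track, uniform in area out to
r_d + r_p, with a composite grid that resolves direct hits even when
r_p ≫ r_d. Lineal energy uses the mean-chord convention y = e/(4r_d/3);
specific energy uses z = 0.1602·y/(ρπr²) (keV, µm, g/cm³ → Gy), applied
with r_d for the domain and R_n for the nucleus. Event dose weights are
deposited on the 200-point log y grid (0.1–2000 keV/µm) with linear
cloud-in-cell weights, which conserves both the total dose and the first
moment; spectrum means agree with direct event statistics to <0.1% and with
10× finer impact-parameter sampling to 2%.

z*\_D applies the saturation correction at the single-event level,
z\*\_D = z₀² Σw(1 − e^{−(z/z₀)²}) / Σwz with z₀ = conv(y₀ = 150 keV/µm, r_d).
The correction produces the expected overkill behaviour: carbon z\*\_D
peaks near 10 MeV/u (≈ 32 Gy for r_d = 0.32 µm) and declines toward both
lower and higher energies.

## RBE models and mixed fields

mMKM: α = α₀ + β₀z\*\_D with β ≡ β₀ (HSG: α₀ = 0.172 Gy⁻¹,
β₀ = 0.0615 Gy⁻², r_d = 0.32 µm, R_n = 3.9 µm). MCF MKM: spectrum
integrals with the saturation factor c(y) = (1 − e^{−A})/A,
A = (α₀ + β₀z_d)z_n + β₀z_n² (HSG: α₀ = 0.117 Gy⁻¹, β₀ = 0.0615 Gy⁻²,
r_d = 0.28 µm, R_n = 4.5 µm); β ≤ β₀ always holds because c ≤ 1.

Mixed fields are dose-weighted: α linearly, β through dose-weighted √β
(the Zaider–Rossi convention; a literal dose-weighted-β variant is exposed
behind `convention="linear"` for sensitivity checks). The RBE-weighted
dose solves the LQ iso-effect closed form
D_ref = (√(α_ref² + 4β_ref(αD + βD²)) − α_ref)/(2β_ref), and clinical dose
multiplies by the carbon-reference factor 2.41. Both conventions are exact
and unit-tested (root-check to 10⁻¹⁰).

## Synthetic machine base data

The generator emulates per-energy beamline base data on a three-region
depth grid: an entrance region of 42 bins ending 2 cm proximal to the
Bragg peak (resolution 0.012–0.68 cm across 100–430 MeV/u), a 4 cm peak
region at 0.05 cm, and an 8 cm tail at 1 cm, extending 10 cm beyond the
peak.

The depth dose is the stopping power of the slowing primary, attenuated by
nuclear interactions (mean free path 25.5 cm), convolved with Gaussian
range spread σ_R = max(0.0045·R, 1.2 mm). The floor stands in for the
ripple filter and source energy spread of a scanning beamline; without it,
millimetre-sharp synthetic peaks would be incommensurate with the 3 mm
energy steps used for SOBPs. A fraction η = 0.8 of the nuclear-loss energy
reappears as charged-fragment dose in five species channels (Z = 1–5) with
power-law build-up (z/R)^{p_Z} and exponential tails; the remainder escapes
as neutrals. The channel coefficients are plumbing, serialized with the
machine for reproducibility — they exercise the mixed-field machinery with
plausible compositions but are not fitted to any measured fragmentation
data. Energy bookkeeping closes to 2% by construction. Lateral width is
σ(z)² = σ_spot² + σ_MCS(z)² with Highland scattering power through
Fermi–Eyges transport (σ_spot = 3 mm default).

Per-depth biological tables assign each species its residual energy
(range–energy inversion; fragments modelled as stopping 3 tail-lengths
beyond the primary range), look up per-ion LQ coefficients from log-energy
quality tables (48 points, 1–450 MeV/u), and mix with the fragment dose
fractions. The mMKM √β table is constant at √0.0615 by construction.

What the generator does **not** emulate: measured fragmentation spectra,
nuclear halo in the lateral profile, energy-spectrum mixing at a given
depth (each depth uses the mean residual energy), or any beamline-specific
commissioning data. Consequences are discussed under Limitations.

## Dose engine, optimization, calibration

Beams are axis-aligned; each spot deposits w·IDD(wed)·G₂D(r; σ(wed)) at
voxel centres (3 mm grid), with water-equivalent depth from cumulative
RSP-weighted path length. Alongside dose the engine accumulates ΣD_iα_i
and ΣD_i√β_i per model, so the voxel effect ε = ΣD_iα_i + (ΣD_i√β_i)² is
exactly quadratic in the spot weights. The optimizer works in this effect
space: quadratic underdose penalty below the prescription effect on the
PTV, quadratic overdose penalty above 110%, optional OAR maximum-dose
terms, L-BFGS-B with non-negativity bounds and weight variables rescaled to
O(1) (unscaled weights ~10⁶ produce gradients below the solver's
termination threshold). No plan normalization is applied. Verified against
central finite differences (10⁻⁴) and exhaustive grid search on a two-spot
problem.

The carbon reference radiation is calibrated per model from the midpoint
of a 6 cm SOBP at 21 cm range, optimized flat in biological effect (the
mixing ratios, hence the calibration, are invariant to the chosen effect
level). With the synthetic base data this yields α_ref = 0.3908 Gy⁻¹
(mMKM; β_ref = 0.0615 exactly) and α_ref = 0.3584, β_ref = 0.0581
(MCF MKM). The published carbon references (0.7554 and 1.019 Gy⁻¹)
correspond to a mixed z\*\_D of ≈ 9.5 Gy at the midpoint, which requires a
roughly three-fold larger stopping-carbon dose share than the synthetic
Bragg curves deliver (peak-to-plateau ≈ 2.5 at 21 cm after the ripple
smearing). Both calibrations are internally consistent — RBE = 1 at the
reference quality by construction — and the published values remain the
package defaults for users who want them.

## Evaluation

DVH metrics use linear interpolation between sorted voxel doses (D_p% is
the (1 − p/100) quantile); V_x is the fraction of voxels at or above x.
Percent differences suppress denominators below 1% of the global maximum
(zero-dose organs report absolute differences). Gamma analysis is global
(normalized to the reference maximum), 3%/3 mm, low-dose cutoff 10% of the
maximum, sub-voxel search on a 1/10-voxel lattice out to 3× the distance
criterion, with shell-ordered early termination; it matches an exhaustive
search oracle exactly on random grids. The metric's ref/eval asymmetry is
bounded (≤ 2 percentage points for distributions agreeing at the
few-percent level) but not zero.

## The water-phantom comparison experiment

A 42 mm cubic target centred in a 12×9×9 cm water box, parallel-opposed
beams, each field optimized independently with the MCF MKM to 5 Gy(RBE)
per fraction (the per-port prescription convention), physical dose frozen,
clinical dose recalculated with the mMKM, per-field clinical doses summed.
Problem size: ~36 000 voxels, ~2 200 spots per field, 46 machine energies;
the experiment runs in a few minutes on one CPU and is fully deterministic.

Measured outcome (seed 0): CTV D95 10.263 vs 10.262 Gy(RBE) (−0.01%),
gamma 3%/3 mm pass rate 100%, median voxel-wise relative difference 0.9%,
maximum 9.2% in the entrance region.

## Limitations

* Both models are fed by the *same* Kiefer–Chatterjee spectra. The real
  MCF MKM uses an analytical microdosimetric function calibrated to track-
  structure simulations, and both clinical models are anchored to the same
  measured survival data, which keeps their clinical-dose predictions
  within ~1.5% of each other. With shared KC spectra and the two distinct
  (α₀, r_d, R_n) parameter sets, the models' α(E) curves diverge by
  several percent at entrance qualities relative to the common mid-SOBP
  calibration — the origin of the 9% maximum entrance difference above.
  Target-level agreement (D95, gamma) is insensitive to this and matches
  the behaviour expected of the real model pair.
* The calibrated α_ref values are ~half the published ones (see above);
  absolute RBE values at the reference quality are exact by construction,
  but absolute α comparisons against published SOBP data inherit the
  synthetic base-data composition.
* Passing tests demonstrate internal consistency, conservation laws and
  oracle equivalence on synthetic data — not agreement with measured
  depth-dose, fragmentation or survival data.
* Beams are axis-aligned; there is no robust optimization, no CT/DICOM
  ingestion, no heterogeneity lateral scaling, and no cell lines beyond
  the single HSG parameter set.
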