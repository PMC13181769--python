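# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `sprgamma`.

## Optical model

Reflectivity of the layered sensor is computed with the standard
characteristic-matrix (Abelès) transfer-matrix method for p-polarized
plane waves, in double precision. Conventions:

* Time dependence `exp(-iωt)`, so absorbing media carry a **positive**
  imaginary permittivity; layers with negative imaginary parts are
  rejected at construction.
* The normal wavevector in each layer is the principal branch of the
  complex square root, sign-fixed (`Im kz ≥ 0`) so evanescent fields
  decay away from the prism. This keeps the lossless total-internal-
  reflection limit exact (R = 1 beyond the critical angle to 1e-9).
* All angles are internal incidence angles at the prism base, in
  degrees. Instrument angles are mapped onto internal angles by a
  single chip-level calibration: the effective prism permittivity is
  derived from a reference liquid of known permittivity through
  ε_prism = ε_ref / sin²θ_TIR. Because the same extraction is applied
  to the reference and the sample, any small systematic bias of the
  edge locator cancels in the bulk-permittivity fit (verified at the
  2e-4 level in the round-trip tests).
* Wavelength defaults to the HeNe line, 632.8 nm; it is a stack
  parameter, not a constant.

The implementation is verified against an independently coded Airy
two-interface closed form on random three-layer stacks at 1e-12, and
against the invariants R ∈ [0, 1], sublayer-splitting invariance, and
R + T = 1 for lossless stacks below the critical angle.

### Default chip parameters

Chip-specific optical constants vary between physical sensors and are
configuration, not constants. The packaged defaults (prism
ε = 3.19473, gold film ε = −6.159 + 2.211i, 47.5 nm) are an *effective
calibration*: the prism value is fixed by the critical-angle relation
at the reference operating point (edge at 49.53° for a bulk of
ε = 1.8489), and the metal parameters are tuned so the layer-free chip
couples at θ_SPR = 62.55° and a 1 nm layer of ε = 2.1070 shifts the
minimum by +0.13°. They form a self-consistent synthetic operating
point; they are not measured constants of any physical chip, and the
imaginary part in particular absorbs unmodelled loss channels
(adhesion layer, roughness) rather than representing pure gold.

## Feature extraction

**TIR edge.** Operationally defined as the maximum of the first
derivative of reflectivity versus angle. The locator first finds the
neighbourhood of the steepest slope on a Savitzky–Golay-smoothed
derivative (window 11 samples, quadratic), which is robust to
reflectivity noise, then re-maximizes the raw finite-difference
derivative within ±2 samples and refines with a 3-point quadratic fit
of the derivative. On clean synthetic data this recovers the analytic
critical angle to better than 0.01° at 0.01° sampling; under additive
reflectivity noise of σ = 0.002 the mean recovered edge stays within
0.005° of the noise-free value. A minimum-slope guard (0.05 /deg)
rejects scans with no genuine edge (e.g. no index contrast).

**SPR minimum.** The plasmon dip of these high-index liquids is broad
and extremely flat near its bottom (curvature ~0.02 /deg²), so a
3-point interpolation is noise-fragile. Instead a quadratic is fitted
by least squares to the raw reflectivity over ±1.5°, and the fit
window is re-centred on the fitted vertex until self-consistent; the
fixed point does not depend on where the initial smoothed-argmin guess
lands. The estimator is exact on polynomial dips, equivariant under
angle shifts, and repeatable to ≤0.01° (1σ) at σ_R = 0.002. Because
the dip is slightly asymmetric, the wide-window vertex carries a small
systematic offset (~0.07° at the default operating point); it is
common mode between index-matched pairs and between model and data in
feature-mode fitting, so differences and fits are unaffected. Ties in
the discrete minimum resolve to the smallest angle.

Default search windows: 48–52° (edge) and 60–66° (minimum), both
configurable.

## Inversion protocol

The default pipeline mirrors the two-stage index-matched analysis:

1. ε_bulk = ε_prism · sin²θ_TIR, with θ_TIR taken from the
   index-matched partner scan when available (fallback: the sample's
   own edge, flagged in the report). The partner is assumed to form no
   interfacial layer of its own — this is an assumption of the method,
   not a measured fact.
2. ε_interf of an interfacial layer of *assumed* thickness t (default
   1 nm) is the single free parameter, found by bounded scalar
   minimization (Brent, tolerance 1e-6 in ε, 200-iteration budget) of
   the mean squared reflectivity mismatch over the SPR window
   ("curve" mode) or of the squared minimum-angle mismatch ("feature"
   mode). Non-convergence raises; it is never silently returned.

A thin layer enters the optics approximately through the product
(ε_interf − ε_bulk)·t, so ε_interf and t cannot be decoupled from one
scan; `fit_full_curve` refuses to free both jointly. The same
compensation makes the downstream surface excess Γ insensitive to the
assumed t (<5% spread across t ∈ {0.5, 1, 2} nm in the tests).

Error amplification: since the layer is ~1 nm against an evanescent
decay length of ~60 nm, a bulk-permittivity error δε_b propagates into
the interfacial fit amplified by roughly the ratio of the two
sensitivities (~80×). The edge locator's noise floor therefore
dominates the ε_interf recovery spread (~0.01 at σ_R = 0.002); its
*bias* is an order of magnitude smaller.

`fit_full_curve` (expert mode) frees up to three named stack
parameters with bounded least squares, seeds deterministically at the
bound midpoints, and attaches a covariance estimate plus a Jacobian
condition number; conditioning above 1e8 is flagged.

Scans with arbitrary intensity units can be normalized to unit mean
over the pre-edge plateau (`normalize_scan`); synthetic scans are
already absolute.

## Composition chain

`cm_fraction(ε) = (ε − 1)/(ε + 2)` is matched to
ρ(x)·[x·r_gly + (1 − x)·r_water]. The two specific refractions are
calibrated from a packaged property table (`data/
glycine_solution_properties.csv`): r_water exactly from the water row,
r_gly by linear least squares over the solution rows. The table holds
(x, ρ, ε) for aqueous glycine at 22 °C, generated from standard
literature correlations — apparent molar volume
φV = 43.19 + 0.85·m cm³/mol, molar refraction 16.4 cm³/mol, water
density 0.99777 g/cm³ and ε = 1.7770 at the HeNe line, α-glycine
crystal density 1.607 g/cm³ — because the original calibration data
set is not redistributable. The numbers it yields are
handbook-consistent (e.g. n = 1.3511 for 10 wt% glycine) but carry a
calibration uncertainty of a few percent, which is why the reference
surface-excess value is quoted with a 40–60 ng/cm² acceptance band
around ~50.

Inversion ε → x is a bracketed Brent root find on x ∈ [0, 1]
(tolerance 1e-12), verified against a 1e-6-step grid-search oracle.
Permittivities below the pure-water value return x = 0 with a flag.
ρ(x) uses a monotone PCHIP interpolant through the table up to the
last tabulated composition (x = 0.20) and, above it — interfacial
compositions exceed saturation — extrapolates the apparent specific
volume of glycine linearly to the crystal value at x = 1. The
extrapolation functional form is a package choice; any smooth monotone
interpolation between the last tabulated density and the crystal
density changes Γ at the few-percent level.

Γ = t·[ρ(x_i)·x_i − ρ(x_b)·x_b] in ng/cm² (1 nm·g/cm³ = 100 ng/cm²);
negative excess (depletion) is reported as negative Γ. Unit
conversions: 1 ng/cm² = 1e-14 ng/nm²; number densities use
N_A/M with M = 75.07 g/mol for glycine.

Temperature is fixed at 22 °C throughout; there is no temperature
model.

## Density-profile analysis

Profiles are mass-density histograms in uniform 0.05 nm bins (default)
over wall distance, averaged over frames; binning conserves mass
exactly. Film width is the distance at which the solvent density first
falls below 0.1 g/cm³, scanning outward from the last bin above half
the bulk solvent density (the guard rejects near-wall depletion dips);
the crossing is interpolated linearly between bin centers. Interfacial
averages weight partial bins by window overlap. The surface excess
integrates (ρ − ρ_bulk) from the wall to the start of a user-chosen
bulk plateau region, with ρ_bulk the overlap-weighted plateau mean;
on plateau-bearing synthetic profiles the result varies <2% with the
plateau choice. Molecular masses default to 75.07 (solute) and 18.015
(solvent) g/mol; the particle reader documents a center-of-mass
convention for wall distances.

Raw MD engine trajectories are deliberately not parsed; inputs are
per-frame particle tables, the package's own profile text format, or
LAMMPS-style chunk-averaged text with an explicit column map.

## Synthetic data

The generators define the study conditions for all tests:

* **Chips**: metal thickness uniform in 46–50 nm, ±2% relative jitter
  on the metal permittivity, polystyrene coat 20–30 nm when present —
  an ensemble emulating chip-to-chip variation around the calibrated
  reference chip.
* **Scan pairs**: sample and reference share ε_bulk exactly (perfect
  index matching); additive Gaussian reflectivity noise, default
  σ = 0.002, matching the instrument-scale repeatability the analysis
  must tolerate; results clipped to [0, 1] with the clip rate
  recorded. Real instrument drift, bubbles and chip degradation are
  *not* emulated, so passing recovery tests demonstrates estimator
  correctness under well-behaved noise, not robustness to artefacts.
* **Films**: solute = bulk + Gaussian peaks (reference preset: two
  strong peaks at 0.35 and 0.70 nm, a weak one at 1.2 nm), solvent
  depleted one-for-one where solute is enriched, both cut off by a
  sigmoid film-vacuum edge (sharpness 0.05 nm) positioned so the
  0.1 g/cm³ criterion lands exactly at the requested width. Bulk
  densities default to a 250 g/kg solution (solute 0.216, solvent
  0.90 g/cm³). The preset can rescale its peak amplitudes so the
  first-nanometre solute average equals a requested value (reference:
  1.0 g/cm³ for the 12.95 nm film). Particle realizations draw z by
  inverse-CDF sampling; counts can be derived from the analytic mass
  so realized densities match in absolute units. Analytic profiles are
  an idealization of MD output: they contain no layering of the
  solvent, no frame-to-frame correlation, and no force-field physics,
  so they validate the *analysis*, not the simulations.

All generators are bitwise-reproducible from (parameters, seed), and
every output records its generating truth in metadata.

## Problem sizes

The test suite and acceptance checks run on synthetic data at desk
scale: 2500-point angle scans (0.01° steps), 100-pair Monte-Carlo
recovery ensembles, 200-replicate feature-noise ensembles, films up to
13 nm with up to 1e4 particles per frame and ≤100 frames. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* No dispersion models, s-polarization, ellipsometry, or multi-mode
  (waveguide) scans.
* The interfacial layer is a single homogeneous slab; graded profiles
  are outside the optical model.
* The composition chain is specific to binary glycine-water at 22 °C;
  other solutes need their own property table and refraction.
* Γ accuracy is limited by the property-table calibration (few
  percent) and, experimentally, by the index-matching assumption that
  the reference liquid forms no interfacial layer of its own.
* The absolute extracted θ_SPR carries the wide-window estimator
  offset described above; only differences and model-matched fits are
  bias-free.
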