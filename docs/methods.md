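# Methods

## Model

The package computes the size-weighted relevant fine fraction (SWeRF) of
a bulk powder: the mass fraction weighted by the EN 481 respirable
convention R(D), the probability that a particle of aerodynamic diameter
D, once airborne and inhaled, reaches the lungs' unciliated airways.
EN 481 is used in its form relative to total airborne particles,

    E_I(D) = 0.5 (1 + exp(−a D)),            a = 0.06 per µm
    R(D)   = E_I(D) (1 − Φ(ln(D/m) / ln g)),  m = 4.25 µm, g = 1.5,

the product of the inhalable convention and a lognormal complement. The
parametrization is fixed by the standard; the conformance checks are the
conventional anchors R(1 µm) = 97.1% and R(10 µm) = 1.3% (to ±0.05
percentage points, half a unit of the last printed digit). These anchors
discriminate this form from the pure lognormal complement, which would
give 99.98% at 1 µm. Probabilities are handled as fractions in [0, 1]
throughout; percent appears only at I/O boundaries.

### SWeRF from a PSD

Instruments report binned volume distributions, so SWeRF is a discrete
sum Σ P(bin)·R(D_rep) rather than a fitted-curve integral. The bin
representative is the geometric mean of the aerodynamic bin edges —
natural for the log-spaced binning of laser diffraction — with a zero
lower edge floored at 0.01 µm. Evaluating R at both edges and averaging
was rejected: it biases coarse-binned PSDs because R is convex over
typical bins. The refinement-stability test bounds the discretization
error: for ≥ 200 log-spaced bins over the support, the result agrees with
a 10×-refined computation within 1e−3 absolute.

The spherical-equivalent → aerodynamic conversion scales every edge by
√SG, or by √(effective density / 1000 kg m⁻³) when an effective density
is set (porous or hollow particles settle by their effective, not
skeletal, density). The basis is an explicit flag and double conversion
is an error, not a silent no-op. Volume and mass fractions are treated as
interchangeable within one uniform-density material; materials of
different density are combined at the component level (mass-weighted
SWeRF values), never by merging PSDs.

The crystalline-silica share SWeRF_CS = w_CS · SWeRF assumes the silica
shares the size distribution of the other minerals (homogeneity). Where
quartz, being harder than its matrix, concentrates in the coarse
fraction, this overestimates SWeRF_CS — conservative for hazard
classification; the sedimentation route is the alternative when the
assumption fails.

### Sedimentation equivalence

An initially homogeneous suspension column, settled for time t and
sampled over its top h, retains size-D particles with probability
S(D) = max(0, 1 − (D/D_c)²) under Stokes settling (v ∝ D²), where D_c is
the aerodynamic diameter that settles exactly through h in t. The
protocol is made equivalent to the convention by equating the integrals
of the two probability curves: ∫S dD over [0, D_c] is (2/3)·D_c, so

    D_c = 1.5 · ∫₀^∞ R(D) dD = 1.5 × 4.2810 µm = 6.4215 µm

for default parameters. The settling time follows from Stokes' law with
buoyancy, written in aerodynamic diameter (physical diameter
d = D_c √(ρ₀/ρ_p)):

    t = 18 η h ρ_p / (g (ρ_p − ρ_l) ρ₀ D_c²).

The unit density ρ₀ enters only through the aerodynamic definition. t is
computed with the extracted depth h (the layer whose survival function is
S), not the full column height. The uniform-PSD equivalence test pins the
construction: for a uniform PSD covering [0, 30] µm, the virtual
experiment and the convention weighting agree within 1e−3 absolute, and
for lognormal powders with aerodynamic medians 2–30 µm and GSD 1.5–2.5
the two routes stay within 0.05 absolute.

The gravimetric estimator SWeRF = m·H/(M·h) rescales the extracted
residue by the extracted share of the column. Ratios slightly above 1
arise from weighing noise and are clamped to 1 with a warning rather than
rejected. Estimates are invariant to rescaling all masses or both
heights.

## Parameters and defaults

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| inhalable_decay | 0.06 | per µm | decay of the inhalable convention |
| respirable_median | 4.25 | µm | median of the respirable lognormal cut |
| respirable_gsd | 1.5 | — | GSD of the respirable cut |
| quadrature upper limit | 100 | µm | R < 1e−9 there; a tail check rejects truncating limits |
| liquid (default) | water 20 °C | — | η = 1.002e−3 kg m⁻¹ s⁻¹, ρ_l = 998 kg m⁻³ |
| gravity, unit density | 9.81, 1000 | m s⁻², kg m⁻³ | physical constants |
| protocol | 5 g in 250 ml | — | solids ≤ 1% v/v; violation warns (advisory limit) |

Temperature is not modelled; viscosity and density are user inputs.
Convention parameters can be overridden through a flat YAML config
(`inhalable_decay`, `respirable_median`, `respirable_gsd`).

## Numerical choices

- Convention integral by adaptive quadrature (relative tolerance 1e−10,
  checked against a 0.01 µm trapezoid oracle); failure raises a
  numerical error rather than returning a degraded value.
- D_c from the closed form 1.5 × integral; no root finding needed.
- Classification thresholds (≥ 10% → STOT RE 1, ≥ 1% → STOT RE 2,
  otherwise none) compare full-precision values; rounding is for display
  only, so 0.96% never rounds into a hazard class. The 1% lower bound is
  taken as inclusive for category 2.
- Repeatability uses the sample (n−1) standard deviation; method
  agreement uses the squared Pearson correlation. Both choices reproduce
  the published validation statistics from the published series.
- Degenerate inputs (empty PSDs, non-settling particles ρ_p ≤ ρ_l,
  inverted geometry h > H, probabilities outside [0, 1]) raise domain
  errors; an already-aerodynamic PSD passed to the converter raises an
  invalid-state error.

## Synthetic data

The generator emulates the granulometry of milled mineral powders as
binned lognormal volume distributions (log-spaced bins over
median·gsd^±4, CDF differences, renormalized; the d50 of the result is
within 1% of the requested median). Spiked blends mirror the recovery
design of a silica-free base spiked with quartz flour, kept strictly at
the component level. The noisy sedimentation run applies multiplicative
Gaussian noise to the supernatant residue mass only — the dominant
gravimetric error (evaporation and weighing of tens of mg) — with column
heights exact; its ~9% relative SD default in tests is a fixture
convention inferred from the published repeatability scatter (SD
1.41 on mean 15.4), not a claim about any laboratory. Tests assert
statistics, not bit-streams, so results do not depend on the RNG
algorithm.

Not emulated: instrument optics (Mie/Fraunhofer), particle shape and
porosity distributions, flocculation and hindered settling, and
between-laboratory effects. Passing tests therefore demonstrate the
internal consistency of the two routes and the statistics under ideal
dispersion, not robustness to non-ideal laboratory behaviour.

Test problem sizes — 3000-bin uniform PSDs, 128–2000-bin lognormals,
200 seven-replicate noise batches, 100 000-draw Monte-Carlo cross-checks
— keep every suite within seconds while leaving discretization and
Monte-Carlo errors far below the asserted tolerances.

## Known limitations

- Platy minerals (talc, mica, kaolin) and swelling or reactive materials
  (bentonite, lime) need adapted dispersion; the package models ideal
  Stokes settling only and documents the caveat.
- Hydrophobic or floating powders (cenospheres, surface-treated) are
  outside the sedimentation model.
- The homogeneity assumption behind the calculated SWeRF_CS can
  overestimate the silica share of blends with coarse-concentrated
  quartz.
- The Stokes regime is assumed; a particle Reynolds number above ~0.3 at
  the cut diameter triggers a warning, not a correction.
- SWeRF quantifies a bulk-material property for classification and
  labelling; it does not predict airborne workplace exposure.
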