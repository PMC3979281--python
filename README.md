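# swerf

Size-weighted relevant fine fraction (SWeRF) of bulk powders, for
classification and labelling of materials containing respirable
crystalline silica.

## The problem

Occupational exposure to respirable crystalline silica (RCS) causes
silicosis, and the EU CLP regulation (EC 1272/2008, aligned with the UN
GHS) classifies the *fine fraction* of crystalline silica as a specific
target organ toxicant (STOT RE, lung). A producer therefore has to
quantify, in a bag of powder, the mass fraction of crystalline silica
that *would be* respirable if the powder became airborne — even though
nothing in the bag is airborne. The SWeRF method resolves this by
weighting each particle of the bulk material by its EN 481 probability of
reaching the lungs' unciliated airways.

This package is for occupational-hygiene and product-stewardship
scientists who have either a laser-diffraction particle size distribution
(PSD) or a gravimetric sedimentation measurement, and need the SWeRF, the
silica share SWeRF_CS, and the resulting STOT RE category.

## The method

**From a PSD.** The EN 481 respirable convention, expressed relative to
total airborne particles, is

```
E_I(D) = 0.5 (1 + e^(−0.06 D))                      inhalable convention
R(D)   = E_I(D) · [1 − Φ(ln(D/4.25 µm) / ln 1.5)]   respirable convention
```

with D the aerodynamic diameter in µm and Φ the standard normal CDF
(R(1 µm) = 97.1%, R(10 µm) = 1.3%). Laser diffraction reports the
spherical-equivalent diameter d, converted by `D = d·√SG` (SG = specific
gravity; effective density for porous particles). Then

```
SWeRF = Σ_bins P(bin) · R(D_bin),    SWeRF_CS = w_CS · SWeRF
```

with P the bin mass fraction, D_bin the geometric mean of the
aerodynamic bin edges, and w_CS the crystalline-silica mass fraction
(homogeneity assumption). Blends combine linearly by component mass.

**By sedimentation.** Fine particles also stay longest in suspension.
Dispersing the powder in a liquid column and extracting the top h after a
settling time t realises a survival curve `S(D) = max(0, 1 − (D/D_c)²)`
(Stokes settling, v ∝ D²). Choosing the cut diameter so that the two
probability curves have equal integrals,

```
D_c = 1.5 · ∫ R(D) dD ≈ 6.42 µm,
t   = 18 η h ρ_p / (g (ρ_p − ρ_l) ρ_0 D_c²),
```

makes the experiment equivalent to the convention weighting. The
gravimetric estimate is `SWeRF = m·H / (M·h)` from the dispersed mass M,
supernatant residue m, column height H and extraction depth h; with the
silica fraction f_CS of the residue (FT-IR/XRD), `SWeRF_CS = SWeRF·f_CS`.

**Classification.** SWeRF_CS ≥ 10% w/w → STOT RE 1; 1–10% → STOT RE 2;
below 1% → not classified.

## Worked example

Generate a synthetic quartz flour (lognormal volume PSD, median 3 µm,
GSD 2) and evaluate it:

```python
import swerf
psd = swerf.lognormal_psd(swerf.LognormalSpec(median=3.0, gsd=2.0))
swerf.write_psd(psd, "quartz_flour.csv")
```

```
$ swerf calc --psd quartz_flour.csv --sg 2.66 --cs-fraction 1.0
SWeRF: 39.4%
SWeRF_CS: 39.4%
Classification: STOT_RE_1
```

39.4% of this flour's mass, size-weighted by the respirable convention,
is relevant fine fraction; as the flour is pure quartz, SWeRF_CS equals
SWeRF and the material exceeds the 10% generic concentration limit.

Plan the equivalent sedimentation run for quartz in water, extracting
the top 50 mm:

```
$ swerf sediment-plan --sg 2.66 --h 50
Cut diameter D_c: 6.422 um (aerodynamic)
Settling time t: 3568 s (00:59:28)
```

Evaluate a gravimetric measurement (5 g dispersed, 100 mg residue in the
top 40 of 200 mm, 28.3% quartz in the residue):

```
$ swerf sediment-eval -M 5000 -m 100 --column-height 200 --extract-height 40 --f-cs 0.283
run 1: SWeRF 10.0%, SWeRF_CS 2.8%, STOT_RE_2
```

`swerf simulate` writes synthetic PSD and measurement CSVs, `swerf
report` renders a results table (markdown or versioned JSON) with the
classification column, and `swerf classify` applies the limits directly.

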