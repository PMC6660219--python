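# conetopo

Analysis of foveal cone photoreceptor topography from adaptive-optics
retinal images, and of how it depends on eye length.

Adaptive-optics scanning laser ophthalmoscopy (AOSLO) resolves individual
cone photoreceptors at the foveal center. Given labeled cone coordinates,
per-eye ocular biometry and fixation traces, this package computes the
quantities that characterize foveal sampling and its dependence on axial
length in myopia:

* **Retinal magnification** — a four-surface paraxial schematic eye,
  individualized by each eye's corneal front radius, anterior chamber depth
  and axial length *x*, locates the secondary nodal point *AN′* and gives
  the retinal magnification factor `RMF = 1000·tan(1°)·(x − AN′)` µm/deg,
  the bridge between angular (cones/deg²) and linear (cones/mm²) density.
* **Density topography** — sliding circular sampling windows (10 arcmin
  diameter, boundary-inclusive counting) produce continuous density maps,
  the peak-density location, and eccentricity profiles in 5-arcmin or
  25-µm annuli and along the horizontal/vertical meridians.
* **Fixation** — the preferred retinal locus (PRL) is the centroid of the
  fixation scatter; stability is the bivariate contour ellipse area
  `BCEA = π·k·√det(Σ)` with `k = χ²₂(0.68) ≈ 2.279`.
* **Sampling limits** — hexagonal-packing Nyquist limit
  `N = ½·√(2D/√3)` cyc/deg and center-to-center spacing `s = 60/(√3·N)`
  arcmin from angular density *D*.
* **Cohort statistics** — simple linear regressions of density on axial
  length with slope CIs and p-values, one-eye-per-subject sensitivity
  reruns, and a sample-size calculation for detecting a regression slope.
* **Synthetic ground truth** — quasi-hexagonal mosaics with controlled
  radial density falloff, Gaussian fixation scatter, and whole cohorts
  generated under three eye-growth models (global expansion, equatorial
  stretching, over-development), so every stage is testable end to end.

A 28-eye reference cohort (biometry, RMF, peak and PRL cone densities) is
packaged as a CSV fixture and drives the validation suite.

## Worked example

Headline regressions over the packaged reference cohort:

```bash
conetopo cohort --out regressions.csv
```

```
peak angular density vs axial length: slope 756.0 (95% CI 308.3 to 1203.7), p=0.001826, r^2=0.32
peak linear density vs axial length: slope -9901.6 (95% CI -14619.0 to -5184.2), p=0.0002051, r^2=0.42
PRL angular density vs axial length: slope 759.4 (95% CI 198.0 to 1320.9), p=0.009961, r^2=0.23
PRL linear density vs axial length: slope -8488.6 (95% CI -14558.6 to -2418.6), p=0.007963, r^2=0.24
```

Angular cone density *rises* with axial length (~750 cones/deg² per mm)
while linear density *falls* (~−9,900 cones/mm² per mm): longer eyes are
stretched at the fovea, but not in proportion to their length, so myopic
eyes retain — indeed gain — angular sampling resolution. Both trends are
significant (p < 0.01).

Generate a synthetic mosaic and map its density:

```bash
conetopo generate --kind mosaic --seed 1 --out cones.csv --peak-density 15000 --extent 40
conetopo density --cones cones.csv --rmf 278.45 --step 8 --out map.csv
# peak 13980 cones/deg^2 (180309 cones/mm^2) at (180.0, 192.1) px
```

The recovered peak sits at the mosaic center and within ~7% of the
generating 15,000 cones/deg² (the 10-arcmin window averages over the
falloff around the peak). Library use mirrors the CLI:

```python
import conetopo as ct

eye = ct.Biometry(axial_length_mm=23.30, corneal_front_radius_mm=7.80, acd_mm=3.12)
print(ct.rmf_from_biometry(eye).rmf_um_per_deg)   # 278.45 um/deg
print(ct.nyquist_limit(15851.0))                  # 67.6 cyc/deg
```

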