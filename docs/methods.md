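# Methods

This note records the models implemented, the parameter choices that
matter, and the conventions adopted where more than one reasonable design
existed. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Schematic eye and retinal magnification

Angular-to-linear conversion uses the relation `I = tan(1°)·(x − AN′)·θ`,
where `x` is axial length, `AN′` the distance from the corneal apex to the
secondary nodal point, and `θ` the visual angle in degrees; the retinal
magnification factor (RMF) is `1000·tan(1°)·(x − AN′)` µm/deg.

`AN′` comes from paraxial reduction of a four-surface eye, individualized
per subject by three measured quantities (corneal front radius, anterior
chamber depth, axial length). Fixed constants:

| parameter | value | note |
|---|---|---|
| corneal back radius | 88.31% of front | Gullstrand ratio |
| corneal thickness | 0.5 mm | Gullstrand |
| n cornea / aqueous / vitreous | 1.376 / 1.336 / 1.336 | Gullstrand |
| lens radii | +10.0 / −6.0 mm | Gullstrand (unaccommodated) |
| lens thickness | 3.6 mm | Gullstrand |
| lens equivalent index | **1.40** | calibrated, see below |

ACD is interpreted IOLMaster-style (corneal front apex → lens front), so
the aqueous gap is `ACD − 0.5 mm`. Sign convention: light travels +z;
radii are positive with the center of curvature to the right of the
vertex. The system matrix acts on `(height, n·angle)`; the equivalent
power is `−C`, the back focal point lies `−n′A/C` behind the last vertex,
and `AN′` sits one front focal length (`1/P`, object space in air) in
front of it. An explicit surface-by-surface ray trace is kept independent
of the matrix reduction so the nodal-point property (a ray aimed at the
first nodal point exits at an unchanged angle, appearing to come from
`AN′`) can be cross-checked to 1e−9 mm.

The lens equivalent index is the one constant the three measured inputs
cannot pin down. It was calibrated once against the 28-row reference
biometry/RMF table: 1.40 gives a maximum relative RMF error of 0.31% with
near-zero mean bias (1.416 would give 0.47%); it was then frozen. The
Bennett reduced-eye approximation `RMF = 13.06·(x − 1.82)` µm/deg is
provided for comparison; because it assumes the ocular focal point falls
on the retina, it overestimates RMF for short eyes and underestimates it
for long eyes relative to the trace.

## Density mapping

Density at a point is the count of cone centers at distance ≤ r from it
(boundary inclusive) divided by the window area, with the default window
10 arcmin in diameter. Distances are computed in pixels through the
angular scale (default 9.48 px/arcmin) with a k-d tree; an all-pairs
brute-force count is the test oracle. Linear density derives from angular
density through `(RMF/1000)²` by default; a fixed-micron-window mode
(`window_density_um`) is provided as well because the reference table's
peak angular and linear columns are mutually inconsistent through its RMF
by up to ~1.6%, which is what one would observe if the two columns were
measured in separately defined angular and micron windows. Neither mode is
asserted to be "the" original; the PRL columns are exactly consistent with
plain conversion.

Windows (or annuli) that cross the data boundary are flagged invalid
rather than area-corrected, so peak finding and profiles stay interior to
the labeled region. Peak location ties resolve to the centroid of the
maximal set (relevant only for degenerate flat maps). Annuli are
inner-exclusive / outer-inclusive with the innermost disk including its
center; widths default to 5 arcmin (angular) and 25 µm (linear). The map
grid step defaults to 1 px; tests and the CLI use coarser steps (4–16 px),
which changes peak estimates by well under the window-induced smoothing.

Note that a 10-arcmin window reports the density profile smoothed over the
window: on a profile that falls off around the peak, the mapped maximum is
a few percent below the underlying point-wise peak. Tests therefore
compare against window-averaged ground truth.

## PRL and fixation stability

The PRL estimate is the mean of the fixation scatter; the stability
ellipse is the sample-covariance ellipse scaled by `k = χ²₂(coverage)`
(≈ 2.2789 at the default 68% coverage), giving `BCEA = π·k·√det(Σ)`. The
k constant is always computed from the χ² quantile so other coverages
work. Because "an ellipse containing 68% of points" is ambiguous between
this parametric construction and literal containment, an empirical mode
dilates the covariance ellipse until it contains exactly `⌈0.68·n⌉`
points. A zero-variance (or collinear) trace yields BCEA 0 with a warning
rather than an error. No temporal filtering or outlier rejection is
applied to traces. BCEA in µm² is the arcmin² value times
`(RMF/60)²`.

## Sampling limits

For a hexagonal mosaic of angular density D, the Nyquist limit is
`N = ½·√(2D/√3)` cyc/deg and the center-to-center spacing
`s = 60/(√3·N)` arcmin, tied by the exact identity `s·N·√3 = 60`. The
approximate Snellen equivalent is `20/(20·30/N)` from the primary spatial
frequency of a letter E.

## Cohort statistics

Regressions are plain OLS with t-based slope CIs and two-sided p-values
(n−2 df), cross-checked against the textbook normal-equation formulas to
1e−10. Both eyes of a subject are pooled as independent observations for
the headline numbers — a deliberate simplification whose guard is the
one-eye-per-subject sensitivity rerun (`first` or seeded `random`
selection). No multiple-testing correction is applied. The sample-size
calculation uses the normal approximation
`n = (z₁₋α/2 + z_power)²·σ²ε/(λ²·σ²x)`; the predictor SD defaults to
1.65 mm (a plausible axial-length spread for a cohort spanning ~5.5 mm,
and the value under which the reference planning inputs give n ≈ 32) and
is exposed as a parameter.

On the packaged 28-eye table, plain OLS yields r² = 0.417 for peak linear
density vs axial length and 0.317 for peak angular density; the
angular-density slope computed from unit-consistent angular values
(linear column × (RMF/1000)²) is 749 with 95% CI (304, 1194), while the
tabulated angular column gives 756 (308, 1204) — the difference traces to
the column inconsistency discussed above.

## Synthetic data

The mosaic generator produces quasi-hexagonal blue-noise point sets by
variable-radius dart throwing: candidates are drawn proportional to the
target density profile `D(r) = peak/(1 + (r/r₀)^γ)` (with vertical radii
scaled by an anisotropy factor), sorted by radius so the dense center
fills first, and accepted when no prior point lies within
`0.86·s_hex(D(r))`, where `s_hex = √(2/(√3·D))` is the hexagonal spacing.
The 0.86 factor was measured once on constant-density fields (this sweep
variant packs denser than plain random sequential adsorption) and frozen;
with it, measured window densities recover the generating profile within
~5%. Defaults `r₀ = 30 arcmin`, `γ = 1.2`, anisotropy 1.15 (steeper
vertical falloff) are test-fixture conventions that qualitatively mimic
real foveal falloff, not biological claims. The generator refuses profiles
implying spacing below 0.05 arcmin (duplicate-label territory).

Cohorts are generated under three growth models anchored at a baseline eye
(axial length 23.5 mm, fixed anterior segment r = 7.8 mm, ACD = 3.6 mm):
global expansion (angular density constant in axial length), equatorial
stretching (linear density constant), and over-development (linear density
growing as `exp(gain·ΔAL)`, default gain 0.02/mm). A continuous blend
exponent α interpolates the first two (`D_ang ∝ RMF^2α`); α ≈ 0.44
produces angular-density slopes in the ~750–820 cones/deg²/mm range for
cohorts spanning 22–27.5 mm. Noise is multiplicative log-normal (default
fractional SD 0.08, a realistic between-eye measurement scatter); the same
draw multiplies the angular and linear values of an eye because they
describe the same mosaic. PRL displacement is Rayleigh with mean 6.1
arcmin and PRL density is 0.95 of peak with half-scale noise. All
randomness flows from one `numpy` Generator seeded by the caller.

What the generator does *not* emulate: optical blur and labeling error,
spatially correlated density fluctuations, anisotropic eye growth within a
subject, and inter-eye correlation within subjects (synthetic eyes are
independent even when they share a subject ID). Passing
generator-recovery tests therefore demonstrates correctness of the
measurement pipeline, not robustness to every property of real AOSLO
data.

## Problem sizes used by the test suite

Synthetic mosaics in tests span 20–90 arcmin with 2,000–7,000 cones;
density maps use 8–16 px grid steps; the BCEA closed-form check uses 10⁴
fixation samples; the slope-recovery experiment uses 200 replicate
cohorts of 28 eyes. These sizes give sampling error comfortably inside
the stated tolerances while the whole suite runs in well under a minute.

## Known limitations

* The schematic eye is paraxial and unaccommodated; no astigmatic or
  chromatic terms.
* Fixed-micron and fixed-arcmin window modes bracket, but cannot settle,
  how the reference densities were originally windowed.
* The pooled-eyes regression understates standard errors when inter-eye
  correlation is present; the sensitivity rerun checks sign and
  significance, not effect-size calibration.
* Generated mosaics are blue-noise rather than crystalline-hexagonal;
  local spacing statistics are matched in mean, not in orientational
  order.
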