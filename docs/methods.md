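# Methods

This note documents the models, conventions and numerical choices behind
`chromalight`, a package for colorimetric analysis of spectral surveys of
natural daylight and natural-object surface properties.

## Spectral data model

All spectra are sampled functions of wavelength on uniform grids with
channel centres in nm, endpoints inclusive. Two canonical grids are used:
380–780 nm at 5 nm (81 channels; surface reflectance and transmittance)
and 380–780 nm at 1 nm (401 channels; daylight radiance and irradiance).
Integrals against standard observer functions are Riemann sums
`Σ value(λ)·table(λ)·Δλ`, the standard quadrature for tabulated
colorimetric data; it is exact for the flat and monochromatic reference
cases used in tests. Resampling between grids is linear interpolation
with extrapolation refused. Reflectance and transmittance estimates are
channelwise ratios of paired measurements; ratio values above 1 are
physically possible under measurement noise and are kept (and logged),
never clipped, because silent clipping would bias chromaticities.

## Standard tables and their provenance

The CIE 1931 2° colour-matching functions are vendored as a CSV fixture at
their native 5 nm tabulation, and the CIE daylight-model components
S0/S1/S2 at their native 10 nm tabulation (linearly interpolated to
working grids, the rule recommended for that table). CMF interpolation to
1 nm uses a shape-preserving monotone cubic, clipped at zero.

Cone fundamentals in the Stockman–Sharpe (CIE 2006/170-2) convention are
*derived at load time* from the colour-matching functions through the
inverse of the published cone-fundamental ↔ XYZ 3×3 transform

    x̄ = 1.94735469·l̄ − 1.41445123·m̄ + 0.36476327·s̄
    ȳ = 0.68990272·l̄ + 0.34832189·m̄
    z̄ = 1.93485343·s̄

Consequences of this construction:

* the luminance identity `kL·l̄ + kM·m̄ = ȳ` holds exactly, with
  kL = 0.68990272 and kM = 0.34832189 (the 1.980647:1 ratio of the
  cone-fundamental luminous efficiency function);
* equal-energy white lands at MacLeod–Boynton l = L/(L+M) = 0.7078
  structurally, because a flat spectrum has X = Y = Z under any
  CMF normalization;
* the s-axis scaling kS is computed once per working grid so that
  s(equal-energy white) = 1.000 exactly, the conventional normalization.

Because the transform is applied to the 1931 observer rather than the
2006 observer's own XYZ tables, the derived fundamentals are an
approximation to the directly tabulated ones; relative differences are
largest below ~470 nm. All chromaticity relations inside the package
(spectral locus, gamut, MacLeod–Boynton vs (x, y)) are mutually
consistent by construction. Luminance uses the 683 lm/W maximum luminous
efficacy, giving cd/m² for radiance input and lx for irradiance input.

## Near-duplicate filtering

Banks of reflectances are cleaned with a Pearson-correlation filter
(threshold r = 0.999 across the 81 channels of the surface grid). The
sweep is greedy in input order: a sample is removed when it correlates
above threshold with any *earlier kept* sample, so the first member of a
duplicate group survives and transitive chains (A~B, B~C, A≁C) keep A and
C. This makes the rule deterministic and idempotent. The filter is
applied across categories globally. Constant (zero-variance) spectra have
an undefined correlation; they are kept and reported separately.

## Optimal colors and the object-color gamut

An optimal color is a 0/1 reflectance with at most two spectral
transitions. Transitions live on channel boundaries (a band covers the
half-open interval [λ1, λ2) of channel centres), which removes any
ambiguity about transitions "at" a wavelength on sampled data. The
enumeration renders every band-pass and band-stop reflectance on a
transition grid (default 5 nm, matching the surface data; a refinement
property test documents that finer grids only raise the envelope) under a
given illuminant, computing CIE (x, y), MacLeod–Boynton (l, s) and
luminance relative to the illuminant. The all-pass case reproduces the
illuminant itself (relative luminance 1, the peak of the surface); the
all-stop case has no chromaticity and is excluded.

The gamut envelope bins the optimal-color cloud into uniform square
chromaticity bins (default width 0.005 per axis) and stores the per-bin
luminance maximum. Because the cloud is a discrete point set, bins
between points can be empty; envelope lookups therefore use the nearest
*occupied* bin (KD-tree on bin centres), with queries far from all
occupied bins treated as outside the envelope support. Containment of a
measured point is luminance ≤ envelope at its bin, with a 1e-9 tolerance
so that the all-pass equality case counts as inside.

## CCT estimation

The correlated color temperature of a chromaticity is the temperature of
the nearest Planckian radiator in CIE 1960 (u, v). Planckian spectra use
`B(λ,T) ∝ λ⁻⁵/(exp(c2/λT) − 1)` with c2 = 1.4388×10⁻² m·K, rendered
through the same CMF tables as every other spectrum (so CCT inversion is
exact with respect to the package's own observer). The search uses a
cached 256-point log-spaced sweep of 10³–10⁶ K to bracket the minimum,
then bounded scalar minimisation on log10 T (tolerance 10⁻⁸), which is
deterministic and accurate to well under 1 K at daylight temperatures.
The (u, v) distance to the locus is reported; beyond 0.05 the CCT is
flagged unconverged (forest-filtered chromaticities are far off-locus and
must not silently yield meaningless temperatures), though the value is
still returned.

CIE daylight spectra are synthesized from a target CCT via the standard
two-branch x_D(T) polynomial (branch split at 7000 K, domain
4000–25000 K), the daylight-locus relation
y = −3.000x² + 2.870x − 0.275, and component weights M1, M2 kept at full
precision (no historical rounding to three decimals), so synthesized
chromaticities track the locus to ~1e-4.

## Daylight record analysis

Low-signal filtering removes records strictly below 10 cd/m² (radiance
conditions) or 10 lx (irradiance conditions); a record exactly at the
threshold is kept. Sun/shadow pairing matches total-daylight and
skylight records by timestamp: candidate pairs within a 15-minute
tolerance are taken greedily in order of increasing gap, each record used
at most once. Paired CCT and log10 level series are compared with
one-tailed Welch t tests (no equal-variance assumption,
Welch–Satterthwaite degrees of freedom); the tested directions are
skylight CCT above total daylight and skylight level below it, the
directions in which the physics of a clear sky points. The quadratic
chromaticity-locus fit is ordinary least squares of y on (x², x, 1);
orthogonal-distance or x-weighted fitting was considered and rejected as
unnecessary for the survey's narrow x range.

## Characteristic-vector (PCA) decomposition

Daylight ensembles are decomposed by SVD of the (n_spectra × n_channels)
matrix. The default is the *uncentered* characteristic-vector
construction — the first component then plays the role of the mean
daylight spectrum, matching the classical daylight-basis construction —
with conventional mean-centred PCA available. For uncentered analyses
"variance explained" is taken about zero (total sum of squares); this is
stated explicitly because the term is ambiguous without centring.
Eigenvector signs are pinned non-negative at 560 nm for determinism.
For comparison across decompositions, components are shifted to minimum
zero and normalized to 1.0 at 580 nm; comparisons report RMS difference
plus mean signed differences in the 380–480 nm and 680–780 nm bands.
The daylight-model reference vector for these comparisons is
configurable (any normalized vector is accepted); the pipeline uses the
model's mean-daylight component.

## Synthetic study generator

The generator emulates the *statistical structure* of the measured
survey, not its data: the shapes and moments it encodes are those the
survey reports, and passing tests show that the pipeline recovers such
structure, not that it reproduces any particular measurement.

* **Reflectance bank** — 359 samples composed as flower 200, leaf 113,
  fruit 23, vegetable 6, bark 8, stone 9, of which 52 are constructed
  near-duplicates (a copy plus Gaussian noise of sd 5×10⁻⁵, correlation
  > 0.999 by construction) appended after their sources. Distinct
  samples are rejection-sampled to stay below r = 0.9985 pairwise so that
  the 0.999 filter removes exactly the duplicates. Category recipes:
  flowers mix 1–2 Gaussian bumps with a long-wavelength sigmoid edge and
  an occasional whitish template (widest chromatic spread); leaves a
  ~550 nm green bump plus a strong red-edge rise beyond ~690 nm; fruit
  sigmoid edges between 555 and 640 nm; bark low curved ramps; stones
  near-flat with gentle slopes and broad low-amplitude bumps. A second
  rejection rule discards any candidate that would be a bright saturated
  green (MacLeod–Boynton l < 0.63 at relative luminance > 0.65 under
  equal-energy white), encoding the survey's reported gap in the natural
  color distribution with a small safety margin inside the scanned
  region (l < 0.62, luminance > 0.7).
* **Leaf transmittance** — two-peaked: a green bump near 550 nm, a
  chlorophyll absorption dip, then a NIR red edge (sigmoid near 720 nm
  plus a final upswing above 740 nm) capped at an overall level of 0.4;
  front-up and back-up variants differ by a smooth multiplicative
  factor.
* **Diurnal daylight** — solar elevation is sinusoidal over the day
  length. Total daylight is a luminance-weighted mixture
  `w·D(CCT_sun) + (1−w)·D(CCT_sky)` of two daylight-model spectra with
  the sun weight w = 0.2 + 0.75·elevation; the paired skylight (shadow)
  record is the sky term alone, so its level is below the total by
  construction and its CCT above it. Sunny days use CCT_sun ≈ 5500 K and
  CCT_sky = 8500 + 3000·elevation K, producing a U-shaped total-CCT
  course and an inverted-U skylight course; cloudy days drive both
  conditions with one overcast profile (9300 − 3200·elevation K) capped
  below 10000 K. A small clock-linear CCT drift (25 K/h) keeps the daily
  extremum unique under near-symmetric sampling. Sampling is dense near
  sunrise/sunset and hourly otherwise; levels scale as elevation^1.6
  (peak ~9000 cd/m²) with a dawn haze floor, deliberately pushing a few
  dawn/dusk records below the 10 cd/m² filter. Level noise is
  multiplicative log-normal (sd 5%); spectral shape is noise-free, since
  chromaticity variation in such series is dominated by the mixture, not
  by shape noise.
* **Site circuit** — five sites visited in sequence in five sessions.
  Open sites share a session daylight spectrum with per-site intensity
  factors and small CCT offsets; the forest site sees
  `(1−g)·D·T_canopy^p + g·D` — canopy-transmitted light plus a fraction
  g = 0.10 of unfiltered gap light — with the canopy transmittance the
  average of 12 leaf draws raised to p = 1.2, rescaled so the open/forest
  illuminance contrast is 51-fold. This yields forest chromaticities
  ~0.03–0.05 above the daylight locus in y (off-locus, greenish) and a
  spectral maximum at 780 nm.
* **Determinism** — every generator draws from its own stream seeded by
  (seed, CRC32 of the generator name), so adding a generator never
  perturbs another and fixed seeds give byte-identical CSV output.

What the generator does *not* model: atmospheric radiative transfer,
aerosols and the solar-elevation dependence of the real sky spectrum
beyond the daylight model's reach; spectral measurement noise;
directional (BRDF) surface effects; seasonal vegetation change. Passing
the pattern-recovery tests therefore shows the pipeline recovers the
intended structure, not that these physical processes are captured.

## Problem sizes and runtime choices

The default study (359 surfaces, 4 diurnal days of ~38 records each, 50
site records) runs the full pipeline in a few seconds. The optimal-color
oracle test uses a 20 nm transition grid (2×(21 choose 2) + degenerate
cases) where exhaustive enumeration is cheap; envelope properties are
verified at 5 nm. The Monte-Carlo unbiasedness check of the locus fit
uses 200 replicates at n = 452 points, and the empirical gamut-bound test
10 000 random reflectances.

## Known limitations

* The cone fundamentals are matrix-derived from the 1931 observer, not
  the directly tabulated 2006 fundamentals (see above); MacLeod–Boynton
  coordinates of strongly short-wavelength-dominated spectra shift
  accordingly, while anchor points (equal-energy white) are exact.
* CCT is defined via CIE 1960 (u, v) nearest distance; other metrics
  (e.g. CIE 1931 minimum-distance variants) would differ slightly far
  off-locus.
* The synthetic locus fit covers a narrower chromaticity range than a
  year-scale measured survey, so its fitted quadratic coefficients are
  not comparable to measured-survey fits; the fit machinery itself is
  validated by exact and Monte-Carlo recovery tests instead.
* `fill_gap_linear` repairs only a single contiguous gap per call.
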