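# Methods

## The measurement problem

A spectrally resolved blue-light FAF device (excitation peak ~450 nm)
records retinal autofluorescence simultaneously in a short-wavelength band
(500–560 nm, the green-emitting fluorophore component, GEFC) and a
long-wavelength band (560–700 nm, REFC, dominated by lipofuscin). The
color-coded export is an 8-bit two-plane raster (native 4608 × 3288 px,
15 µm/px lateral sampling, no blue plane). Two endpoints are quantified in
concentric macular sectors: the percentage of pixels classified as GEFC
(area fraction) and the mean green-channel brightness, and both are
assessed for test–retest repeatability across two sessions.

## Pixel spectral features and GEFC classification

The manufacturer's pixel → (intensity, wavelength) mapping is proprietary.
We adopt the simplest convention consistent with a two-band measurement:
total intensity `G + R` (0–510) and an emission-wavelength estimate by the
band-centroid weighted mean

    λ(G, R) = (λ_G·G + λ_R·R) / (G + R),   λ_G = 530 nm, λ_R = 630 nm,

with λ undefined at zero intensity. The centroids sit at the midpoints of
the two detection bands and are configurable. A pixel is GEFC when its
intensity and wavelength fall in a closed selection window; the default
window is the full green band at any positive intensity, which reduces to
`G > 0 and 7R ≤ 3G`. Because "a GEFC signal at any intensity" is also
readable as "green channel positive regardless of red", that alternative
(`green-positive`) classifier is implemented and selectable; the centroid
rule is the default because it respects the wavelength axis of the
device's intensity/wavelength display. Interval endpoints are inclusive
(required for bit-exact masks), and no smoothing, morphology or minimum
blob size is applied.

## Sector topography

The macula is the 6.0 mm diameter circle centred on the fovea anchor
(an input, not detected). Subfields follow the concentric ETDRS-style
rings: fovea = central 1.5 mm disk, parafovea = 1.5–3.0 mm annulus,
perifovea = 3.0–6.0 mm annulus. Although the rings are conventionally
quoted by outer diameter (1.5/3.0/6.0 mm), annuli are the only reading
under which the three sub-field fractions are distinct measurements; a
nested-disk mode exists for sensitivity analysis. Membership is by
pixel-centre distance in mm, inclusive inner radius, strictly-less outer
radius — this makes the three rings an exact partition of the macular
disk, so the macular GEFC count is identically the sum of the ring counts.
No eccentricity/distortion correction is applied (a single lateral
resolution is assumed across the field). Sector intensity is the mean of
*all* green-plane pixels in the sector, not only the GEFC-classified ones.

## Repeatability statistics

For n subjects × 2 sessions, with d_i the signed difference and m_i the
session mean of subject i:

* **ICC(A,1)** — two-way random effects, absolute agreement, single
  measurement: `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`
  from the subjects × sessions ANOVA. F-based confidence intervals are
  available (`icc_confidence_interval`) but are not part of the standard
  report.
* **CR** (95% coefficient of repeatability) = `1.96 · SD(d)` (sample SD,
  n−1): the value below which the difference between two measurements lies
  in 95% of cases. This is the direct operational definition; it equals
  the common `1.96·√2·within-subject SD` form when the mean difference is
  zero.
* **CV%** — root-mean-square within-subject method,
  `100·sqrt(mean_i(s_i²/m_i²))` with `s_i² = d_i²/2` for k = 2. Undefined
  (typed error) when any subject mean is ≤ 0.
* **Mean absolute intraobserver variability** = `mean_i |d_i|`.
* **Bland–Altman** — points (m_i, d_i), limits of agreement
  `mean(d) ± 1.96·SD(d)`.

Degenerate inputs (zero total variance for ICC, nonpositive scale for CV)
raise typed errors rather than returning NaN. Note that on any dataset
`CR = 1.96·SD(d) ≥ 1.96·(mean|d| − |mean d| adjustments)` — in particular
CR can never be an order of magnitude *below* the mean absolute
variability; reported instrument-repeatability tables that violate this
cannot be reproduced by any standard definition, so this package pins the
formulas above and treats such tables as qualitative context only.

## Cohort comparisons

Session-1 values feed the group analyses. Quartiles use linear
interpolation between order statistics (the common statistical-package
default; stated because median/IQR depend on it). The Friedman statistic
uses within-subject mid-ranks with the standard tie correction (Conover
form), χ² reference with m−1 df; an all-tied table returns Q = 0, p = 1.
Pairwise follow-up is the Wilcoxon signed-rank test (zeros dropped;
all-zero differences → p = 1), reported with both raw and
Bonferroni-adjusted p — the choice of post-hoc procedure and correction is
genuinely open in this design, so both columns are emitted. The age
comparison is Mann–Whitney U (U = pairs where group A exceeds B, ties ½),
exact when `n_A·n_B ≤ 400` and tie-free, otherwise normal approximation
with tie and continuity corrections; the age dichotomy defaults to
25 years. The rank tests are computed through scipy.stats with these
conventions pinned; the test suite validates them against from-scratch
exact-enumeration oracles for small n.

## Synthetic cohort generator

The generator is a statistical/topographic phantom of the study
conditions, not an optical simulation: no vessels, optic disc, PSF or
disease phenotypes. Defaults encode the target cohort: 30 eyes, two
sessions, sector fraction medians (IQRs) of 33.3 (21.9–41.2) %,
5.3 (2.4–8.1) %, 0.5 (0.2–0.8) % for fovea/parafovea/perifovea, and green
intensity levels 39.4/60.3/81.7. The default frame is 822 × 1152 px at
60 µm/px — a reduced scale that preserves all geometric relations (the
6 mm circle spans 100 px) while keeping a full cohort analysis in seconds;
the device-native 3288 × 4608 @ 15 µm is available via config.

Mechanics, per eye:

* **Fractions** are log-normal around the configured medians with log-SD
  `ln(q3/q1)/(2·0.6745)` matched to the configured IQR (fractions are
  positive and right-skewed; the configured IQRs are asymmetric about the
  medians). A single latent load factor drives all three sectors
  (comonotone draws), which models eyes being globally GEFC-rich or
  GEFC-poor and guarantees the fovea > parafovea > perifovea ordering per
  eye. Draws are clipped to [0, 100].
* **Speckle** — GEFC pixels are the top-k pixels of a Gaussian-smoothed
  (σ = 2 px) random field within each ring, where k = round(fraction ×
  sector pixel count). This produces spatially clustered blobs that stress
  sector-boundary handling while hitting the planted count exactly, making
  the truth channel exact by construction.
* **Green plane** = attenuation × eye-brightness × (sector level + 25 at
  GEFC foci) + Gaussian texture (SD 6). The macular-pigment attenuation is
  `1 − A·exp(−d²/2s²)` with defaults A = 0.15, s = 0.75 mm — a modest
  central darkening, since the configured sector levels already embed the
  observed (post-pigment) values; raising A strictly darkens the fovea.
  The per-eye brightness factor is log-normal with log-SD 0.25,
  representing between-eye variation in media transmission and fluorophore
  load; it is what gives the intensity endpoint a realistic
  between-subject variance (ICC ≈ 0.98 at default noise, matching the
  high-repeatability regime the instrument reports).
* **Red plane** — lipofuscin-dominated background at level 120 × the same
  eye-brightness factor, plus texture, clipped to ≥ 30 counts; at GEFC
  foci the red value is tied to green (ratio 0.3) and capped at
  `floor(3G/7)`. These integer constraints guarantee that the default
  centroid classifier recovers the planted mask bit-exactly on both
  sessions, so parameter recovery isolates the pipeline's own behaviour.
* **Session 2** = session 1 with (i) integer-pixel registration jitter of
  the retinal pattern relative to the fixed sector grid (default ±1 px),
  (ii) a relative log-scale jitter of the planted fractions (default 3 %
  of the value — relative, because sector fractions span two orders of
  magnitude), and (iii) fresh intensity noise (default SD 3 counts),
  applied once as a global brightness offset per plane and again per
  pixel. These defaults produce foveal area-fraction CR ≈ 2 percentage
  points, ICC > 0.99, and a median absolute session-2 recovery error of
  ≈ 0.6 percentage points — the high-repeatability regime of a
  same-operator, short-interval design. All noise enters as
  (config SD) × (standard draws from a fixed-order per-eye stream), so
  cohorts at different noise levels are coupled realizations: repeatability
  metrics respond monotonically to the noise level, which the tests
  exploit.
* **Demographics** — ages ~ N(26.2, 2.8²) rounded and clipped to 23–32;
  sex male with probability 22/30; independent of the image content (no
  planted age effect).

What passing tests show — and what they do not: exact parameter recovery
and the oracle equivalences validate the geometry, the classifier and the
statistics as implemented; the synthetic cohorts validate the pipeline's
behaviour under the assumed noise structure. They do not establish
device-level accuracy on real retinas (optics, registration to anatomy,
fovea localization and pathology are all outside the phantom).

## Numerical and design choices

* Coordinates are row-major, 0-based; pixel centres at integer
  coordinates; the fovea centre may be fractional. Metadata travels in a
  JSON sidecar (raster formats carry no retinal calibration).
* Stored channel values are treated as linear intensity; any device gamma
  is unknown and would cancel out of the area-fraction endpoint in any
  monotone case, though not out of intensity means.
* Boundary rules (inclusive inner radius / strict outer radius; inclusive
  selection intervals) are fixed so masks are bit-reproducible.
* Problem sizes: the default reduced-scale cohort (30 eyes, 822 × 1152)
  analyses in ~15 s; oracle comparisons run on 32 × 32 images and ≤ 110 px
  geometries where exhaustive per-pixel loops are cheap; large-sample
  statistical checks use n = 1000–2000 direct simulations of the paired
  model rather than image cohorts.
* Known limitations: no fovea auto-detection, no 9-field ETDRS quadrants,
  no inter-observer (>2 session / multi-rater) designs, no REFC-based
  atrophy quantification.
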