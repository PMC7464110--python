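# specfaf — quantifying green-emitting fluorophores in spectrally resolved fundus autofluorescence

Blue-light fundus autofluorescence (FAF) of the retina is dominated by
lipofuscin, which emits in the long-wavelength (red) part of the spectrum.
A spectrally resolved FAF device excited at ~450 nm additionally captures the
much weaker *green-emitting fluorophore component* (GEFC, emission
500–560 nm) — attributed mainly to flavin adenine dinucleotide (FAD), a
mitochondrial coenzyme and candidate metabolic biomarker — separately from
the red component (REFC, 560–700 nm). This package implements, and validates
on synthetic cohorts with exact ground truth, the full quantification
pipeline for such two-channel images:

1. **Image model** — 8-bit green/red emission planes with physical
   calibration (µm per pixel) and a fovea anchor; per-pixel spectral
   features by the band-centroid convention
   `intensity = G + R`, `λ = (λ_G·G + λ_R·R)/(G + R)` with λ_G = 530 nm,
   λ_R = 630 nm.
2. **GEFC segmentation** — binarization of pixels whose intensity and
   emission-wavelength centroid fall in a closed selection window (default:
   any positive intensity, 500–560 nm), plus a `green-positive` alternative
   rule.
3. **Sector topography** — macula = 6.0 mm circle centred on the fovea,
   subdivided into fovea (1.5 mm disk), parafovea (1.5–3.0 mm annulus) and
   perifovea (3.0–6.0 mm annulus); per sector the GEFC **area fraction** (%)
   and the **mean green-channel intensity** (0–255).
4. **Repeatability statistics** for a two-session test–retest design —
   ICC(A,1) (two-way random effects, absolute agreement, from the
   subjects × sessions ANOVA), 95% coefficient of repeatability
   CR = 1.96·SD(differences), root-mean-square within-subject coefficient
   of variation, mean absolute intraobserver variability, and Bland–Altman
   limits of agreement.
5. **Cohort comparisons** — medians/IQR, Friedman test across the related
   macular rings with pairwise Wilcoxon signed-rank follow-up, and
   Mann–Whitney U between age subgroups.
6. **Synthetic cohort generator** — paired-session image phantoms with
   log-normal per-eye sector fractions, spatially clustered GEFC speckle,
   a central macular-pigment attenuation profile and controllable
   test–retest noise, plus an exact truth channel for parameter-recovery
   validation.

## Worked example

```python
import specfaf as sf

cfg = sf.SyntheticCohortConfig(seed=1)          # 30 eyes, 2 sessions
img1, img2, truth = sf.synthesize_eye(cfg, 0)   # one eye
grid = sf.build_sector_grid(img1.shape, img1.fovea_center_px,
                            img1.pixel_pitch_um)
mask = sf.select_gefc_pixels(img1)              # centroid rule, 500-560 nm
m = sf.compute_sector_metrics(mask, img1, grid)
print({s: round(v, 2) for s, v in m.area_fraction_pct.items()})
```

prints

```
{'macula': 4.27, 'fovea': 38.84, 'parafovea': 7.17, 'perifovea': 0.7}
```

— for this eye, 38.84 % of foveal pixels carry a green-band emission
centroid, falling to 7.17 % in the parafovea and 0.70 % in the perifovea,
and these values equal the generator's planted truth exactly
(`truth.true_fraction_pct`).

The cohort-scale analysis is driven by the numbered scripts:

```bash
python analysis/01_simulate_cohort.py      # images -> scratch/cohort
python analysis/02_quantify_gefc.py        # -> results/sector_metrics.csv
python analysis/03_repeatability.py        # -> results/repeatability_*.csv
python analysis/04_cohort_comparisons.py   # -> results/cohort_report_*.json
```

With the default configuration and seed 1 this yields a session-1 GEFC area
fraction of 2.98 % (IQR 1.78–5.21) in the macula, 30.06 % (20.51–44.58) in
the fovea, 4.36 % (2.08–9.28) in the parafovea and 0.40 % (0.17–0.94) in the
perifovea; green-channel intensities order the opposite way (fovea 40.0 <
parafovea 57.6 < perifovea 79.9, the macular-pigment signature); the
Friedman test across rings gives Q = 60.0 (p < 1e-13); and the area-fraction
ICCs are ≥ 0.999 with CR between 0.09 and 2.0 percentage points.

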