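# wedgemap

Optical-mapping electrophysiology of perfused ventricular wedge
preparations, in Python.

Voltage-sensitive-dye imaging (e.g. di-4-ANEPPS at ~1 mm spatial and
1 kHz temporal resolution) turns the electrical activity of a wedge of
ventricular wall into a T×H×W fluorescence movie. `wedgemap` implements
the measurement chain used to characterize arrhythmogenic remodeling of
such preparations — for example left-ventricular wedges from a porcine
model of repaired tetralogy of Fallot (rTOF) against sham-operated
controls — together with a synthetic movie generator whose ground truth
is known in closed form, so the whole chain is testable without animal
data.

## What it measures

- **Activation time (AT)** — per pixel, the time of maximal upstroke
  dF/dt relative to its pacing stimulus (parabolic sub-sample
  refinement).
- **Repolarization time (RT) and APD80** — RT is the downward crossing
  of baseline + 0.2·amplitude after the peak; APD80 = RT − AT.
  Regional means are taken in 5×5 mm ROIs at the base, mid free wall
  and apex; dispersion is the spatial SD (with the 5–95 percentile
  range alongside).
- **Conduction velocity anisotropy** — activation is sampled along rays
  from the stimulus site (3–15 mm annulus) and distance is regressed on
  time; CV_L and CV_T are the fastest and slowest passing directions,
  with a gradient-tensor estimator (`1/|∇t|`) as an independent
  cross-check. Isochrone maps use 5 ms spacing.
- **Dynamic APD restitution** — steady-state APD80 vs diastolic
  interval DI over 1–5 Hz pacing, fitted with
  `APD(DI) = APD_max − a·exp(−DI/τ)`; the maximal slope of the fitted
  curve (slope > 1 predisposes to alternans).
- **ERP** — S1-S2 extrastimulus protocol; ERP is the longest
  non-capturing coupling interval plus half the coupling step, with
  censoring when all or none of the couplings capture.
- **Alternans** — beat-to-beat APD alternation per pacing frequency
  (magnitude = mean |ΔAPD|/2, phase consistency = fraction of
  sign-alternating successive differences).
- **Arrhythmia events** — epochs of activations not time-locked to
  stimuli; VT vs VF by cycle-length regularity (CV ≤ 0.15 → VT),
  sustained = lasting ≥ 30 s, plus the induction frequency.
- **Cohort statistics** — exact Mann-Whitney U tests (full permutation
  distribution for groups of ≤ 8, mid-ranks under ties), Spearman rank
  correlation with seeded permutation p-values at small n, and
  mean ± SD comparison tables for two groups of preparations.

The synthetic generator (`wedgemap.synthetic`) produces movies from an
anisotropic eikonal activation field, a Gaussian-random-field APD80
map, a mono-exponential restitution map iterated per pixel (alternans
and loss of capture emerge from the map itself), additive noise, and
dye-polarity inversion. Sham-like and rTOF-like presets pin the ground
truth to published group means (midwall APD80 403 vs 301 ms
endocardially and 390 vs 280 ms epicardially; CV_L 51.27 vs
65.37 cm/s; CV_T 30.19 vs 27.34 cm/s). See `docs/methods.md` for the
model details and their rationale.

## Worked example

```python
from wedgemap import preset_movie, dynamic_protocol
from wedgemap.pipeline import analyze_movie

site = (50, 50)
movie, truth = preset_movie(
    "rtof", "endocardium",
    grid_shape=(100, 100), noise_sd=0.02, seed=11,
    protocol=dynamic_protocol([1.0], beats_per_frequency=2, stimulus_site=site),
    stimulus_site=site,
)
results = analyze_movie(movie)
for name, value in sorted(results.variables().items()):
    print(f"{name:26s} {value:8.2f}")
```

prints

```
apd_apex_endo_ms             404.74
apd_base_endo_ms             408.28
apd_dispersion_endo_ms        11.74
apd_mid_endo_ms              409.22
cv_long_cm_s                  51.46
cv_ratio                       1.71
cv_trans_cm_s                 30.15
rt_dispersion_endo_ms         44.22
```

The movie was generated with a heterogeneous APD field of mean 403 ms
(rTOF endocardial preset; the midwall ROI of this particular random
field sits a few ms above the global mean), CV_L = 51.27 cm/s and
CV_T = 30.19 cm/s — the regional APD80 means, the spatial dispersion
and both conduction velocities are recovered by the pipeline from the
noisy fluorescence movie alone.

A thin CLI wraps the same functions:

```sh
wedgemap simulate --preset rtof --protocol dynamic --frequencies 1,2,2.5 --seed 1 --out run1
wedgemap analyze run1 --out run1/results
wedgemap compare cohortA/ cohortB/ --out report.csv
```

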