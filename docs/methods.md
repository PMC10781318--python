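# Methods

This note documents the models, parameter choices and numerical conventions
behind `thermoface`, and what the synthetic-data tests do and do not
demonstrate about real thermographic data.

## Thermal codec

Decoding is the affine map `T = T_min + gray / T_mgv · (T_max − T_min)` with
`T_mgv` the **per-frame** maximum gray value, not the bit-depth maximum: the
hottest pixel in the frame is assumed to sit at the top of the temperature
scale, as in auto-ranged radiometric exports. A `full_scale` mode
(`T_mgv = 2^depth − 1`) covers cameras that emit fixed full-depth maps.
Consequences of the per-frame convention:

- Decoding is only exact when the sidecar's `T_max` really is the frame's
  maximum temperature. The synthetic generator therefore writes an
  **auto-ranged sidecar** (`T_min` fixed at 18 °C, `T_max` = the rendered
  field's true maximum), which guarantees one pixel encodes to the top gray
  level and makes the decode/encode round trip exact to half a quantisation
  step `(T_max − T_min) / (2 · max_gray)`. A fixed 18–40 °C scale whose
  frames never reach 40 °C would make per-frame-`T_mgv` decoding
  systematically biased; that combination is representable but not the
  generator default.
- Encoding rounds half away from zero; decoding uses real division. The
  round-trip bound above is exact under these conventions and is asserted
  as a property test.

Frames travel as 8-bit PNG or 8/16-bit TIFF plus a JSON sidecar
(`t_min`, `t_max`, ids, phase, optionally the face box). An all-zero frame
is rejected (`T_mgv = 0` would divide by zero).

## ROI geometry

The five rectangles are defined by inclusive index ranges scaled by the
detected face box (see README). Conventions the equations leave open:

- **Rounding.** Fractional offsets (`w/16`, `h/13`, `12w/35`, …) and
  non-integer anchors round to the nearest integer, half away from zero.
  The brute-force oracle used in tests applies the same rule, so geometry
  tests are exact set comparisons.
- **Inclusivity.** Both ends of every range are included, matching
  summation-style bounds.
- **Chirality.** "Right cheek" is the region at the *lower* column indices
  (the image's left side, the subject's right side as seen by the camera,
  assuming an unmirrored image). No mirroring is applied. The left cheek's
  outer bound `12w/35` is asymmetric with the right cheek's `w/3`; it is
  implemented verbatim, not "corrected".
- **Clipping.** Regions are clipped to the image and flagged; a region
  entirely outside raises, and a frame with any failed ROI is marked
  incomplete and excluded from the feature table.
- **Order of averaging.** The geometry is written over gray values but the
  features are mean *temperatures*. Because the decode map is affine, the
  mean of decoded pixels equals the decode of the mean gray value; a
  property test asserts this, so averaging order is immaterial.

The face box comes from the landmark provider (detector box or ground-truth
sidecar); it is deliberately **not** recomputed from the landmark hull,
because the ROI extents scale with the detected box, which is generally
padded relative to the hull. A labelled fallback (`box_from_landmarks`)
exists for data without boxes.

## Landmark providers

`GroundTruthProvider` reads per-frame landmark CSVs and face boxes written
alongside the frames — the reference path for tests and for annotated data.
`ThermalContrastDetector` is a lightweight detector for frontal thermal
faces: it thresholds the decoded temperature field at the midpoint of its
range, takes the largest warm connected component's bounding box as the face
box, and instantiates the canonical 68-point template in it. It is suitable
for high-contrast frontal scenes (such as the synthetic frames, where it
localises landmarks to within 5 % of face width); it is *not* a trained
statistical detector and no claim of detector accuracy on real imagery is
made or tested. Both sit behind one `detect(frame)` contract, so a trained
backend can be slotted in without touching downstream code.

## Statistics

Summary cells are sample mean and SD (n − 1) per ROI × state over frames.
The Friedman test uses **subjects as blocks** (k = 3 per-phase means,
default 4 frames averaged per phase): the repeated-measures exchangeability
assumption holds at the subject level, whereas frame-level blocks would
treat correlated frames as independent. A frame-level mode exists for
sensitivity analysis only. The statistic uses within-block mean ranks with
the standard tie correction and is referred to χ² with k − 1 df; a fully
tied matrix returns Q = 0, p = 1. Calibration is verified by simulation
(type-I error within [0.03, 0.07] at α = 0.05 over 2000 null replicates,
n = 25 blocks) and the implementation is cross-checked against an
independent library routine.

## Classifier

Multiclass RBF-SVM with the reference configuration C = 100, γ = 10 on the
five ROI temperatures **in °C without standardization** — the configuration
is stated without a scaling step, so none is applied by default. Note that
γ = 10 implies a kernel length-scale of ≈ 0.2 °C, far narrower than
between-subject temperature variation; on weakly separated data this makes
the SVM memorise rather than generalise. A `standardize` flag (z-scoring
pipeline) exists because of this scale sensitivity.

Splits and folds are **grouped by participant** (all of a person's frames on
one side of every boundary): within-subject correlation otherwise leaks
identity across folds and inflates accuracy. A row-level mode exists for
comparison. Cross-validation pools held-out predictions from all folds into
a single confusion matrix (class order baseline, relax, stress). Grid
search, when requested, evaluates every (C, γ) pair with the same folds and
breaks ties deterministically toward the smallest C, then smallest γ.

Report conventions: per-class precision/recall/F1 are computed exactly and
additionally rounded to integer percent; recall is also reported to two
decimals (the "accuracy" column convention of per-class report tables);
overall accuracy and error rate sum to 100 exactly before rounding. A class
that is never predicted yields an undefined (NaN) precision with a warning,
not a silent zero.

`reconstruct_confusion` inverts printed per-class metrics to the integer
confusion matrices consistent with them (row sums bounded, recall matched
within 0.01 to absorb round-vs-truncate ambiguity in the last printed digit,
precision matched at integer percent). For the published 66-frame
evaluation it finds exactly one matrix; its overall accuracy is 95.45 %.
The 66-frame evaluation total is taken as printed even though the described
20/5-participant split yields 60 test frames; the package reports whatever
total its own split produces and uses 66 only for the metrics
reconstruction.

## Synthetic generator

Each frame is a uniform background (27 °C) with a warm elliptical face
(33 °C base) inscribed in the face box (half the image width, three quarters
of its height, jittered ±4 px per subject), 240 × 320 px, 8-bit. The
canonical 68-point template is a fixed normalised layout whose four anchor
points sit on the face midline in the order bridge, base, tip, chin; all
five derived ROIs fall inside the face box across box sizes 64–256 px
(tested). Ground-truth landmarks and boxes are written next to the frames.

ROI temperatures follow a mixed model:

```
T[roi, subject, state, frame] = grand_mean[roi]
    + state_effect_scale · (mu[roi][state] − grand_mean[roi])
    + b[roi, subject] + eps
b   = dispersion_scale · sd_total[roi] · √f · z_subject,  z shared across ROIs/frames
eps ~ N(0, (dispersion_scale · sd_total[roi])² · (1 − f))   per frame and ROI
```

with `f = subject_sd_fraction` (default 0.5) splitting total variance into a
subject random effect and frame-level residual, plus N(0, 0.1 °C) per-pixel
texture. The subject effect exists because marginal state distributions of
facial temperature overlap heavily; only the within-subject correlation
structure makes state classification plausible, and the generator exposes
that structure explicitly. The single z shared across ROIs models a whole-
face thermal offset (individual metabolic/ambient baseline). The true
per-subject correlation in real data is unknown; `f` is a free, documented
parameter.

Presets:

- **table1** (default): `mu[roi][state]` set to the published per-ROI
  per-state means; `sd_total[roi]` set to the published SDs averaged over
  the three states (the model has one dispersion per ROI, so strong
  per-state heteroscedasticity — e.g. a forehead SD tripling under stress —
  is *not* reproduced; marginal per-ROI SDs are, within 15 % at n = 300).
  Used for summary-statistic recovery: every mean cell is recovered within
  two (correlation-aware) standard errors at the default 25 × 12 design.
- **separable**: state effects scaled ×3 and total dispersion scaled to ⅓,
  `f = 0.5`. This is the designated classifier-recovery surface. The
  calibration is deliberate: with effect ×3 alone at the table1 dispersions,
  the three state distributions still overlap so much that the *Bayes-
  optimal* multiclass accuracy is ≈ 82 % — no classifier could reach the
  ≥ 90 % recovery bar, so such a preset would test nothing. Shrinking the
  dispersion to ⅓ models a strongly stress-responsive, low-noise population
  in which the reference SVM configuration genuinely attains ≥ 97 % pooled
  grouped-CV accuracy across seeds while label-permuted data stays at
  chance (≈ 1/3). The preset demonstrates classifier *recovery* on
  separable data, not expected field performance.

Scales: sidecar `T_min` 18 °C, `T_max` auto-ranged per frame (see codec);
every stamped temperature is validated against the configured bound
(default 40 °C). Generation is fully determined by the seed, and identical
seeds produce byte-identical files.

**What the synthetic tests do not show.** The generator uses frontal
elliptical faces, rectangle-stamped ROI temperatures, Gaussian noise and
exact landmarks. Passing tests demonstrate the pipeline's correctness
(geometry, decoding, aggregation, classification mechanics) and its
statistical calibration — not detector robustness, not performance under
head pose, occlusion or emissivity drift, and not the classification
accuracy attainable on real human thermograms.

## Problem sizes

Default test and acceptance runs use the full 25-subject × 12-frame design
(300 frames of 240 × 320 px) for end-to-end checks, 1000 random 8 × 8 frames
for codec round trips, 500 randomised draws for the geometry oracle, and
2000 replicates for Friedman calibration; unit tests use smaller sessions
(2–6 subjects, 120 × 160 px). These sizes give stable statistics while
keeping the whole suite around ten seconds.

## Known limitations

- Single frontal face per frame; no pose, occlusion or multi-face handling.
- Rectangular ROIs only; no contour segmentation or outlier rejection.
- The per-frame `T_mgv` convention ties decoding accuracy to auto-ranged
  scales; fixed-scale exports should use `full_scale` mode.
- Per-state heteroscedasticity is not modelled by the generator.
- The reference γ = 10 on unstandardized °C features generalises poorly
  across subjects unless states are strongly separated (see above); real
  deployments should consider the `standardize` flag and grid search.
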