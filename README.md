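# thermoface

Automatic stress-state assessment from facial infrared thermography.

Skin temperature over specific facial regions (nose, cheeks, forehead, chin)
tracks autonomic responses to acute stress: vasoconstriction cools the nose
tip during a stressor, and the pattern reverses during relaxation. This
package implements the full analysis pipeline for a shortened
Trier-Social-Stress-Test (TSST) style protocol in which each participant is
imaged in three states — **baseline**, **stress**, **relax** — and every
thermal frame is classified into one of those states from five facial
region-of-interest (ROI) temperatures. It is aimed at researchers working
with radiometric grayscale thermograms and 68-point facial landmarks.

## The method

1. **Thermal decoding.** A grayscale thermogram with temperature scale
   `[T_min, T_max]` (°C) decodes per pixel as

   `T(i,j) = T_min + gray(i,j) / T_mgv · (T_max − T_min)`

   where `T_mgv` is the largest gray value anywhere in the frame (the hottest
   pixel sits at the top of the scale).

2. **ROI placement.** Four landmarks of the standard 68-point annotation —
   9 (chin), 28 (nose bridge), 31 (nose base), 34 (nose tip) — anchor five
   rectangular ROIs whose extents scale with the detected face box
   (width `w`, height `h`). With anchor `(Sx, Sy)`, inclusive pixel ranges:

   | ROI | columns `i` | rows `j` |
   |---|---|---|
   | nose | `[Sx − w/16, Sx + w/16]` | `[Sy − h/13, Sy]` |
   | right cheek | `[Sx − w/3, Sx − w/5]` | `[Sy − h/14, Sy + h/14]` |
   | left cheek | `[Sx + w/5, Sx + 12w/35]` | `[Sy − h/14, Sy + h/14]` |
   | forehead | `[Sx − w/12, Sx + w/12]` | `[Sy − h/4, Sy − h/9]` |
   | chin | `[Sx − w/12, Sx + w/12]` | `[Sy − h/8, Sy]` |

3. **Feature extraction.** The mean decoded temperature over each ROI gives
   a five-dimensional feature vector per frame (°C).

4. **Statistics.** Per-ROI, per-state mean/SD summaries and the Friedman
   repeated-measures rank test (subjects as blocks, k = 3 conditions,
   tie-corrected, χ² with 2 df).

5. **Classification.** A multiclass RBF-SVM (C = 100, γ = 10) maps each
   frame's feature vector to baseline / stress / relax, evaluated with
   participant-grouped 5-fold cross-validation and a pooled confusion matrix
   with per-class precision, recall and F1.

A seeded synthetic thermal-face generator renders full sessions — frames,
JSON sidecars, ground-truth landmark CSVs and a stamped-temperature truth
table — so every stage is testable without access to human-subject data.

## Worked example

Simulate a strongly stress-responsive population, extract features, and
cross-validate the classifier:

```sh
thermoface simulate --out frames --preset separable --seed 1
# wrote 300 frames to frames
thermoface extract --frames frames --out features.csv
# wrote 300 feature rows to features.csv (0 frames failed)
thermoface summarize --features features.csv --out summary.csv
thermoface cv --features features.csv --out report.json --seed 1
```

The summary table (°C) shows the induced state differences — e.g. the nose
cools from 33.75 at baseline to 33.10 under stress, and each ROI's Friedman
test flags the state effect:

```
        roi  baseline_mean  baseline_sd  stress_mean  stress_sd  relax_mean  relax_sd  friedman_q  friedman_p  p_lt_0.05
       nose          33.75         0.36        33.10       0.40       33.11      0.37       37.68         0.0       True
 left_cheek          35.03         0.28        34.54       0.24       33.00      0.29       50.00         0.0       True
   ...
```

The cross-validation report pools predictions over the five held-out folds:

```
   class  accuracy_recall_2dp  precision_pct  recall_pct  f1_pct
baseline                 97.0            100          97      98
   relax                100.0             98         100      99
  stress                 98.0             97          98      98
overall accuracy 98.33%
```

`accuracy_recall_2dp` is per-class recall to two decimals (the "accuracy"
column of per-class report tables); the overall accuracy is the pooled
fraction of correctly classified frames.

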