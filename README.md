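# accelcut

Accelerometer cut-point comparison for preschooler physical activity.

Hip-worn accelerometers summarise movement as dimensionless *activity
counts* per epoch (here 5 s). Turning counts into time spent sedentary, in
light activity, or in moderate-to-vigorous physical activity (MVPA) requires
*cut-points* — thresholds in counts per minute (cpm) — and for 3–5-year-olds
several incompatible sets are in common use. Which set you pick changes the
minutes you report and, downstream, which children count as meeting the
≥60 min/day MVPA guideline. `accelcut` is a reusable pipeline for
quantifying exactly that disagreement. It is written for researchers in
paediatric physical-activity epidemiology who work with epoch-level count
exports.

It provides:

- **Epoch I/O** — a plain-CSV dialect (`timestamp,axis1,axis2,axis3`) for
  tri-axial epoch counts, with vector magnitude (VM, the Euclidean norm of
  the three axes) always derived, never stored, and exact re-integration to
  coarser epochs.
- **Wear time** — non-wear = runs of ≥20 min of consecutive zero counts
  (evaluated within calendar days); valid day = ≥10 h wear; children are
  retained only with enough valid weekdays and weekend days.
- **Cut-points** — the three published preschool sets, on both axes where a
  calibration exists (cpm: sedentary upper / MVPA lower):
  vertical — Pate 800/1680, Butte 239/2120, Johansson 580/3480;
  VM — Butte 820/1908, Johansson 2136/6144. Sedentary is strictly below the
  first bound, MVPA at or above the second, light in between; thresholds
  rescale to the analysis epoch as exact rationals.
- **Aggregation** — per-day and per-period (weekday / weekend / total) mean
  daily minutes per intensity, mean cpm per axis, and the active flag
  (period-mean MVPA ≥ 60 min/day).
- **Agreement** — 2×2 cross-classification of two active/inactive
  labelings, raw percent agreement, Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e), qualitative bands, and exact reconstruction of
  an unprinted 2×2 table from published marginals + raw agreement.
- **Statistics** — Pearson χ² (no continuity correction) for sex
  differences in active proportions, exact noncentral-*t* sample-size
  calculation for paired designs, *t*-based confidence intervals, and
  Bonferroni-corrected pairwise paired *t*-tests with compact similarity
  letters.
- **Synthetic cohorts** — a seed-reproducible semi-Markov generator of
  7-day tri-axial preschooler recordings (diurnal structure, intermittent
  bouts, zero-count non-wear, sex and weekend effects), so the whole
  pipeline is testable without restricted cohort data.

## Worked example

Reconstructing chance-corrected agreement from published marginals
(`examples/03_cutpoint_agreement.py`): in a 134-child cohort, Pate
classified 58 of 74 boys active on weekdays and Butte 44 of 74, with 81.08%
raw agreement. That fixes the 2×2 table uniquely:

```
reconstructed 2x2 (Pate vs Butte, boys, weekdays):
  both active=44  pate only=14  butte only=0  both inactive=16
  raw agreement 81.08%   kappa 0.576 -> moderate

Pate vs Johansson (Johansson classifies everyone inactive):
  raw agreement 21.62%   kappa 0.000 -> no agreement
```

The 81% raw agreement shrinks to κ = 0.576 ("moderate") once chance
agreement between two mostly-active marginals is removed — and a classifier
that calls everyone inactive gets κ = 0 exactly, whatever its raw agreement.

Running the full pipeline on a synthetic cohort
(`examples/02_classify_and_summarise.py`) shows the cut-point effect
directly — the same child's week, five threshold sets:

```
cut-points   axis                  SB  light   MVPA  active?
pate         vertical             515     87     65  yes
butte        vertical             374    249     44  no
johansson    vertical             475    177     14  no
butte        vector_magnitude     424    102    141  yes
johansson    vector_magnitude     540    102     25  no
```

Columns are mean daily minutes over valid days; the guideline verdict flips
with the threshold set, which is the point.

There is also a thin CLI: `accelcut simulate|process|agree|power|run-all`
(e.g. `accelcut power --dz 0.5 --alpha 0.05 --power 0.95` prints
`required n: 54`).

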