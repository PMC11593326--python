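# Methods

## The analysis pipeline

The pipeline turns epoch-level tri-axial activity counts into intensity
minutes, guideline-compliance flags, and agreement statistics between
cut-point sets. Stages, in order:

1. **Epoch series.** Counts are integers per epoch on three axes; the
   vector magnitude (VM) is recomputed on demand as the Euclidean norm, so
   VM ≥ vertical always holds and there is no second source of truth.
   Timestamps mark epoch starts and intervals are half-open, which makes
   the assignment of the midnight epoch to a calendar day unambiguous. The
   epoch length must divide 60 s so cpm thresholds rescale exactly.
2. **Non-wear.** A maximal run of consecutive zero-count epochs lasting at
   least `min_zero_run_minutes` (default 20, inclusive) is non-wear. Two
   interpretation choices are deliberate:
   - *Minutes, not epochs.* The rule is read as 20 minutes of consecutive
     zeros (240 five-second epochs), following the standard wear-time
     literature; a literal 20-epoch reading (100 s) would delete ordinary
     stillness. The threshold is configurable, so the literal reading is
     available as a sensitivity analysis (`min_zero_run_minutes=100/60`).
   - *Vertical axis only.* All three cut-point sets housed here calibrate
     the vertical axis; an all-axes-zero test is selectable
     (`zero_test="all_axes"`).
   Runs are evaluated within calendar days: a run crossing midnight is
   split and each part tested alone. This keeps day-level wear totals
   self-contained and the partition property (worn + non-worn = 1440 min on
   a fully recorded day) exact.
3. **Valid days and children.** A day is valid with ≥ `min_wear_minutes`
   wear (default 600 = 10 h, inclusive). Source protocols typically do not
   state a per-period minimum of valid days, so the per-child retention
   rule (≥1 valid weekday and ≥1 valid weekend day by default) is exposed
   as configuration rather than asserted as a standard.
4. **Classification.** Sedentary iff count < sedentary bound, MVPA iff
   count ≥ MVPA bound, light otherwise — the strict/inclusive pattern of
   the published thresholds. Per-epoch thresholds are cpm × epoch/60 kept
   as exact rationals; vectorised classification multiplies counts by
   60/epoch (an integer) instead, which is algebraically identical and
   avoids any float-threshold drift at 5 s. Moderate and vigorous are not
   separated: the housed sets publish only an MVPA lower bound.
5. **Aggregation.** Day minutes are epoch counts × epoch/60, so
   sedentary + light + MVPA = wear exactly. Period means are unweighted
   means over valid days; "total" averages all valid days rather than the
   two period means (days are the sampling unit). A child is *active* in a
   period when the period-mean MVPA is ≥ 60 min/day (inclusive). The
   mean-based rule is an interpretation: it is the only rule under which a
   child can coherently be active on weekdays and inactive at the weekend,
   which compliance tables routinely show. 95% CIs are mean ± t(0.975, n−1)·SE.
6. **Agreement.** Cohen's κ = (p_o − p_e)/(1 − p_e) with the usual 2×2
   expected agreement; if p_e = 1 (all mass in one agreement cell) κ is 1
   for perfect agreement, else 0 by convention. κ is *reported* truncated —
   not rounded — to three decimals, matching how the compliance literature
   prints values such as 0.265 for a computed 0.2656; internal computation
   keeps full precision. Banding: ≤0 no agreement, (0, 0.20) weak,
   [0.20, 0.40) reasonable, [0.40, 0.60) moderate, [0.60, 0.80) substantial,
   [0.80, 1.00] excellent. No κ standard errors are produced (the printed
   sources give none and state no method).
7. **2×2 reconstruction.** Given n, both active marginals and the raw
   percent agreement, the agreement count is A = round(pct·n/100) — (a+d)
   must be an integer, and printed percentages can carry rounding residue
   (e.g. 82.42% of 74 is 60.99, i.e. 61 children) — and the both-active
   cell is a = (first + second + A − n)/2. The arithmetic solution is
   verified by brute-force search over all feasible a, which must find
   exactly one; parity or negativity violations raise a diagnostic instead
   of returning a nearest fit.

## Auxiliary statistics

- **Sex differences in active proportions**: Pearson χ² on the 2×2
  sex × active table, df = 1, *without* Yates continuity correction — the
  uncorrected statistic is what reproduces conventionally printed p-values
  for these tables; a zero margin (e.g. a set classifying everyone
  inactive) makes the test undefined and is flagged, not silently dropped.
- **A-priori paired-t sample size**: power is computed exactly from the
  noncentral t distribution (df = n−1, noncentrality d_z·√n, two-sided
  rejection at t(1−α/2, n−1)) and n is the smallest value reaching the
  target, found by upward iteration. For d_z = 0.5, α = 0.05, power 0.95
  this gives n = 54 with critical t ≈ 2.006. A statsmodels solver serves as
  an independent cross-check in the tests only.
- **Similarity letters**: all k(k−1)/2 paired t-tests, p multiplied by the
  number of pairs (capped at 1); conditions are grouped by the transitive
  closure of the non-significance relation (the standard compact-letter
  convention, adopted here as a design choice since the display format does
  not pin down an algorithm) and lettered A, B, C… in descending-mean
  order. The repeated-measures GLM with sphericity correction that often
  accompanies such tables is deliberately out of scope; only descriptive
  means/CIs and the pairwise procedure are implemented.

## The synthetic cohort generator

No raw preschool count cohorts of this design are publicly deposited, so
the generator emulates the study design: by default 134 children (74 boys;
sex drawn per child with p = 74/134), ages uniform on [3, 5], seven
consecutive days starting Monday, 5-s epochs.

**Model.** A semi-Markov chain over four states — sleep/non-wear,
sedentary, light, MVPA — with exponential dwell times (means 170, 6, 3,
2 min) truncated to whole epochs, minimum one. State entry probabilities
are proportional to per-hour weights; night hours (21:00–07:00) are
dominated by sleep/non-wear, giving the diurnal profile, and the short
light/MVPA dwells give the intermittent bout structure characteristic of
preschoolers. Vertical counts within a state are gamma (shapes 1.2/3/4;
means 200/900/2450 cpm scaled to the epoch), zero-inflated at 0.5 for
sedentary, and exactly zero on all axes for sleep/non-wear. Horizontal
axes are synthesised to hit a VM target of vertical × `vm_ratio` ×
lognormal(0, 0.15) noise, floored at the vertical count; `vm_ratio`
defaults to 2.2, the approximate ratio of VM to vertical worn-time cpm
means (≈1179/535) reported for preschool hip data. Boys' MVPA entry rate
is multiplied by `sex_effect` (default 1.25) and weekend sedentary dwell by
`weekend_effect` (default 1.15); both defaults are plausible-magnitude
choices, as published tables report directions and category prevalences
rather than generative parameters.

**Calibration.** The free distribution parameters were fixed once so that
a default cohort lands near published preschool hip-accelerometry anchors:
worn-time vertical mean ≈ 585 cpm (anchor 535 ± 15%), wear ≈ 10.5 h/day,
daily MVPA ≈ 83 min under Pate, ≈ 58 under Butte, ≈ 18 under Johansson,
with Johansson classifying 0% of children active. The generator is not
fitted to any published cohort's table of means, and the anchors are
documentation, not assertions.

**Reproducibility.** Each child's stream is seeded from
(cohort seed, child index) via numpy's SeedSequence, so cohorts are
bit-identical under a fixed config and any child can be regenerated alone.

**What passing tests do and do not show.** The generator reproduces the
*structural* features the pipeline relies on (zero-run non-wear, diurnal
occupancy, right-skewed counts, VM dominance, threshold-ordering
consequences); it does not emulate device filtering, spike artefacts,
posture-specific count signatures, seasonal effects, or between-child
correlation beyond the sex/weekend multipliers. Green tests therefore
validate the processing rules and statistics, not any claim about a real
cohort's minute totals.

## Numerical and scale choices

- Exact-rational threshold comparison (no float thresholds at short epochs).
- Re-integration sums integer axis counts, conserving totals exactly; VM is
  recomputed after summing (it is not additive).
- Degenerate inputs: empty tables, zero margins, infeasible reconstructions
  and unreachable power targets raise or flag explicitly rather than
  returning silent defaults.
- Test problem sizes are scaled to keep the suite fast while estimates stay
  well inside the asserted bands: the cpm calibration check uses 36
  children across 3 seeds, ordering/nesting invariants 20 cohorts of 2
  children × 2 days, and Monte-Carlo monotonicity 10 seeds; all are
  deterministic given their fixed seeds.

## Known limitations

- Anthropometry/BMI categorisation, repeated-measures GLM inference,
  intra-class correlation, weighted kappa and binary device-file parsing
  (AGD/GT3X) are out of scope.
- The default retention rule (≥1/≥1 valid days) is lenient; stricter
  conventions (e.g. ≥3 weekdays) are a one-line config change.
- Printed percent agreements can be inconsistent with any integer count
  (82.42% of 74 children); the nearest-integer agreement count resolves
  this, and the reconstruction refuses genuinely infeasible inputs rather
  than guessing.
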