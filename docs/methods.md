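# Methods

## The measurement problem

Weekly minutes of moderate (MPA, 3.0–5.9 MET) and vigorous (VPA, ≥ 6 MET)
physical activity can be estimated from hip-worn accelerometry, an activity
diary, or the IPAQ short-form questionnaire — and the four resulting numbers
(accelerometry is evaluated at both 10-s and 60-s epochs) routinely disagree.
This package operationalises three complementary quality criteria over two
measurement weeks T0 and T1, computed separately for adults and children:

* **reliability** — Spearman correlation of the same tool across weeks;
* **validity** — correlation between two tools within a week;
* **stability of differences** — per-participant paired differences
  `tool_a − tool_b` are formed within each week, and the T0 differences are
  correlated with the T1 differences. A high value means the tools disagree
  *systematically*: whoever is over-estimated by tool a relative to tool b in
  week one is over-estimated in week two as well.

## Device pipeline

The accelerometer side starts from MET epoch series (MET estimation from raw
acceleration is upstream of this package; inputs are already MET-valued).

1. **Aggregation.** Epochs are anchored at local midnight (epoch *k* covers
   `[k·e, (k+1)·e)` seconds, half-open), so results are shift-invariant
   across days. Longer epochs are means of their constituents, which
   conserves total MET·time; the aggregated wear flag is true iff ≥ 50 % of
   constituents are worn, and a worn epoch's mean uses only worn
   constituents (otherwise unworn resting values would dilute the signal).
   Conservation is therefore exact whenever wear flags are homogeneous
   within each output window — guaranteed for synthetic data, where non-wear
   boundaries sit on the 60-s grid. Aggregation composes: 1 s → 60 s equals
   (1 s → 10 s) → 60 s, because means of means with equal weights collapse.
2. **Classification.** Closed intervals as printed: MPA is
   `3.0 ≤ MET ≤ 5.9`, VPA is `MET ≥ 6.0`. Values in the open gap (5.9, 6.0)
   classify as below-moderate; the synthetic generator never produces epoch
   means in the gap, and the convention is explicit in `CutPoints`.
3. **Wear validity.** A day is valid at ≥ 480 wear minutes (a plain reading
   of "at least 8 h"); a week needs ≥ 4 of 7 valid days, otherwise the
   estimate is missing with an `insufficient_wear` flag. Weekly minutes are
   7 × the mean over valid days only — invalid days cannot influence the
   estimate, and the result is invariant to day order.
4. **Non-wear detection** is a variance-threshold stand-in operating on the
   MET signal alone (an unworn device records a flat resting trace): a 30-s
   interval is non-wear when its surrounding 10-min window has SD < 0.05 MET
   and mean ≤ 1.0 MET. Devices in the emulated study used a temperature-based
   algorithm; temperature is not simulated, and synthetic data carry
   ground-truth wear flags, so the detector is opt-in and is validated
   against those flags (sensitivity and specificity ≥ 0.95 in the suite).

The one-minute illustration that motivates the epoch comparison: 20 s of
stair climbing at 7 MET followed by 40 s of standing at 1.8 MET yields two
vigorous 10-s epochs (20 s VPA) but a single 60-s epoch at
(20·7 + 40·1.8)/60 ≈ 3.53 MET — one moderate minute and no VPA at all,
although total MET·time is identical.

## Self-report scoring

* **Diary**: MPA = Σ durations of entries perceived as moderate, VPA = Σ
  vigorous; light entries are ignored (no comparable questionnaire item).
  Participants are instructed to log only activities *longer than* 10 min;
  by default entries ≤ 10 min are also dropped at scoring time (strict
  inequality), controllable via `enforce_10min`. An empty week scores 0 with
  an `empty_week` flag, because the diary format cannot distinguish "no
  activity" from "not filled in" — downstream users choose the
  interpretation.
* **IPAQ short form**: plain `days × minutes/day`, with walking counted into
  MPA alongside the moderate item. No truncation and no MET-minute weighting
  by default (the official protocol's 180 min/day cap is available behind
  `truncate_min_per_day`). Children's questionnaire yields no minutes/week
  outcome and is excluded: the schema simply has no `ipaq` rows for
  children, and requesting them is a hard configuration error.

## Statistics

* **Spearman's r\_s** with average ranks for ties; two-sided p-value from the
  t-approximation `t = r_s·√((n−2)/(1−r_s²))` on n−2 df. At `|r_s| = 1` the
  t statistic degenerates and the p-value is reported as the permutation
  bound `2/n!` (n ≤ 10) or 0. An exact-permutation option exists for n ≤ 10.
  The reference R implementation (`cor.test`) uses an exact/AS89 method
  without ties; with ties both fall back to t-approximations, and the
  divergence only affects tiny samples.
* **Bootstrap CIs**: percentile intervals from 1000 resamples of complete
  participant pairs. Replicates with a constant margin (undefined r\_s) are
  discarded and counted; more than 50 % degenerate replicates raise an
  error rather than returning a misleading interval. BCa was considered and
  rejected: the emulated analysis specifies plain bootstrapping, and
  percentile intervals are the minimal-assumption reading.
* **Missingness**: pairwise deletion everywhere. A difference parameter is
  missing whenever either source estimate is missing; a stability
  correlation uses participants complete for all four underlying values
  (both tools at both weeks). Adding a participant with any missing value
  never changes any statistic.
* **Normality check**: a one-sample Kolmogorov–Smirnov test against a normal
  with the sample's mean/SD is provided as an advisory diagnostic; the
  pipeline always proceeds with rank correlations regardless.
* **Significance** is judged at α = 0.05 on the p-value, not on the CI. No
  multiple-testing correction is applied by default (matching the emulated
  analysis); the summary tables expose raw p-values so users can apply one.
* **Rendering**: summary tables round to 2 decimals, half away from zero,
  only at render time; all internal statistics stay at full precision.
  `diff_mean` equals `t1_mean − t0_mean` on the complete subset, which is
  algebraically the mean of per-participant T1−T0 changes.

## Synthetic cohort

The generator emulates the data-generating process the analysis assumes —
it is the package's test bed, not a model fitted to any dataset.

* **Traits** (stable per person): habitual weekly MPA/VPA volume
  (normal, truncated at 0, around 300/60 min/week for adults and 350/120 for
  children), a gamma bout-length distribution (mean 480 s for adults, 90 s
  for children — the short, intermittent pattern characteristic of
  children's play), a diary duration bias (log-normal, median 0.9), an IPAQ
  bias (log-normal, median 1), a wear propensity (hours/day), and the share
  of reported MPA recalled as walking.
* **Weeks**: weekly volume = `max(0, habitual + N(0, week_noise_sd))`.
  Randomness is split into documented substreams per participant: a
  *structure* stream (wear schedule, bout repertoire — durations, MET
  levels, day assignments — rest noise, placement) that does not depend on
  the week, and a *week* stream (volume noise, diary omission and intensity
  confusion, IPAQ recall). Each week consumes the prefix of the habitual
  bout repertoire needed to reach its volume target, so weeks with equal
  targets are identical — in the `week_noise_sd = 0` limit all reliability
  and stability correlations equal 1 exactly — and nearby targets share
  almost all of their bouts, which is also how habitual routines behave.
* **Bout MET levels**: uniform on 3.1–4.5 MET for MPA (walking-grade) and
  6.1–8.5 MET for VPA (running-grade). Narrow, low-in-band moderate levels
  are what make the 60-s epochs smooth boundary epochs below the cut point,
  producing the characteristic acc10 > acc60 ordering; spreading levels over
  the entire printed band would cancel that effect and is not how moderate
  activity distributes in practice.
* **Non-wear**: contiguous morning/evening blocks on the 60-s grid around a
  daily wear window (≈ `wear_propensity` hours); with probability
  `p_invalid_day` a day gets only 1–7.5 h of wear and fails the 8-h rule.
  Non-wear epochs record a flat 1.0 MET; worn rest epochs are noisy around
  1.3 MET and never reach the MPA band.
* **Diary**: only bouts > 10 min are eligible; each is omitted with
  `diary_omission_prob`, perceived intensity is drawn from the confusion
  matrix row of the true intensity, and the duration is scaled by the
  personal bias — net under-reporting.
* **IPAQ**: recalled volume = `ipaq_overreport_factor × ipaq_bias × truth`,
  allocated over the days that actually contained such bouts and rounded to
  a minutes/day grid (default 10 min) — net over-reporting.

Under default parameters the simulated adult cohort reproduces the
descriptive ordering IPAQ > acc10 > acc60 > diary for mean MPA.

### What the generator does *not* emulate

* Children's diaries are nearly empty: with a 90-s mean gamma bout length,
  essentially no bout exceeds 10 min, whereas real children report long
  structured sessions (sports training) alongside unreported intermittent
  play. Child diary reliability is therefore degenerate in simulation
  (constant zeros surface the undefined-correlation contract, not a number).
* Sedentary and light-intensity behaviour, posture, and 24-h wear are out of
  scope; rest is a generic low-MET process.
* MET values appear directly; raw acceleration, barometric signals and the
  temperature channel used by the real non-wear algorithm are not simulated.

Passing tests on this cohort show that the *analysis machinery* is correct
and that the assumed generative structure is recoverable; they cannot show
that any real population satisfies those assumptions.

## Problem sizes and numerical choices

Simulation-backed tests use sizes chosen to make their statistical
assertions stable: 10,000 random day-long series for MET·time conservation
(tolerance 1e-9 relative), 500 seeded cases (n ≤ 7) against an exhaustive
rank-formula/permutation oracle (r\_s to 1e-12), 200 participants for
parameter recovery in a trait-dominated regime (between-person trait SD five
times the week-to-week noise SD, transient diary/IPAQ noise scaled down in
proportion; all reliability and stability r\_s > 0.8), 20 seeds × 100
participants for the independent-weeks null (mean |r\_s| < 0.15), and 500
adults for the descriptive tool ordering. Simulation-heavy tests run the
generator at a 10-s base epoch: by the mean-of-means composition identity
this is lossless for the 10-s and 60-s analysis epochs.

Ties in ranks use average ranks; correlations are clipped to [−1, 1] against
floating-point overshoot; `|r_s| ≥ 1 − 1e-15` triggers the permutation-bound
p-value. Bootstrap resampling treats the participant pair as the unit.
Degenerate inputs fail loudly (`UndefinedCorrelationError`,
`DegenerateBootstrapError`) instead of returning NaN silently, and the batch
analyses record such rows with an `error` note while continuing.

## Known limitations

* The variance-based non-wear detector cannot separate sleep from non-wear
  and is calibrated only against the generator's flat non-wear model.
* The stability statistic's n counts participants complete across both
  weeks; analyses that delete within-week only would report larger n.
* The percentage column sometimes printed alongside mean differences in
  published tables of this kind has no reproducible definition from the
  printed quantities and is deliberately not implemented.
* ICC and Bland–Altman agreement analyses are out of scope.
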