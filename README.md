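# pa-concordance

Tools for asking a deceptively simple question in physical-activity (PA)
research: **when a questionnaire, a diary and an accelerometer disagree about
how active someone was, is the disagreement at least systematic?**

The package implements, end to end, the comparison framework used to study
self-reported versus device-measured PA in a family cohort (adults and
children) over two measurement weeks:

* **Accelerometry** — MET (metabolic equivalent of task) epoch series are
  re-aggregated to 10-s and 60-s epochs, classified with cut points
  MPA 3.0–5.9 MET / VPA ≥ 6 MET, filtered by wear-validity rules
  (≥ 8 h wear per day, ≥ 4 of 7 valid days), and extrapolated to minutes/week
  as 7 × the mean over valid days.
* **Self-report** — a PA diary (entries > 10 min, perceived intensity) and
  the IPAQ short form (days × minutes/day; walking counts toward MPA) are
  scored into the same minutes/week currency.
* **Quality criteria** — for every pair of tools, per-participant paired
  differences are formed each week; Spearman's r\_s (average ranks, t-approximation
  p-values, percentile bootstrap CIs with *n* = 1000) then quantifies

  - **stability of differences** (the headline statistic):
    corr(difference at T0, difference at T1),
  - **test–retest reliability**: each tool T0 vs T1,
  - **concurrent validity**: tool pairs within one week,

  with pairwise deletion throughout and missingness propagating through the
  differences. Adults contribute 6 tool combinations, children 3 (their
  questionnaire has no minutes/week outcome).
* **Synthetic cohort** — a generator that emulates the assumed data-generating
  process (bout-structured MET series with short intermittent bouts for
  children, non-wear schedules, stable personal traits, diary under-reporting,
  IPAQ over-reporting), so the whole analysis is testable without access to
  any study's raw data.

## Worked example

```bash
cat > run.yaml <<'YAML'
seed: 7
n_boot: 1000
sim:
  n_adults: 32
  n_children: 32
  base_epoch_s: 10
  seed: 7
YAML
pa-concordance all --config run.yaml --out results/
```

This simulates 32 adults and 32 children over two weeks, scores all four
tools, and writes `weekly_estimates.csv`, `truth.csv`, `stability.csv`,
`reliability.csv`, `validity.csv`, `summary_table.csv` and a reproducibility
`manifest.json`. The adult MPA stability table from this exact run:

```
        label  n   r_s  p_value  ci_lo  ci_hi
Acc 10–Acc 60 32 0.559    0.001  0.191  0.816
 Acc 10–Diary 32 0.859    0.000  0.709  0.932
  Acc 10–IPAQ 32 0.977    0.000  0.937  0.989
 Acc 60–Diary 32 0.854    0.000  0.697  0.931
  Acc 60–IPAQ 32 0.974    0.000  0.932  0.988
   Diary–IPAQ 32 0.966    0.000  0.906  0.986
```

Each row asks: is the *disagreement* between two tools the same kind of
disagreement in both weeks? Here, for example, the per-person gap between
the 10-s accelerometry estimate and the IPAQ is strongly preserved across
weeks (r\_s = 0.98): the questionnaire over-reports, but it over-reports
*consistently per person* — exactly the kind of systematic difference the
stability statistic is designed to detect. Re-running the same command
reproduces these files byte for byte.

The same machinery is available as a library:

```python
from pa_concordance import SimConfig, simulate_dataset, stability_analysis, tool_pairs

est = simulate_dataset(SimConfig(n_adults=32, n_children=32, seed=7)).estimates
adults = est[est.population == "adult"]
stability_analysis(adults, tool_pairs(["acc10", "acc60", "diary", "ipaq"]), "MPA", seed=7)
```

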