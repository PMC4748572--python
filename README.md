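# mewskit

A toolkit for building and evaluating a hospital-customized Modified Early
Warning Score (MEWS) program end to end:

- **`mewskit.scoring`** — a fully configurable vital-sign banding rubric
  (systolic blood pressure, heart rate, respiratory rate, temperature, AVPU
  consciousness, and a nurse-concern item, each worth 0–3 points; default
  maximum total 15), per-observation scoring, and daily-maximum reduction.
- **`mewskit.wz_analysis`** — the warning-zone (WZ) threshold audit:
  stratified cardiac-arrest rates by maximum score with exact
  Clopper–Pearson intervals, uncorrected chi-squared and Fisher's exact 2×2
  tests, and a threshold-selection rule (smallest score at which every
  stratum above it is significantly elevated over the stratum below).
- **`mewskit.incidence`** — admission-denominated incidence: rates per 1000
  admissions, calendar-month series with mean ± SD control limits, cohort
  background summaries, and before/after outcome comparisons.
- **`mewskit.callout`** — the callout algorithm as an explicit state machine
  (monitor → alert cascade → ward treatment → ICU transfer, with DNR
  termination), plus a cohort simulator with a post-alert multiplicative
  hazard reduction θ.
- **`mewskit.synthetic`** — a synthetic inpatient-cohort generator with
  score-conditional IHCA/death hazards (calibrated by default to audit
  rates of 0.18 % / 1.38 % / 1.75 % / 3.57 % for scores ≤6 / 7 / 8 / ≥9 and
  ~51 WZ patients per month), band-consistent vital-sign draws that rescore
  to their intended totals, and byte-reproducible output tables.
- **`mewskit.io` / `mewskit.cli`** — CSV/YAML readers and writers with
  row-level validation, run manifests with input checksums, and the
  umbrella CLI.

## Command-line usage

```bash
# score a vitals file (per-row, or per-patient-day maxima with WZ flags)
mewskit score --vitals vitals.csv --daily-max --threshold 7

# stratified event table and threshold selection
mewskit stratify --scores max_scores.csv --events events.csv --top-bin 9
mewskit select-wz --scores max_scores.csv --events events.csv --alpha 0.05

# incidence and period comparison
mewskit incidence --admissions adm.csv --events events.csv --by-month
mewskit compare --admissions-a before/adm.csv --events-a before/ev.csv \
                --admissions-b after/adm.csv  --events-b after/ev.csv \
                --outcome ihca --alpha 0.01

# synthetic cohorts and intervention simulation
mewskit generate --params params.yaml --seed 1 --out cohort/
mewskit simulate --arm after --theta 0.46 --seed 1 --out sim/

# end-to-end pipeline from a YAML config
mewskit run --config pipeline.yaml --out results/
```

File formats are plain CSV (UTF-8, ISO-8601 dates, empty field = missing);
the score table is a YAML document mirroring the shipped default in
`src/mewskit/data/default_score_table.yaml`, and any subset of it can be
overridden.

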