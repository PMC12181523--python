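# somnoprot

Secondary sleep — napping outside the main nightly sleep episode — is common
in very old adults and increasingly measurable at scale with consumer
wearables. `somnoprot` is a reusable, fully tested pipeline for relating
wearable-derived secondary-sleep phenotypes to plasma proteomic profiles
measured on Olink-style NPX panels, aimed at sleep/aging researchers who
have episode-level sleep logs, a long-format NPX table and a covariate
table — or who want to validate the workflow on simulated cohorts first.

## What it computes

**Sleep phenotyping.** Device-logged sleep episodes (≥ 1 h, per-stage
minutes) are assigned to the calendar day of their wake time. Per day, the
episode with the largest total sleep time (TST = light + deep + REM minutes,
awake excluded) is the *main* sleep; everything else is *secondary*.
Secondary episodes inside 09:00–19:00 are *daytime* sleep, split into
*morning* (ending by noon) and *afternoon* (starting at or after noon).
Days with 24-h TST < 2 h are dropped; participants need ≥ 90 valid days.
Per-participant averages are standardized across the cohort:
`z_i = (x_i − x̄) / s`.

**Association.** For a sleep outcome *y* (z-scored secondary, daytime, or
afternoon TST) and assay NPX matrix **G**, a two-step screen-then-test
workflow:

1. LASSO: `min_b (1/2n)‖y − Xb‖² + λ Σ_j w_j |b_j|` over all assays plus
   covariates (covariates unpenalized, `w_j = 0`), λ by seeded 10-fold CV;
   assays with non-zero coefficients are short-listed.
2. Per short-listed assay *g*: OLS `NPX_g ~ sleep_z + age + sex + BMI +
   steps_z + metabolic + hypertension + arrhythmia/HF + cystatin C` over
   the samples where the assay passed QC.
3. Empirical-Bayes variance moderation: residual variances are shrunk via
   `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` with (d₀, s₀²) moment-matched
   on the observed log-variances; moderated t uses d₀ + d_g df.
4. Benjamini–Hochberg step-up over the short-list; significance at
   q < 0.05. A quadratic variant adds the centered square of the outcome
   and tests that coefficient.

**Enrichment.** Significant proteins are tested against GMT gene sets with
the accumulative hypergeometric tail p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)
over the measured-protein background; terms pass at p < 0.01, overlap ≥ 3
and enrichment factor (k/n)/(K/N) > 1.5, then cluster by Cohen's kappa on
membership vectors (average linkage, similarity threshold 0.3), with the
most significant term representing each cluster.

**Simulation.** `simulate_study` generates a full synthetic study at the
published cohort's conditions — 77 participants aged 80+, ~1 year of daily
logs, main sleep 374 ± 54 min, secondary sleep 6.1 ± 7.8 min/day inversely
coupled to main sleep, 4 panels × 92 assays measuring 355 distinct
proteins, sporadic QC warnings — with planted protein–sleep effects and
enriched terms, so every stage can be checked against ground truth.

## Worked example

```python
from datetime import datetime
from somnoprot import SleepEpisode, build_day_records

def ep(s, e):
    span = int((e - s).total_seconds() // 60)
    return SleepEpisode("P1", s, e, span - 2*(span//3), span//3, span//3, 0)

day = build_day_records([
    ep(datetime(2022, 11, 1, 22, 0), datetime(2022, 11, 2, 4, 0)),
    ep(datetime(2022, 11, 2, 4, 30), datetime(2022, 11, 2, 6, 30)),
    ep(datetime(2022, 11, 2, 10, 30), datetime(2022, 11, 2, 11, 30)),
    ep(datetime(2022, 11, 2, 15, 0), datetime(2022, 11, 2, 17, 0)),
])[0]
print(day.main_tst, day.secondary_tst, day.daytime_tst,
      day.morning_tst, day.afternoon_tst)
```

prints `360 300 180 60 120`: the 22:00–04:00 episode is the main sleep
(6 h); the three naps contribute 5 h of secondary TST, of which the two
between 09:00 and 19:00 give 3 h of daytime TST — 1 h morning
(10:30–11:30) and 2 h afternoon (15:00–17:00). The 04:30–06:30 nap counts
toward secondary sleep but sits outside every daytime window.

A full simulated run:

```bash
somnoprot run-all --config config.yaml
```

with a minimal `config.yaml`:

```yaml
seed: 1
out_dir: runs/demo
simulate: {n_participants: 77, n_days: 365}
```

writes episode logs, NPX tables, phenotypes, per-outcome association
tables, enrichment tables and a manifest with the counts at every filter.

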