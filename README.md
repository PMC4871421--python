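# diarydyn

Per-patient multivariate time-series analysis for daily diary studies:
stationarity-gated bivariate VAR modelling of 0–100 visual-analogue-scale
items, Granger causality in both directions, (orthogonalised) impulse
response functions with Hall bootstrap bands, accumulated impulse
responses, forecast-error variance decomposition, plus linear-trend and
same-day-correlation descriptives. A synthetic diary generator with known
ground truth makes every pipeline stage testable without patient data.

## Layout

| module | contents |
|---|---|
| `diarydyn.diary_io` | wide-CSV reading/writing, validation, gap-filling, regression imputation |
| `diarydyn.stationarity` | augmented Dickey–Fuller test (MacKinnon p-values), stationary-window scan |
| `diarydyn.var_core` | VAR(k) least-squares estimation, lag selection (AIC/FPE/HQ/SC), stability + Portmanteau diagnostics, re-estimation loop |
| `diarydyn.causality_dynamics` | Granger F tests, IRF/OIRF, accumulated IRF, residual bootstrap bands, FEVD |
| `diarydyn.descriptives` | standardised linear time trends, windowed Pearson correlations, cohort summaries |
| `diarydyn.synthetic_data` | seeded VAR-based diary generator and named benchmark scenarios |
| `diarydyn.pipeline` / `diarydyn.cli` | per-patient orchestration, cohort tables, `diarydyn` command line |

## Command line

```bash
# list benchmark scenarios, then generate one synthetic diary
diarydyn simulate --list
diarydyn simulate --scenario unidirectional --seed 1 --out data/diary.csv

# analyse one CSV (or a directory of CSVs) and write reports
diarydyn analyze data/diary.csv --out results/run1
# optional YAML config: alpha, T_min, step, p_max, B, H, band_method,
# window_overrides: {PATIENT_ID: [start_day, end_day]}, ...
diarydyn analyze data/ --config config.yaml --out results/run2

# merge per-patient JSON reports into cohort CSV tables
diarydyn report results/run1 --out results/cohort
```

Input CSVs are wide format with header
`patient_id,group,day,<item...>`, values in `[0,100]`, missing cells empty
or `NA`; absent days become all-missing rows on a gap-free daily grid.
Exit codes: 0 ok, 1 validation error, 2 every patient excluded, 3 hard
error.

## Per-patient procedure

1. missing values imputed by same-day cross-item regression with a linear
   day term (deterministic; optional seeded residual noise);
2. analysis window determined on the focus pair (emotional intolerance ×
   restraint): full range if both pass the ADF gate, otherwise the longest
   stepped window on which both reject the unit root;
3. remaining items ADF-screened on that window (failures excluded with a
   recorded reason);
4. per pair: lag order by consensus of AIC/FPE/HQ/SC, re-estimation at
   higher orders until the eigenvalue stability condition and the adjusted
   Portmanteau test pass;
5. Granger causality in both directions — F(k, 2·T_eff − 4k − 2) with
   T_eff the window length minus the order;
6. orthogonalisation ordering chosen by the significant Granger direction;
   IRF/OIRF with Hall bootstrap bands, accumulated IRF over 10 days, FEVD
   cause-share at 10 days, same-day correlation on the window;
7. trends computed per item on the full participation period.

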