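# lobstat

Analysis toolkit for small-scale trap fisheries managed with periodic
no-take-zone (NTZ) closures: a seeded synthetic survey generator, the
catch/effort raising estimator for monthly landings and value, zero-altered
(hurdle) count models of CPUE, and catch-composition / compliance
statistics. Everything is plain-text in and out (CSV/YAML/JSON).

## Modules

| module | contents |
| --- | --- |
| `lobstat.simulate` | `SimConfig`, `default_config`, `simulate_season`, `simulate_hurdle_counts` — synthetic seasons with exposed ground truth |
| `lobstat.estimation` | boat activity coefficient `B = A/T`, fleet size, monthly CPUE, the raising chain `E = D·B·F`, `L = E·C`, `V = L·P`, imputation, season totals, percent changes, sample-adequacy checks |
| `lobstat.hurdle` | ZAP/ZANB hurdle models by direct maximum likelihood: `fit_hurdle`, `lrt`, `select_family`, `stepwise_simplify`, `predict_cpue`, `residuals_vs_fitted` |
| `lobstat.composition` | species composition by month, berried proportions, under-MLS fraction, two-sample Kolmogorov–Smirnov test, size histograms/KDE, TL~CL regressions, median daily earnings |
| `lobstat.fileio` / `lobstat.cli` | CSV schemas, NTZ calendar, price schedule, YAML configs, the `lobstat` command |

## CLI

```sh
lobstat simulate --seed 7 --outdir sim/            # three CSVs + ground truth
lobstat estimate --surveys sim/daily_surveys.csv \
    --records sim/boat_records.csv --prices prices.csv --out monthly.csv
lobstat model --records sim/boat_records.csv --calendar ntz.csv --out-prefix fit
lobstat compose --lobsters sim/lobsters.csv --out-prefix comp
lobstat report --monthly monthly.csv --out summary.csv
```

`simulate` is fully reproducible: the same config and `--seed` produce
byte-identical files, and every output carries a `config_hash` header.
`estimate` writes one row per month (days, survey occasions, B, F, E, C, L,
P, V); `report` derives the headline statistics (percent change in catch,
value and price at an NTZ opening, CPUE as a percentage of the preceding
months' mean, season totals).

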