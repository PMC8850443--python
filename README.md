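# cropclim

Harmonization and meta-analysis pipeline for projected crop-yield climate
impacts. It consolidates per-simulation yield projections (maize, rice,
soybean, wheat) into a canonical schema and computes the derived statistics a
cross-study assessment needs:

- **corpus** — canonical record schema, validation, CSV/xlsx readers and
  writers bound via a column mapping, ESM ensemble averaging, and the
  top-producing-country filter for grid-aggregated records.
- **impacts** — relative yield impact `(Yf − Yb)/Yb × 100`, the counterfactual
  no-climate-change variant, linear rescaling of effect sizes to a common
  baseline midpoint (2005), and per-decade / per-degree normalizations.
- **adaptation** — matched with/without-adaptation pairing and the adaptation
  potential (percentage-point difference), plus best-planting-time selection.
- **imputation** — random-forest imputation of missing local/global warming
  and precipitation change, with candidate feature sets compared by k-fold CV
  RMSE and out-of-bag explained variance.
- **climate** — half-degree climate-normal grids, point extraction with a
  fixed cell-boundary convention, harvested-area-weighted aggregation, and
  scenario CO₂-concentration interpolation.
- **summaries** — distribution summaries (quartiles, skewness, kurtosis),
  1.5×IQR outlier rules (median- or quartile-anchored), sensitivity reports
  and grouped impact tables.
- **synthetic** — corpus generator with a known yield-response surface,
  left-skewed noise, ~50% missing local warming and matched adaptation pairs,
  so every stage is testable against ground truth.

## CLI

Each pipeline stage is a subcommand of `cropclim`:

```sh
cropclim simulate  --seed 42 --n 2000 --out corpus.csv --truth truth.json
cropclim ingest    --input corpus.csv --out clean.csv --reject-report rejects.csv
cropclim harmonize --input clean.csv --out harmonized.csv
cropclim impute    --input clean.csv --target dTl_2005 --folds 10 --seed 42 \
                   --report report.json --out imputed.csv
cropclim adaptation --input clean.csv --out pairs.csv --report unmatched.csv
cropclim summarize --input clean.csv --group crop,scenario \
                   --metrics per_decade,per_degree --out table.csv
cropclim climate   --grid tave.csv --records clean.csv --out with_climate.csv
```

`--mapping`/`--config` options take JSON or TOML files; see
`cropclim.corpus.ColumnMapping` for the mapping keys (`columns`,
`missing_values`, `sheet`, `unit_scales`).

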