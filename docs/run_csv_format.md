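# Canonical run CSV format

The vendor's exact column set is proprietary, so niptkit defines its own
canonical dialect. It is UTF-8, comma-separated, one header row, one row
per sample (1–16 rows).

## Filename

`YYMMDD_<runid>.csv` — the run date is parsed from the first six
characters. Two-digit years pivot at 80: `00–79 → 20YY`, `80–99 → 19YY`
(the assay era is post-2020). Invalid calendar dates are rejected.

## Optional run-QC header comments

Lines starting with `#` before the header row carry run-level QC
metrics. All are optional:

```
# q30_pct=96.2
# cluster_density_k_mm2=182.0
# library_conc_nM=21.5;33.0;47.2
```

## Columns

| Column | Type | Notes |
| --- | --- | --- |
| `SampleID` | text | unique within the run, non-empty |
| `Barcode` | text | library barcode |
| `SampleType` | enum | `singleton`, `control`, or `unknown` |
| `NCV_13`, `NCV_18`, `NCV_21`, `NCV_X`, `NCV_Y` | float | Z-score-like normalized chromosome values |
| `FF` | float | fetal fraction **in percent** (e.g. `2.3` = 2.3%); stored internally as a fraction |
| `NCD_A`, `NCD_B`, … | float | normalized chromosomal denominator values; any set of `NCD_*` columns is accepted (at least one required) |
| `Cov_chr1` … `Cov_chr22`, `Cov_chrX`, `Cov_chrY` | float ≥ 0 | normalized per-chromosome coverage, autosome-mean-scaled (euploid expectation 1.0) |

Any **unknown extra column** is preserved per sample as a string in
`vendor_qc` and written back verbatim — nothing is silently dropped.

Column order is irrelevant on read; the writer emits the canonical order
above (vendor columns last).

## Error behaviour

Parsing is total: every malformed input raises a typed error, never a
partial batch.

| Condition | Error |
| --- | --- |
| no `YYMMDD` prefix / impossible date | `MalformedFilenameError` |
| missing required column (named in message) | `SchemaError` |
| more than 16 sample rows | `SchemaError` |
| non-numeric cell (row + column named) | `CellValueError` |
| repeated `SampleID` | `DuplicateSampleError` |
| zero sample rows / empty file | `EmptyRunError` |
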