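# niptkit

A headless engine for interpreting noninvasive prenatal testing (NIPT)
results from 16-sample-per-run cfDNA screening assays. It covers the
full desk workflow without a web front-end:

* **I/O** — parse/write a canonical per-run result CSV (NCV, NCD, fetal
  fraction, per-chromosome coverage, vendor QC pass-through) with the
  run date encoded in the `YYMMDD_` filename prefix
  ([format docs](docs/run_csv_format.md));
* **store** — an embedded SQLite run store with an append-only,
  user-tagged audit trail and historical queries for plotting and
  calibration;
* **calibration** — all decision thresholds in one JSON-serializable
  config (defaults: trisomy flag at NCV > 4 with FF ≥ 2%, inconclusive
  on [3, 4]), plus an outlier-robust NCV(X)→NCV(Y) regression with a
  ±3-residual-SD band for sex-chromosome assessment;
* **interpret** — per-sample autosomal calls, sex assessment, sample and
  run QC with red-flag highlights ([rules](docs/interpretation_rules.md));
* **viz/report** — renderer-agnostic chart specs (NCV-vs-FF scatters
  over the historical cloud, NCV X/Y plot with regression band,
  coverage profiles) and PDF reports with HTML twins;
* **synthetic** — a seeded cohort generator with known truth labels,
  including the 84-sample clinical-verification design (47 normal,
  5 T13, 13 T18, 16 T21, 3 SCA over six runs), so everything is testable
  without real data.

## CLI

```bash
# generate the verification cohort (6 run CSVs + truth labels)
niptkit simulate --out-dir runs --seed 20201101 --verification

# import with an audited user, then calibrate the sex regression
niptkit --store lab.db import --user geneticist1 runs/2011*.csv
niptkit --store lab.db calibrate --user geneticist1 --out-config cal.json

# interpret a run against history and render reports
niptkit --store lab.db --config cal.json interpret --user geneticist1 \
    --run 201102_synrun1 --out results.csv
mkdir -p reports
niptkit --store lab.db --config cal.json report    --user geneticist1 --run 201102_synrun1 --out-dir reports
niptkit --store lab.db --config cal.json qc-report --user geneticist1 --run 201102_synrun1 --out-dir reports

# traceability
niptkit --store lab.db list-runs
niptkit --store lab.db audit --out audit.csv
```

Exit codes: 0 success, 1 domain error, 2 usage error.

## Notes

* The engine flags, it does not diagnose; interpretation remains a human
  responsibility, and reports use "consistent with / flag for review"
  wording.
* Per-chromosome assay CVs in the simulator are plausible stand-ins, not
  measured values; see the note at the end of
  [docs/interpretation_rules.md](docs/interpretation_rules.md).
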