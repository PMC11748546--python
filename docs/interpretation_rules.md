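# Interpretation rules and defaults

The engine emits machine flags that *guide* human review; report wording
is "consistent with" / "flag for review", never a diagnosis.

## Autosomal calls (chromosomes 13, 18, 21)

With fetal fraction (FF) at or above `ff_min` (default 2%):

| NCV | Call |
| --- | --- |
| `> ncv_call` (default 4) | `aneuploidy_flag` |
| `[ncv_gray_low, ncv_call]` (default [3, 4], **closed** interval) | `inconclusive` |
| `< ncv_gray_low` | `normal` |

NCV exactly 4 or exactly 3 is inconclusive. `FF < ff_min` yields
`no_call_low_ff` regardless of NCV — low fetal fraction always takes
precedence.

Large **negative** autosomal NCVs (possible monosomy or processing
artefact) are never auto-called; they surface through the symmetric
`|NCV| >= ncv_gray_low` highlight rule while the call stays per the
one-sided table above.

A NaN NCV is `inconclusive` plus a highlight.

## Sex assessment

A regression of NCV(Y) on NCV(X) is fitted on presumed-male calibration
samples (`NCV_Y >= male_ncvY_min`, default 4) with a constant-width band
of ± `band_sd_mult` (default 3) residual standard deviations — the
"99%" band. Presumed females are summarized as an NCV_X cluster
(mean ± SD). The fit sigma-clips gross outliers (default 4 SD) so sex
chromosome aneuploidies present in the calibration set do not distort
the line.

* `NCV_Y >= male_ncvY_min` and inside the band at that NCV_X →
  `xy_consistent`; outside → `sca_flag`.
* Female side: `|NCV_X − female_x_mean| <= band_sd_mult · female_x_sd` →
  `xx_consistent`; outside → `sca_flag`.
* `FF < ff_min` → `no_call_low_ff`.

Two documented conventions (the source material fixes neither): the band
is residual-SD based with constant width, not a pointwise OLS prediction
interval; and the orientation is Y-on-X.

## Sample QC

Highlights (each names the `ThresholdConfig` field that triggered it):

* `|NCD| > ncd_limit` (default 4),
* per-chromosome coverage z-score vs the historical per-chromosome
  mean/SD exceeding `coverage_z_limit` (default 3) in absolute value
  (skipped, with a note, when fewer than 3 historical samples exist),
* `FF < ff_min`.

`qc_status` is `fail` iff FF is below the floor, `warn` if any other
highlight exists, else `pass`.

## Run QC

One finding per metric outside its range; missing metrics produce
"not assessed" findings:

* `q30_pct > q30_min_pct` (default 95),
* `cluster_density_k_mm2` within 140–250,
* every `library_conc_nM` value within 10–250.

## Calibration file

`save_config`/`load_config` read and write a JSON file:

```json
{
  "thresholds": { "ncv_call": 4.0, "ncv_gray_low": 3.0, "ff_min": 0.02,
                  "band_sd_mult": 3.0, "ncd_limit": 4.0,
                  "coverage_z_limit": 3.0, "q30_min_pct": 95.0,
                  "cluster_density_range_k_mm2": [140.0, 250.0],
                  "library_conc_range_nM": [10.0, 250.0],
                  "male_ncvY_min": 4.0 },
  "sex_calibration": { "slope": -1.5, "intercept": 0.0, "resid_sd": 1.0,
                       "n_fit": 40, "female_x_mean": 0.0,
                       "female_x_sd": 1.0, "fitted_on": ["..."] }
}
```

Defaults are the clinically verified values; laboratories are expected
to recalibrate the NCD and coverage limits, which are documented
symmetric-Z stand-ins.

## Synthetic model note

The simulator draws euploid NCVs from Normal(0, 1) and trisomic NCVs
from Normal((ff/2)/cv, 1). The `NCV > 4` rule is therefore meaningful at
FF ≥ 2% **only because the per-chromosome cv defaults are small**
(0.004–0.006); at FF ≈ 2–4% trisomic means sit near the inconclusive
band, deliberately exercising the gray zone.
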