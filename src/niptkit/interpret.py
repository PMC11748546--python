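"""QC rules and classification logic.

The engine emits machine flags that guide human review; it never
diagnoses.  Autosomal calls use a one-sided rule: with adequate fetal
fraction, NCV > ``ncv_call`` flags a possible trisomy, the closed
interval [``ncv_gray_low``, ``ncv_call``] is inconclusive, and values
below it are normal.  NCV exactly at either boundary is inconclusive.
Low fetal fraction (< ``ff_min``) yields a no-call regardless of NCV.

Sex assessment tests a sample against the calibrated male regression
band or, on the female side, against the female NCV_X cluster; points
falling outside are flagged for possible sex-chromosome aneuploidy.

Large negative autosomal NCVs are never auto-called; they are surfaced
through a symmetric ``|NCV| >= ncv_gray_low`` highlight so a reviewer
sees possible monosomies or processing artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import SexCalibration, ThresholdConfig, band_bounds
from .models import ALL_CHROMS, HistoricalSet, RunBatch, SampleRecord

AUTOSOME_TARGETS = ("13", "18", "21")

# autosome call values
NORMAL = "normal"
INCONCLUSIVE = "inconclusive"
ANEUPLOIDY_FLAG = "aneuploidy_flag"
NO_CALL_LOW_FF = "no_call_low_ff"

# sex assessment values
XX_CONSISTENT = "xx_consistent"
XY_CONSISTENT = "xy_consistent"
SCA_FLAG = "sca_flag"

QC_PASS = "pass"
QC_WARN = "warn"
QC_FAIL = "fail"


@dataclass
class Highlight:
    """One out-of-threshold value; ``rule`` names a ThresholdConfig field."""

    field: str
    value: float
    rule: str


@dataclass
class Interpretation:
    sample_id: str
    autosome_calls: dict[str, str] = field(default_factory=dict)
    sex_assessment: str = NO_CALL_LOW_FF
    qc_status: str = QC_PASS
    highlights: list[Highlight] = field(default_factory=list)
    run_qc_findings: list[str] = field(default_factory=list)

    def is_euploid_normal(self) -> bool:
        """Normal on all of 13/18/21 (used for historical reference sets)."""
        return all(
            self.autosome_calls.get(c) == NORMAL for c in AUTOSOME_TARGETS
        )


def classify_autosome(ncv: float, ff: float, cfg: ThresholdConfig) -> str:
    """Classify one autosomal NCV under the printed decision rule.

    ff < ff_min -> no-call; NCV > ncv_call -> aneuploidy flag;
    ncv_gray_low <= NCV <= ncv_call -> inconclusive (closed interval);
    below -> normal.  A NaN NCV is inconclusive (flagged upstream).
    """
    if ff < cfg.ff_min:
        return NO_CALL_LOW_FF
    if math.isnan(ncv):
        return INCONCLUSIVE
    if ncv > cfg.ncv_call:
        return ANEUPLOIDY_FLAG
    if ncv >= cfg.ncv_gray_low:
        return INCONCLUSIVE
    return NORMAL


def assess_sex(
    ncv_x: float,
    ncv_y: float,
    ff: float,
    calib: SexCalibration,
    cfg: ThresholdConfig,
) -> str:
    """Assess sex-chromosome consistency against the calibration.

    Male side (NCV_Y >= male_ncvY_min): inside the regression band at
    ncv_x -> XY-consistent, outside -> SCA flag.  Female side: within
    band_sd_mult female SDs of the female NCV_X mean -> XX-consistent,
    outside -> SCA flag.  Low fetal fraction -> no-call.
    """
    if ff < cfg.ff_min:
        return NO_CALL_LOW_FF
    if ncv_y >= cfg.male_ncvY_min:
        low, high = band_bounds(calib, cfg, ncv_x)
        return XY_CONSISTENT if low <= ncv_y <= high else SCA_FLAG
    if abs(ncv_x - calib.female_x_mean) <= cfg.band_sd_mult * calib.female_x_sd:
        return XX_CONSISTENT
    return SCA_FLAG


def _coverage_stats(history: HistoricalSet) -> dict[str, tuple[float, float]]:
    records = history.records()
    stats: dict[str, tuple[float, float]] = {}
    if len(records) < 3:
        return stats
    for chrom in ALL_CHROMS:
        vals = np.array([r.coverage[chrom] for r in records], dtype=float)
        sd = float(np.std(vals, ddof=1))
        if sd > 0:
            stats[chrom] = (float(np.mean(vals)), sd)
    return stats


def qc_sample(
    rec: SampleRecord, history: HistoricalSet, cfg: ThresholdConfig
) -> tuple[str, list[Highlight], list[str]]:
    """Per-sample QC: NCD limits, coverage outliers vs history, FF floor.

    Returns ``(qc_status, highlights, notes)``.  Status is ``fail`` iff
    FF is below the minimum, ``warn`` if any other highlight exists,
    ``pass`` otherwise.  With fewer than 3 historical samples the
    coverage z-check is skipped and noted.
    """
    highlights: list[Highlight] = []
    notes: list[str] = []

    for label, value in rec.ncd.items():
        if abs(value) > cfg.ncd_limit:
            highlights.append(Highlight(f"NCD_{label}", value, "ncd_limit"))

    stats = _coverage_stats(history)
    if stats:
        for chrom in ALL_CHROMS:
            if chrom not in stats:
                continue
            mean, sd = stats[chrom]
            z = (rec.coverage[chrom] - mean) / sd
            if abs(z) > cfg.coverage_z_limit:
                highlights.append(
                    Highlight(f"Cov_chr{chrom}", rec.coverage[chrom],
                              "coverage_z_limit")
                )
    else:
        notes.append("coverage z-check skipped: insufficient history")

    low_ff = rec.ff < cfg.ff_min
    if low_ff:
        highlights.append(Highlight("FF", rec.ff, "ff_min"))

    if low_ff:
        status = QC_FAIL
    elif highlights:
        status = QC_WARN
    else:
        status = QC_PASS
    return status, highlights, notes


def qc_run(batch: RunBatch, cfg: ThresholdConfig) -> list[str]:
    """Run-level QC findings; missing metrics yield 'not assessed'."""
    findings: list[str] = []
    qc = batch.run_qc or {}

    q30 = qc.get("q30_pct")
    if q30 is None:
        findings.append("q30_pct not assessed (metric missing)")
    elif q30 <= cfg.q30_min_pct:
        findings.append(
            f"q30_pct {q30:g} below minimum {cfg.q30_min_pct:g}"
        )

    density = qc.get("cluster_density_k_mm2")
    lo, hi = cfg.cluster_density_range_k_mm2
    if density is None:
        findings.append("cluster_density_k_mm2 not assessed (metric missing)")
    elif not lo <= density <= hi:
        findings.append(
            f"cluster_density_k_mm2 {density:g} outside range [{lo:g}, {hi:g}]"
        )

    concs = qc.get("library_conc_nM")
    lo, hi = cfg.library_conc_range_nM
    if not concs:
        findings.append("library_conc_nM not assessed (metric missing)")
    else:
        bad = [c for c in concs if not lo <= c <= hi]
        if bad:
            findings.append(
                f"library_conc_nM: {len(bad)} value(s) outside "
                f"range [{lo:g}, {hi:g}] (worst {max(bad, key=abs):g})"
            )
    return findings


def interpret_run(
    batch: RunBatch,
    history: HistoricalSet,
    calib: SexCalibration | None,
    cfg: ThresholdConfig,
) -> list[Interpretation]:
    """Compose QC + classification into one Interpretation per sample.

    Deterministic given inputs.  If no calibration is supplied the sex
    assessment is skipped (reported as a no-call with a note).
    """
    run_findings = qc_run(batch, cfg)
    out: list[Interpretation] = []
    for rec in batch.samples:
        status, highlights, notes = qc_sample(rec, history, cfg)

        calls = {
            c: classify_autosome(rec.ncv[c], rec.ff, cfg)
            for c in AUTOSOME_TARGETS
        }
        for c in AUTOSOME_TARGETS:
            value = rec.ncv[c]
            if math.isnan(value) or abs(value) >= cfg.ncv_gray_low:
                highlights.append(Highlight(f"NCV_{c}", value, "ncv_gray_low"))

        if calib is not None:
            sex = assess_sex(rec.ncv["X"], rec.ncv["Y"], rec.ff, calib, cfg)
        else:
            sex = NO_CALL_LOW_FF
            notes.append("sex assessment skipped: no calibration available")
        if sex == SCA_FLAG:
            highlights.append(Highlight("NCV_X", rec.ncv["X"], "band_sd_mult"))

        if status == QC_PASS and highlights:
            status = QC_WARN
        out.append(
            Interpretation(
                sample_id=rec.sample_id,
                autosome_calls=calls,
                sex_assessment=sex,
                qc_status=status,
                highlights=highlights,
                run_qc_findings=run_findings + notes,
            )
        )
    return out


def interpretations_to_rows(interps: list[Interpretation]) -> list[dict]:
    """Flatten to one row per sample-chromosome call (results CSV shape)."""
    rows = []
    for itp in interps:
        for chrom in AUTOSOME_TARGETS:
            rows.append(
                {
                    "sample_id": itp.sample_id,
                    "chromosome": chrom,
                    "call": itp.autosome_calls[chrom],
                    "sex_assessment": itp.sex_assessment,
                    "qc_status": itp.qc_status,
                    "n_highlights": len(itp.highlights),
                }
            )
    return rows
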