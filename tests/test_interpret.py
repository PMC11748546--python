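import math

import pytest

from niptkit.calibration import ThresholdConfig
from niptkit.interpret import (
    ANEUPLOIDY_FLAG,
    INCONCLUSIVE,
    NORMAL,
    NO_CALL_LOW_FF,
    QC_FAIL,
    QC_PASS,
    QC_WARN,
    SCA_FLAG,
    XX_CONSISTENT,
    XY_CONSISTENT,
    assess_sex,
    classify_autosome,
    interpret_run,
    qc_run,
    qc_sample,
)
from niptkit.models import EMPTY_HISTORY, HistoricalSet

from conftest import make_batch, make_sample


class TestClassifyAutosome:
    @pytest.mark.parametrize(
        "ncv,ff,expected",
        [
            (5.0, 0.03, ANEUPLOIDY_FLAG),
            (3.5, 0.05, INCONCLUSIVE),
            (10.0, 0.015, NO_CALL_LOW_FF),
            (0.0, 0.10, NORMAL),
        ],
    )
    def test_examples(self, cfg, ncv, ff, expected):
        assert classify_autosome(ncv, ff, cfg) == expected

    def test_boundaries_closed_gray_interval(self, cfg):
        assert classify_autosome(4.0, 0.05, cfg) == INCONCLUSIVE
        assert classify_autosome(3.0, 0.05, cfg) == INCONCLUSIVE
        assert classify_autosome(4.0 + 1e-9, 0.05, cfg) == ANEUPLOIDY_FLAG
        assert classify_autosome(3.0 - 1e-9, 0.05, cfg) == NORMAL

    def test_ff_boundary(self, cfg):
        assert classify_autosome(10.0, 0.02, cfg) == ANEUPLOIDY_FLAG
        assert classify_autosome(10.0, 0.02 - 1e-12, cfg) == NO_CALL_LOW_FF

    def test_nan_is_inconclusive(self, cfg):
        assert classify_autosome(float("nan"), 0.05, cfg) == INCONCLUSIVE

    def test_low_ff_precedence_over_everything(self, cfg):
        for ncv in (-50.0, 0.0, 3.5, 50.0, float("nan")):
            assert classify_autosome(ncv, 0.001, cfg) == NO_CALL_LOW_FF

    def test_monotone_severity_in_ncv(self, cfg):
        rank = {NORMAL: 0, INCONCLUSIVE: 1, ANEUPLOIDY_FLAG: 2}
        calls = [
            rank[classify_autosome(x / 10.0, 0.05, cfg)] for x in range(-50, 101)
        ]
        assert calls == sorted(calls)

    def test_large_negative_not_autocalled(self, cfg):
        assert classify_autosome(-8.0, 0.05, cfg) == NORMAL


class TestAssessSex:
    def test_male_on_line_consistent(self, calib, cfg):
        assert assess_sex(-10.0, 15.0, 0.08, calib, cfg) == XY_CONSISTENT

    def test_female_baseline_consistent(self, calib, cfg):
        assert assess_sex(0.5, 0.2, 0.08, calib, cfg) == XX_CONSISTENT

    def test_monosomy_x_like(self, calib, cfg):
        # X depleted as in a male, Y absent: female side, far off cluster
        assert assess_sex(-8.0, 0.0, 0.08, calib, cfg) == SCA_FLAG

    def test_xxy_like(self, calib, cfg):
        # Y elevated but X at female baseline: off the male line
        assert assess_sex(0.0, 15.0, 0.08, calib, cfg) == SCA_FLAG

    def test_xyy_like(self, calib, cfg):
        # Y at twice the male level for this X
        assert assess_sex(-10.0, 30.0, 0.08, calib, cfg) == SCA_FLAG

    def test_low_ff_no_call(self, calib, cfg):
        assert assess_sex(-10.0, 15.0, 0.01, calib, cfg) == NO_CALL_LOW_FF

    def test_band_edges_inclusive(self, calib, cfg):
        # center at x=-10 is 15, half-width 3*1.0
        assert assess_sex(-10.0, 18.0, 0.08, calib, cfg) == XY_CONSISTENT
        assert assess_sex(-10.0, 18.001, 0.08, calib, cfg) == SCA_FLAG


def _history(n=30, cov_jitter=0.01):
    import numpy as np

    rng = np.random.default_rng(11)
    from niptkit.models import ALL_CHROMS

    samples = tuple(
        (
            make_sample(
                f"H{i}",
                coverage={
                    c: float(rng.normal(1.0, cov_jitter)) for c in ALL_CHROMS
                },
            ),
            "200101_hist",
            None,
        )
        for i in range(n)
    )
    return HistoricalSet(samples=samples, filter_spec="test history")


class TestQcSample:
    def test_nominal_sample_passes(self, cfg):
        status, highlights, _ = qc_sample(make_sample(), _history(), cfg)
        assert status == QC_PASS
        assert highlights == []

    def test_ncd_highlight(self, cfg):
        status, highlights, _ = qc_sample(
            make_sample(ncd={"A": 5.2, "B": 0.0}), _history(), cfg
        )
        assert status == QC_WARN
        assert len(highlights) == 1
        assert highlights[0].field == "NCD_A"
        assert highlights[0].rule == "ncd_limit"

    def test_low_ff_fails(self, cfg):
        status, highlights, _ = qc_sample(make_sample(ff=0.01), _history(), cfg)
        assert status == QC_FAIL
        assert any(h.rule == "ff_min" for h in highlights)

    def test_coverage_outlier_highlight(self, cfg):
        rec = make_sample(coverage={"7": 1.2})
        status, highlights, _ = qc_sample(rec, _history(), cfg)
        assert status == QC_WARN
        assert any(h.field == "Cov_chr7" and h.rule == "coverage_z_limit"
                   for h in highlights)

    def test_empty_history_skips_coverage_check(self, cfg):
        rec = make_sample(coverage={"7": 5.0})
        status, highlights, notes = qc_sample(rec, EMPTY_HISTORY, cfg)
        assert status == QC_PASS
        assert highlights == []
        assert any("skipped" in n for n in notes)

    def test_every_highlight_rule_names_config_field(self, cfg):
        rec = make_sample(ff=0.001, ncd={"A": 9.0, "B": -9.0},
                          coverage={"3": 2.0})
        _, highlights, _ = qc_sample(rec, _history(), cfg)
        for h in highlights:
            assert hasattr(cfg, h.rule)


class TestQcRun:
    def test_nominal_run(self, cfg):
        batch = make_batch(run_qc={
            "q30_pct": 96.2,
            "cluster_density_k_mm2": 180.0,
            "library_conc_nM": [50.0, 60.0],
        })
        assert qc_run(batch, cfg) == []

    def test_density_out_of_range(self, cfg):
        batch = make_batch(run_qc={
            "q30_pct": 96.2,
            "cluster_density_k_mm2": 300.0,
            "library_conc_nM": [50.0],
        })
        findings = qc_run(batch, cfg)
        assert len(findings) == 1
        assert "cluster_density" in findings[0]

    def test_low_q30(self, cfg):
        batch = make_batch(run_qc={
            "q30_pct": 94.0,
            "cluster_density_k_mm2": 180.0,
            "library_conc_nM": [50.0],
        })
        assert any("q30" in f for f in qc_run(batch, cfg))

    def test_conc_out_of_range(self, cfg):
        batch = make_batch(run_qc={
            "q30_pct": 97.0,
            "cluster_density_k_mm2": 180.0,
            "library_conc_nM": [50.0, 400.0],
        })
        assert any("library_conc" in f for f in qc_run(batch, cfg))

    def test_all_missing_yields_not_assessed(self, cfg):
        findings = qc_run(make_batch(run_qc={}), cfg)
        assert len(findings) == 3
        assert all("not assessed" in f for f in findings)


class TestInterpretRun:
    def test_one_interpretation_per_sample(self, calib, cfg):
        batch = make_batch(n=5)
        interps = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        assert [i.sample_id for i in interps] == batch.sample_ids

    def test_deterministic(self, calib, cfg):
        batch = make_batch(n=4)
        a = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        b = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        assert a == b

    def test_all_euploid_run_no_flags(self, calib, cfg):
        batch = make_batch(n=8)
        interps = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        for itp in interps:
            assert all(c == NORMAL for c in itp.autosome_calls.values())
            assert itp.sex_assessment == XX_CONSISTENT

    def test_trisomy_sample_flagged_and_highlighted(self, calib, cfg):
        batch = make_batch(n=1)
        batch.samples[0].ncv["21"] = 9.0
        itp = interpret_run(batch, EMPTY_HISTORY, calib, cfg)[0]
        assert itp.autosome_calls["21"] == ANEUPLOIDY_FLAG
        assert any(h.field == "NCV_21" and h.rule == "ncv_gray_low"
                   for h in itp.highlights)
        assert itp.qc_status == QC_WARN

    def test_negative_ncv_highlighted_but_normal(self, calib, cfg):
        batch = make_batch(n=1)
        batch.samples[0].ncv["13"] = -6.0
        itp = interpret_run(batch, EMPTY_HISTORY, calib, cfg)[0]
        assert itp.autosome_calls["13"] == NORMAL
        assert any(h.field == "NCV_13" for h in itp.highlights)

    def test_nan_ncv_inconclusive_with_highlight(self, calib, cfg):
        batch = make_batch(n=1)
        batch.samples[0].ncv["18"] = math.nan
        itp = interpret_run(batch, EMPTY_HISTORY, calib, cfg)[0]
        assert itp.autosome_calls["18"] == INCONCLUSIVE
        assert any(h.field == "NCV_18" for h in itp.highlights)

    def test_no_calibration_sex_skipped(self, cfg):
        batch = make_batch(n=1)
        itp = interpret_run(batch, EMPTY_HISTORY, None, cfg)[0]
        assert itp.sex_assessment == NO_CALL_LOW_FF
        assert any("calibration" in n for n in itp.run_qc_findings)

    def test_run_findings_attached(self, calib, cfg):
        batch = make_batch(n=2, run_qc={"q30_pct": 90.0})
        interps = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        for itp in interps:
            assert any("q30" in f for f in itp.run_qc_findings)
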