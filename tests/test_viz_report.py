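import datetime as dt

import pytest

from niptkit.errors import MissingInterpretationError
from niptkit.interpret import interpret_run
from niptkit.models import EMPTY_HISTORY, HistoricalSet
from niptkit.viz_report import (
    NIPT_REPORT,
    QC_REPORT,
    build_charts,
    charts_to_json,
    render_report,
)

from conftest import make_batch, make_sample


def _history(n=70):
    samples = tuple(
        (make_sample(f"H{i}"), "201001_hist", dt.date(2020, 10, 1))
        for i in range(n)
    )
    return HistoricalSet(samples=samples, filter_spec="70 normals")


class TestBuildCharts:
    def test_chart_inventory(self, calib, cfg):
        batch = make_batch(n=14)
        charts = build_charts(batch, _history(70), calib, cfg)
        kinds = [c.kind for c in charts]
        assert kinds.count("ncv_vs_ff") == 5
        assert kinds.count("ncvx_vs_ncvy") == 1
        assert kinds.count("coverage_profile") == 14

    def test_point_counts(self, calib, cfg):
        batch = make_batch(n=14)
        charts = build_charts(batch, _history(70), calib, cfg)
        chr21 = [c for c in charts if "chr21" in c.title][0]
        assert len(chr21.current_points) == 14
        assert len(chr21.history_points) == 70

    def test_threshold_overlays_on_autosome_charts(self, calib, cfg):
        charts = build_charts(make_batch(), _history(), calib, cfg)
        chr21 = [c for c in charts if "chr21" in c.title][0]
        ys = {ov["y"] for ov in chr21.overlays if ov["type"] == "hline"}
        assert ys == {3.0, 4.0}

    def test_sex_chart_has_regression_and_band(self, calib, cfg):
        charts = build_charts(make_batch(), _history(), calib, cfg)
        sex = [c for c in charts if c.kind == "ncvx_vs_ncvy"][0]
        types = {ov["type"] for ov in sex.overlays}
        assert types == {"line", "band"}
        line = [ov for ov in sex.overlays if ov["type"] == "line"][0]
        assert line["slope"] == calib.slope
        band = [ov for ov in sex.overlays if ov["type"] == "band"][0]
        assert band["sd_mult"] == cfg.band_sd_mult

    def test_empty_history(self, calib, cfg):
        charts = build_charts(make_batch(), EMPTY_HISTORY, calib, cfg)
        for c in charts:
            assert c.history_points == []

    def test_current_sample_ids_exist_in_run(self, calib, cfg):
        batch = make_batch(n=4)
        charts = build_charts(batch, _history(10), calib, cfg)
        ids = set(batch.sample_ids)
        for c in charts:
            for _x, _y, sid in c.current_points:
                assert sid in ids

    def test_determinism(self, calib, cfg):
        batch = make_batch(n=4)
        a = build_charts(batch, _history(10), calib, cfg)
        b = build_charts(batch, _history(10), calib, cfg)
        assert [c.to_dict() for c in a] == [c.to_dict() for c in b]

    def test_json_export(self, calib, cfg):
        import json

        charts = build_charts(make_batch(), _history(5), calib, cfg)
        payload = json.loads(charts_to_json(charts))
        assert len(payload) == len(charts)


class TestRenderReport:
    def _render(self, tmp_path, calib, cfg, batch=None, kind=NIPT_REPORT,
                history=None):
        batch = batch or make_batch(n=3)
        history = history if history is not None else _history(10)
        interps = interpret_run(batch, history, calib, cfg)
        charts = build_charts(batch, history, calib, cfg)
        out = tmp_path / f"{batch.run_id}_{kind}.pdf"
        pdf = render_report(batch, interps, charts, kind, out,
                            user="g1", cfg=cfg, calib=calib)
        return pdf, out.with_suffix(".html"), interps

    def test_pdf_and_html_twin_written(self, tmp_path, calib, cfg):
        pdf, html, _ = self._render(tmp_path, calib, cfg)
        assert html.exists()
        assert open(pdf, "rb").read(5) == b"%PDF-"

    def test_html_structure(self, tmp_path, calib, cfg):
        batch = make_batch(n=3)
        _, html_path, _ = self._render(tmp_path, calib, cfg, batch=batch)
        text = html_path.read_text()
        assert text.count("<svg") >= 7  # 5 NCV/FF + sex + >=1 coverage
        assert text.count("<tr>") >= 3  # one row per sample
        assert "g1" in text
        assert batch.run_date.isoformat() in text
        assert "ncv_call" in text  # config version block

    def test_zero_highlight_run_has_no_red_cells(self, tmp_path, calib, cfg):
        _, html_path, interps = self._render(tmp_path, calib, cfg)
        assert all(not i.highlights for i in interps)
        assert 'class="highlight"' not in html_path.read_text()

    def test_styled_cell_count_equals_highlight_count(self, tmp_path, calib,
                                                      cfg):
        batch = make_batch(n=4)
        batch.samples[0].ncv["21"] = 9.0
        batch.samples[1].ncd["A"] = 8.0
        batch.samples[2].ff = 0.01
        _, html_path, interps = self._render(tmp_path, calib, cfg,
                                             batch=batch)
        n_highlights = sum(len(i.highlights) for i in interps)
        assert n_highlights > 0
        assert html_path.read_text().count('class="highlight"') == n_highlights

    def test_qc_report_includes_findings(self, tmp_path, calib, cfg):
        batch = make_batch(n=2, run_qc={"q30_pct": 90.0})
        _, html_path, _ = self._render(tmp_path, calib, cfg, batch=batch,
                                       kind=QC_REPORT)
        text = html_path.read_text()
        assert "Run QC findings" in text
        assert "q30" in text

    def test_missing_interpretation_raises(self, tmp_path, calib, cfg):
        batch = make_batch(n=3)
        interps = interpret_run(batch, EMPTY_HISTORY, calib, cfg)[:2]
        charts = build_charts(batch, EMPTY_HISTORY, calib, cfg)
        with pytest.raises(MissingInterpretationError):
            render_report(batch, interps, charts, NIPT_REPORT,
                          tmp_path / "x.pdf")

    def test_export_audited_when_store_given(self, tmp_path, calib, cfg):
        from niptkit.store import Store

        batch = make_batch(n=2)
        interps = interpret_run(batch, EMPTY_HISTORY, calib, cfg)
        charts = build_charts(batch, EMPTY_HISTORY, calib, cfg)
        with Store(tmp_path / "s.db") as store:
            store.import_run(batch, "g1")
            render_report(batch, interps, charts, NIPT_REPORT,
                          tmp_path / "r.pdf", user="g1", store=store)
            assert [e.action for e in store.audit_log()] == [
                "import", "report_export",
            ]
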