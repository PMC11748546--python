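"""Chart data construction and report rendering.

:class:`ChartSpec` is a renderer-agnostic description of one chart: the
current run's points, the historical cloud behind them, and overlay
descriptors (threshold separator lines, the sex regression line and its
confidence band).  :func:`build_charts` produces, per run:

* five NCV-vs-FF scatters (chromosomes 13, 18, 21, X, Y) with separator
  lines at the inconclusive and call thresholds,
* one NCV_X-vs-NCV_Y scatter with the fitted regression line and band,
* one 24-chromosome coverage profile per sample.

Reports are rendered as a PDF plus an HTML twin with identical content;
the HTML twin is the stable test surface (PDF byte output is
toolchain-dependent).  Every highlight in an interpretation appears as
exactly one red-styled element in the report table.
"""

from __future__ import annotations

import datetime as _dt
import html
import io as _stdio
import json
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages

from .calibration import SexCalibration, ThresholdConfig, band_bounds
from .errors import MissingInterpretationError
from .interpret import AUTOSOME_TARGETS, Interpretation
from .models import ALL_CHROMS, NCV_CHROMS, HistoricalSet, RunBatch

NIPT_REPORT = "nipt_report"
QC_REPORT = "qc_report"


@dataclass
class ChartSpec:
    """One chart: kind, current/history point clouds, overlay descriptors."""

    kind: str  # ncv_vs_ff | ncvx_vs_ncvy | coverage_profile
    title: str
    x_label: str
    y_label: str
    current_points: list[tuple[float, float, str]] = field(default_factory=list)
    history_points: list[tuple[float, float]] = field(default_factory=list)
    overlays: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "title": self.title,
            "x_label": self.x_label,
            "y_label": self.y_label,
            "current_points": [list(p) for p in self.current_points],
            "history_points": [list(p) for p in self.history_points],
            "overlays": self.overlays,
        }


def charts_to_json(charts: list[ChartSpec]) -> str:
    return json.dumps([c.to_dict() for c in charts], indent=2)


def build_charts(
    batch: RunBatch,
    history: HistoricalSet,
    calib: SexCalibration | None,
    cfg: ThresholdConfig,
) -> list[ChartSpec]:
    """Build all chart specs for one run over its historical cloud.

    Deterministic: point order follows sample order within the run and
    (run_date, run_id, position) for history.  Current and historical
    points are disjoint by construction (history never includes the run
    under review; the store guarantees exclusion, this function just
    plots what it is given).
    """
    charts: list[ChartSpec] = []

    for chrom in NCV_CHROMS:
        spec = ChartSpec(
            kind="ncv_vs_ff",
            title=f"NCV chr{chrom} vs fetal fraction",
            x_label="Fetal fraction (%)",
            y_label=f"NCV chr{chrom}",
            current_points=[
                (s.ff * 100.0, s.ncv[chrom], s.sample_id)
                for s in batch.samples
            ],
            history_points=[
                (s.ff * 100.0, s.ncv[chrom])
                for s, _rid, _rd in history.samples
            ],
        )
        if chrom in AUTOSOME_TARGETS:
            spec.overlays = [
                {"type": "hline", "y": cfg.ncv_gray_low,
                 "label": "inconclusive threshold (ncv_gray_low)"},
                {"type": "hline", "y": cfg.ncv_call,
                 "label": "call threshold (ncv_call)"},
            ]
        charts.append(spec)

    sex_spec = ChartSpec(
        kind="ncvx_vs_ncvy",
        title="NCV X vs NCV Y",
        x_label="NCV X",
        y_label="NCV Y",
        current_points=[
            (s.ncv["X"], s.ncv["Y"], s.sample_id) for s in batch.samples
        ],
        history_points=[
            (s.ncv["X"], s.ncv["Y"]) for s, _rid, _rd in history.samples
        ],
    )
    if calib is not None:
        xs = [p[0] for p in sex_spec.current_points + [
            (x, y, "") for x, y in sex_spec.history_points]]
        x_lo = min(xs + [-1.0]) - 1.0
        x_hi = max(xs + [1.0]) + 1.0
        lo_l, hi_l = band_bounds(calib, cfg, x_lo)
        lo_r, hi_r = band_bounds(calib, cfg, x_hi)
        sex_spec.overlays = [
            {
                "type": "line",
                "slope": calib.slope,
                "intercept": calib.intercept,
                "x_range": [x_lo, x_hi],
                "label": "sex regression line",
            },
            {
                "type": "band",
                "x_range": [x_lo, x_hi],
                "low": [lo_l, lo_r],
                "high": [hi_l, hi_r],
                "sd_mult": cfg.band_sd_mult,
                "label": "confidence band (band_sd_mult)",
            },
        ]
    charts.append(sex_spec)

    hist_records = history.records()
    hist_mean = {}
    if hist_records:
        for chrom in ALL_CHROMS:
            vals = [r.coverage[chrom] for r in hist_records]
            hist_mean[chrom] = sum(vals) / len(vals)
    for s in batch.samples:
        charts.append(
            ChartSpec(
                kind="coverage_profile",
                title=f"Coverage profile: {s.sample_id}",
                x_label="Chromosome",
                y_label="Normalized coverage",
                current_points=[
                    (i + 1, s.coverage[c], s.sample_id)
                    for i, c in enumerate(ALL_CHROMS)
                ],
                history_points=[
                    (i + 1, hist_mean[c]) for i, c in enumerate(ALL_CHROMS)
                ]
                if hist_mean
                else [],
                overlays=[
                    {"type": "hline", "y": 1.0, "label": "euploid expectation"}
                ],
            )
        )
    return charts


def _render_chart(spec: ChartSpec, ax) -> None:
    if spec.history_points:
        hx = [p[0] for p in spec.history_points]
        hy = [p[1] for p in spec.history_points]
        ax.scatter(hx, hy, s=12, c="#b0b0b0", label="history", zorder=1)
    if spec.current_points:
        cx = [p[0] for p in spec.current_points]
        cy = [p[1] for p in spec.current_points]
        ax.scatter(cx, cy, s=24, c="#1f77b4", label="current run", zorder=3)
    for ov in spec.overlays:
        if ov["type"] == "hline":
            ax.axhline(ov["y"], color="#d62728", lw=1, ls="--", zorder=2)
        elif ov["type"] == "line":
            x0, x1 = ov["x_range"]
            ax.plot(
                [x0, x1],
                [ov["slope"] * x0 + ov["intercept"],
                 ov["slope"] * x1 + ov["intercept"]],
                color="#2ca02c", lw=1.2, zorder=2,
            )
        elif ov["type"] == "band":
            ax.fill_between(
                ov["x_range"], ov["low"], ov["high"],
                color="#2ca02c", alpha=0.15, zorder=0,
            )
    ax.set_title(spec.title, fontsize=9)
    ax.set_xlabel(spec.x_label, fontsize=8)
    ax.set_ylabel(spec.y_label, fontsize=8)
    ax.tick_params(labelsize=7)


def _chart_svg(spec: ChartSpec) -> str:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    _render_chart(spec, ax)
    buf = _stdio.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


_CSS = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 3px 8px; font-size: 12px; }
.highlight { background: #ffd7d7; color: #b00000; font-weight: bold; }
.charts svg { margin: 8px; }
"""


def _call_table_html(
    batch: RunBatch, interps_by_id: dict[str, Interpretation]
) -> str:
    head = (
        "<tr><th>Sample</th><th>Type</th><th>FF (%)</th>"
        + "".join(f"<th>NCV {c}</th>" for c in NCV_CHROMS)
        + "".join(f"<th>Call {c}</th>" for c in AUTOSOME_TARGETS)
        + "<th>Sex assessment</th><th>QC</th><th>Flags</th></tr>"
    )
    rows = []
    for s in batch.samples:
        itp = interps_by_id[s.sample_id]
        flags = " ".join(
            f'<span class="highlight">{html.escape(h.field)}='
            f"{h.value:.4g} ({html.escape(h.rule)})</span>"
            for h in itp.highlights
        )
        cells = [
            f"<td>{html.escape(s.sample_id)}</td>",
            f"<td>{html.escape(s.sample_type)}</td>",
            f"<td>{s.ff * 100.0:.2f}</td>",
        ]
        cells += [f"<td>{s.ncv[c]:.3f}</td>" for c in NCV_CHROMS]
        cells += [
            f"<td>{html.escape(itp.autosome_calls[c])}</td>"
            for c in AUTOSOME_TARGETS
        ]
        cells.append(f"<td>{html.escape(itp.sex_assessment)}</td>")
        cells.append(f"<td>{html.escape(itp.qc_status)}</td>")
        cells.append(f"<td>{flags}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return f"<table>{head}{''.join(rows)}</table>"


def render_report(
    batch: RunBatch,
    interpretations: list[Interpretation],
    charts: list[ChartSpec],
    kind: str,
    out,
    user: str = "",
    cfg: ThresholdConfig | None = None,
    calib: SexCalibration | None = None,
    store=None,
) -> str:
    """Render a PDF report (plus an ``.html`` twin) and return the PDF path.

    ``kind`` is ``nipt_report`` or ``qc_report``; the QC variant adds the
    run-level QC findings section.  Raises
    :class:`MissingInterpretationError` when any sample in the batch
    lacks an interpretation.  When a store is supplied the export is
    recorded as a ``report_export`` audit entry.
    """
    if kind not in (NIPT_REPORT, QC_REPORT):
        raise ValueError(f"unknown report kind {kind!r}")
    interps_by_id = {itp.sample_id: itp for itp in interpretations}
    missing = [s.sample_id for s in batch.samples if s.sample_id not in interps_by_id]
    if missing:
        raise MissingInterpretationError(
            f"no interpretation for sample(s): {', '.join(missing)}"
        )

    out = os.fspath(out)
    html_path = os.path.splitext(out)[0] + ".html"

    cfg_desc = (
        json.dumps(cfg.to_dict(), sort_keys=True) if cfg is not None else "n/a"
    )
    calib_desc = (
        json.dumps(calib.to_dict(), sort_keys=True)
        if calib is not None
        else "n/a"
    )
    findings = interpretations[0].run_qc_findings if interpretations else []

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html.escape(kind)} {html.escape(batch.run_id)}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>{'NIPT report' if kind == NIPT_REPORT else 'NIPT QC report'}</h1>",
        "<table class='meta'>",
        f"<tr><th>Run</th><td>{html.escape(batch.run_id)}</td></tr>",
        f"<tr><th>Run date</th><td>{batch.run_date.isoformat()}</td></tr>",
        f"<tr><th>Source file</th><td>{html.escape(batch.source_filename)}</td></tr>",
        f"<tr><th>Samples</th><td>{len(batch.samples)}</td></tr>",
        f"<tr><th>Exported by</th><td>{html.escape(user or 'unknown')}</td></tr>",
        f"<tr><th>Exported at (UTC)</th><td>"
        f"{_dt.datetime.now(_dt.timezone.utc).isoformat()}</td></tr>",
        f"<tr><th>Thresholds</th><td><code>{html.escape(cfg_desc)}</code></td></tr>",
        f"<tr><th>Calibration</th><td><code>{html.escape(calib_desc)}</code></td></tr>",
        "</table>",
        "<h2>Per-sample calls</h2>",
        "<p>Machine flags guide review; results are 'consistent with' or "
        "'flag for review', never a diagnosis.</p>",
        _call_table_html(batch, interps_by_id),
    ]
    if kind == QC_REPORT:
        parts.append("<h2>Run QC findings</h2><ul class='findings'>")
        if findings:
            parts += [f"<li>{html.escape(f)}</li>" for f in findings]
        else:
            parts.append("<li>all run QC metrics within range</li>")
        parts.append("</ul>")
    parts.append("<h2>Charts</h2><div class='charts'>")
    for spec in charts:
        parts.append(_chart_svg(spec))
    parts.append("</div></body></html>")

    with open(html_path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))

    with PdfPages(out) as pdf:
        fig = plt.figure(figsize=(8.3, 11.7))
        fig.text(0.08, 0.95,
                 "NIPT report" if kind == NIPT_REPORT else "NIPT QC report",
                 fontsize=16, weight="bold")
        lines = [
            f"Run: {batch.run_id}   Date: {batch.run_date.isoformat()}",
            f"Source: {batch.source_filename}   Samples: {len(batch.samples)}",
            f"Exported by: {user or 'unknown'}",
        ]
        if kind == QC_REPORT:
            lines.append("Run QC findings:")
            lines += [f"  - {f}" for f in findings] or ["  - none"]
        y = 0.91
        for line in lines:
            fig.text(0.08, y, line, fontsize=9)
            y -= 0.02
        col_labels = ["Sample", "FF%"] + [f"NCV{c}" for c in NCV_CHROMS] + [
            "13", "18", "21", "Sex", "QC"]
        cell_rows = []
        for s in batch.samples:
            itp = interps_by_id[s.sample_id]
            cell_rows.append(
                [s.sample_id, f"{s.ff * 100:.1f}"]
                + [f"{s.ncv[c]:.2f}" for c in NCV_CHROMS]
                + [itp.autosome_calls[c][:6] for c in AUTOSOME_TARGETS]
                + [itp.sex_assessment[:8], itp.qc_status]
            )
        ax = fig.add_axes([0.05, 0.08, 0.9, max(0.2, y - 0.15)])
        ax.axis("off")
        table = ax.table(cellText=cell_rows, colLabels=col_labels, loc="upper center")
        table.auto_set_font_size(False)
        table.set_fontsize(6)
        pdf.savefig(fig)
        plt.close(fig)
        for spec in charts:
            fig, ax = plt.subplots(figsize=(8.3, 5.5))
            _render_chart(spec, ax)
            pdf.savefig(fig)
            plt.close(fig)

    if store is not None and user:
        store.record_export(user, batch.run_id)
    return out
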