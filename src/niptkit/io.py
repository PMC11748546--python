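"""Read/write the canonical per-run result CSV dialect.

The vendor's exact column set is proprietary, so the package defines its
own canonical dialect (documented in ``docs/run_csv_format.md``):

* filename ``YYMMDD_<runid>.csv``; the run date is parsed from the first
  six characters of the stem,
* optional leading ``#``-comment lines carrying run-level QC metrics
  (``# q30_pct=96.2``, ``# cluster_density_k_mm2=182``,
  ``# library_conc_nM=21.5;33.0;...``),
* a header row ``SampleID,Barcode,SampleType,NCV_13,NCV_18,NCV_21,NCV_X,
  NCV_Y,FF,NCD_A,NCD_B,Cov_chr1..Cov_chrY`` (NCD columns are discovered
  by scanning for the ``NCD_`` prefix, so the denominator-group set is
  extensible),
* one row per sample, at most 16; FF is percent in the file and a
  fraction in memory,
* unknown extra columns are preserved per sample in ``vendor_qc`` and
  written back verbatim.
"""

from __future__ import annotations

import datetime as _dt
import io as _stdio
import math
import os
import re

import pandas as pd

from .errors import (
    CellValueError,
    DuplicateSampleError,
    EmptyRunError,
    MalformedFilenameError,
    SchemaError,
)
from .models import (
    ALL_CHROMS,
    NCV_CHROMS,
    RUN_CAPACITY,
    SAMPLE_TYPES,
    RunBatch,
    SampleRecord,
)

FIXED_COLUMNS = ["SampleID", "Barcode", "SampleType"]
NCV_COLUMNS = [f"NCV_{c}" for c in NCV_CHROMS]
FF_COLUMN = "FF"
COV_COLUMNS = [f"Cov_chr{c}" for c in ALL_CHROMS]
DEFAULT_NCD_COLUMNS = ["NCD_A", "NCD_B"]

#: Canonical header order used by the writer.
CANONICAL_HEADER = (
    FIXED_COLUMNS + NCV_COLUMNS + [FF_COLUMN] + DEFAULT_NCD_COLUMNS + COV_COLUMNS
)

_RUN_QC_SCALARS = ("q30_pct", "cluster_density_k_mm2")

_YYMMDD_RE = re.compile(r"^(\d{6})")


def parse_run_date(filename: str) -> _dt.date:
    """Parse the YYMMDD prefix of a run filename into a date.

    The two-digit year uses a century pivot: 00-79 -> 20YY, 80-99 -> 19YY
    (the assay era is post-2020).  Raises :class:`MalformedFilenameError`
    for a missing prefix or an impossible calendar date.
    """
    stem = os.path.basename(str(filename))
    m = _YYMMDD_RE.match(stem)
    if not m:
        raise MalformedFilenameError(
            f"filename {stem!r} must begin with a YYMMDD date"
        )
    yy, mm, dd = (int(m.group(1)[i : i + 2]) for i in (0, 2, 4))
    year = 2000 + yy if yy < 80 else 1900 + yy
    try:
        return _dt.date(year, mm, dd)
    except ValueError as exc:
        raise MalformedFilenameError(
            f"filename {stem!r}: invalid calendar date {m.group(1)!r} ({exc})"
        ) from exc


def _parse_float_cell(raw, row_label: str, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise CellValueError(
            f"row {row_label!r}, column {column!r}: "
            f"cannot parse {raw!r} as a number"
        ) from None
    if isinstance(raw, float) and math.isnan(raw):
        raise CellValueError(
            f"row {row_label!r}, column {column!r}: missing value"
        )
    return value


def _split_header_comments(text: str) -> tuple[dict, str]:
    """Split leading ``#`` comment lines (run QC) from the CSV body."""
    run_qc: dict = {}
    body_lines: list[str] = []
    in_header = True
    for line in text.splitlines():
        if in_header and line.startswith("#"):
            payload = line.lstrip("#").strip()
            if "=" not in payload:
                continue
            key, _, raw = payload.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key in _RUN_QC_SCALARS:
                run_qc[key] = _parse_float_cell(raw, "header", key)
            elif key == "library_conc_nM":
                if raw:
                    run_qc[key] = [
                        _parse_float_cell(v, "header", key)
                        for v in raw.split(";")
                    ]
            else:
                run_qc[key] = raw
        else:
            in_header = False
            body_lines.append(line)
    return run_qc, "\n".join(body_lines)


def parse_run_csv(path) -> RunBatch:
    """Parse a canonical run CSV into a validated :class:`RunBatch`.

    Raises typed errors rather than returning partial data:
    :class:`MalformedFilenameError`, :class:`SchemaError` (missing
    required column or >16 rows), :class:`CellValueError` (non-numeric
    cell, naming row and column), :class:`DuplicateSampleError`,
    :class:`EmptyRunError`.
    """
    path = os.fspath(path)
    run_date = parse_run_date(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()

    run_qc, body = _split_header_comments(text)
    if not body.strip():
        raise EmptyRunError(f"{path}: file has no header row")
    try:
        frame = pd.read_csv(
            _stdio.StringIO(body), dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise EmptyRunError(f"{path}: file has no header row") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: unparseable CSV body ({exc})") from exc

    columns = list(frame.columns)
    ncd_columns = [c for c in columns if c.startswith("NCD_")]
    required = FIXED_COLUMNS + NCV_COLUMNS + [FF_COLUMN] + COV_COLUMNS
    for col in required:
        if col not in columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if not ncd_columns:
        raise SchemaError(f"{path}: missing required column 'NCD_*'")

    if len(frame) == 0:
        raise EmptyRunError(f"{path}: run has 0 sample rows")
    if len(frame) > RUN_CAPACITY:
        raise SchemaError(
            f"{path}: {len(frame)} sample rows exceed the "
            f"{RUN_CAPACITY}-sample run capacity"
        )

    known = set(required) | set(ncd_columns)
    extra_columns = [c for c in columns if c not in known]

    samples: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sample_id = str(row["SampleID"]).strip()
        if not sample_id:
            raise CellValueError(f"{path}: empty SampleID cell")
        if sample_id in seen:
            raise DuplicateSampleError(
                f"{path}: duplicate sample_id {sample_id!r}"
            )
        seen.add(sample_id)
        sample_type = str(row["SampleType"]).strip().lower()
        if sample_type not in SAMPLE_TYPES:
            raise CellValueError(
                f"row {sample_id!r}, column 'SampleType': "
                f"{row['SampleType']!r} not in {SAMPLE_TYPES}"
            )
        ncv = {
            c: _parse_float_cell(row[f"NCV_{c}"], sample_id, f"NCV_{c}")
            for c in NCV_CHROMS
        }
        ff_pct = _parse_float_cell(row[FF_COLUMN], sample_id, FF_COLUMN)
        ncd = {
            col[len("NCD_"):]: _parse_float_cell(row[col], sample_id, col)
            for col in ncd_columns
        }
        coverage = {
            c: _parse_float_cell(row[f"Cov_chr{c}"], sample_id, f"Cov_chr{c}")
            for c in ALL_CHROMS
        }
        vendor_qc = {c: str(row[c]) for c in extra_columns}
        samples.append(
            SampleRecord(
                sample_id=sample_id,
                barcode=str(row["Barcode"]),
                sample_type=sample_type,
                ncv=ncv,
                ncd=ncd,
                ff=ff_pct / 100.0,
                coverage=coverage,
                vendor_qc=vendor_qc,
            )
        )

    stem = os.path.splitext(os.path.basename(path))[0]
    batch = RunBatch(
        run_id=stem,
        run_date=run_date,
        samples=samples,
        run_qc=run_qc,
        source_filename=os.path.basename(path),
    )
    batch.validate()
    return batch


def _fmt(value: float) -> str:
    return repr(float(value))


def write_run_csv(batch: RunBatch, path) -> str:
    """Write a :class:`RunBatch` as a canonical run CSV; returns the path.

    The written file re-parses to a batch equal to the input (FF within
    1e-9; all other floats exactly, via ``repr`` round-tripping).
    """
    batch.validate()
    path = os.fspath(path)

    ncd_labels = sorted({label for s in batch.samples for label in s.ncd})
    extra_cols: list[str] = []
    for s in batch.samples:
        for key in s.vendor_qc:
            if key not in extra_cols:
                extra_cols.append(key)

    header = (
        FIXED_COLUMNS
        + NCV_COLUMNS
        + [FF_COLUMN]
        + [f"NCD_{label}" for label in ncd_labels]
        + COV_COLUMNS
        + extra_cols
    )

    lines: list[str] = []
    for key in _RUN_QC_SCALARS:
        if key in batch.run_qc:
            lines.append(f"# {key}={_fmt(batch.run_qc[key])}")
    if "library_conc_nM" in batch.run_qc:
        joined = ";".join(_fmt(v) for v in batch.run_qc["library_conc_nM"])
        lines.append(f"# library_conc_nM={joined}")
    lines.append(",".join(header))
    for s in batch.samples:
        row = [s.sample_id, s.barcode, s.sample_type]
        row += [_fmt(s.ncv[c]) for c in NCV_CHROMS]
        # FF is percent in the file; %.12g keeps "2.3" readable while the
        # fraction round-trips well within the 1e-9 contract.
        row.append(f"{s.ff * 100.0:.12g}")
        row += [_fmt(s.ncd[label]) for label in ncd_labels]
        row += [_fmt(s.coverage[c]) for c in ALL_CHROMS]
        row += [s.vendor_qc.get(key, "") for key in extra_cols]
        lines.append(",".join(row))

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def _sample_close(a: SampleRecord, b: SampleRecord, ff_tol: float) -> bool:
    return (
        a.sample_id == b.sample_id
        and a.barcode == b.barcode
        and a.sample_type == b.sample_type
        and a.ncv == b.ncv
        and a.ncd == b.ncd
        and abs(a.ff - b.ff) <= ff_tol
        and a.coverage == b.coverage
        and a.vendor_qc == b.vendor_qc
    )


def batches_equal(a: RunBatch, b: RunBatch, ff_tol: float = 1e-9) -> bool:
    """Field-by-field equality of two batches, FF within ``ff_tol``."""
    return (
        a.run_date == b.run_date
        and a.run_qc == b.run_qc
        and len(a.samples) == len(b.samples)
        and all(
            _sample_close(x, y, ff_tol) for x, y in zip(a.samples, b.samples)
        )
    )
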