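"""Persistent, audited storage of imported runs and their interpretations.

Backed by a single-file embedded SQLite database behind a small storage
contract (``Store``), so a server database could be swapped in later.
Every state-changing operation records exactly one append-only
:class:`AuditEntry` tagged with the acting user; SQL triggers make the
audit table immutable at the database level.
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
from dataclasses import dataclass

from .errors import DuplicateRunError, NiptError
from .interpret import Interpretation, Highlight
from .models import HistoricalSet, RunBatch, SampleRecord

AUDIT_ACTIONS = ("import", "calibrate", "interpret", "report_export")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id TEXT PRIMARY KEY,
    source_filename TEXT NOT NULL UNIQUE,
    run_date TEXT NOT NULL,
    run_qc TEXT NOT NULL,
    imported_by TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS samples (
    run_id TEXT NOT NULL REFERENCES runs(run_id),
    position INTEGER NOT NULL,
    sample_id TEXT NOT NULL,
    payload TEXT NOT NULL,
    PRIMARY KEY (run_id, sample_id)
);
CREATE TABLE IF NOT EXISTS interpretations (
    run_id TEXT NOT NULL REFERENCES runs(run_id),
    sample_id TEXT NOT NULL,
    payload TEXT NOT NULL,
    PRIMARY KEY (run_id, sample_id)
);
CREATE TABLE IF NOT EXISTS audit (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    user TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    action TEXT NOT NULL,
    run_id TEXT NOT NULL DEFAULT ''
);
CREATE TRIGGER IF NOT EXISTS audit_immutable_update
    BEFORE UPDATE ON audit
    BEGIN SELECT RAISE(ABORT, 'audit entries are immutable'); END;
CREATE TRIGGER IF NOT EXISTS audit_immutable_delete
    BEFORE DELETE ON audit
    BEGIN SELECT RAISE(ABORT, 'audit entries are immutable'); END;
"""


@dataclass(frozen=True)
class AuditEntry:
    """One immutable audit record."""

    user: str
    timestamp: _dt.datetime
    action: str
    run_id: str = ""


def _sample_to_json(rec: SampleRecord) -> str:
    return json.dumps(
        {
            "sample_id": rec.sample_id,
            "barcode": rec.barcode,
            "sample_type": rec.sample_type,
            "ncv": rec.ncv,
            "ncd": rec.ncd,
            "ff": rec.ff,
            "coverage": rec.coverage,
            "vendor_qc": rec.vendor_qc,
        }
    )


def _sample_from_json(payload: str) -> SampleRecord:
    return SampleRecord(**json.loads(payload))


def _interp_to_json(itp: Interpretation) -> str:
    return json.dumps(
        {
            "sample_id": itp.sample_id,
            "autosome_calls": itp.autosome_calls,
            "sex_assessment": itp.sex_assessment,
            "qc_status": itp.qc_status,
            "highlights": [
                [h.field, h.value, h.rule] for h in itp.highlights
            ],
            "run_qc_findings": itp.run_qc_findings,
        }
    )


def _interp_from_json(payload: str) -> Interpretation:
    d = json.loads(payload)
    d["highlights"] = [Highlight(*h) for h in d["highlights"]]
    return Interpretation(**d)


class Store:
    """Embedded run store; usable as a context manager."""

    def __init__(self, path):
        self._path = str(path)
        self._conn = sqlite3.connect(self._path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- audit ---------------------------------------------------------

    def _record(self, user: str, action: str, run_id: str = "") -> None:
        if not user:
            raise NiptError("a non-empty user is required for this operation")
        if action not in AUDIT_ACTIONS:
            raise NiptError(f"unknown audit action {action!r}")
        now = _dt.datetime.now(_dt.timezone.utc)
        row = self._conn.execute(
            "SELECT MAX(timestamp) FROM audit"
        ).fetchone()
        if row[0] is not None:
            prev = _dt.datetime.fromisoformat(row[0])
            if now < prev:  # clock skew guard: keep timestamps monotone
                now = prev
        self._conn.execute(
            "INSERT INTO audit (user, timestamp, action, run_id) "
            "VALUES (?, ?, ?, ?)",
            (user, now.isoformat(), action, run_id),
        )

    def audit_log(self) -> list[AuditEntry]:
        """Complete append-only audit trail in chronological order."""
        rows = self._conn.execute(
            "SELECT user, timestamp, action, run_id FROM audit ORDER BY seq"
        ).fetchall()
        return [
            AuditEntry(u, _dt.datetime.fromisoformat(ts), action, rid)
            for u, ts, action, rid in rows
        ]

    # -- runs ----------------------------------------------------------

    def import_run(self, batch: RunBatch, user: str) -> str:
        """Persist a run atomically; one 'import' audit entry; run_id back."""
        batch.validate()
        exists = self._conn.execute(
            "SELECT run_id FROM runs WHERE source_filename = ?",
            (batch.source_filename,),
        ).fetchone()
        if exists:
            raise DuplicateRunError(
                f"a run imported from {batch.source_filename!r} already "
                f"exists (run_id={exists[0]!r}); refusing to overwrite"
            )
        try:
            self._conn.execute(
                "INSERT INTO runs (run_id, source_filename, run_date, "
                "run_qc, imported_by) VALUES (?, ?, ?, ?, ?)",
                (
                    batch.run_id,
                    batch.source_filename,
                    batch.run_date.isoformat(),
                    json.dumps(batch.run_qc),
                    user,
                ),
            )
            self._conn.executemany(
                "INSERT INTO samples (run_id, position, sample_id, payload) "
                "VALUES (?, ?, ?, ?)",
                [
                    (batch.run_id, i, rec.sample_id, _sample_to_json(rec))
                    for i, rec in enumerate(batch.samples)
                ],
            )
            self._record(user, "import", batch.run_id)
        except sqlite3.IntegrityError as exc:
            self._conn.rollback()
            raise DuplicateRunError(str(exc)) from exc
        except Exception:
            self._conn.rollback()
            raise
        self._conn.commit()
        return batch.run_id

    def get_run(self, run_id: str) -> RunBatch:
        row = self._conn.execute(
            "SELECT run_id, source_filename, run_date, run_qc FROM runs "
            "WHERE run_id = ?",
            (run_id,),
        ).fetchone()
        if row is None:
            raise NiptError(f"no run with id {run_id!r}")
        samples = [
            _sample_from_json(payload)
            for (payload,) in self._conn.execute(
                "SELECT payload FROM samples WHERE run_id = ? ORDER BY position",
                (run_id,),
            )
        ]
        return RunBatch(
            run_id=row[0],
            source_filename=row[1],
            run_date=_dt.date.fromisoformat(row[2]),
            run_qc=json.loads(row[3]),
            samples=samples,
        )

    def list_runs(self) -> list[tuple[str, _dt.date, int]]:
        """(run_id, run_date, n_samples) for all stored runs, by date."""
        rows = self._conn.execute(
            "SELECT r.run_id, r.run_date, COUNT(s.sample_id) "
            "FROM runs r LEFT JOIN samples s ON s.run_id = r.run_id "
            "GROUP BY r.run_id ORDER BY r.run_date, r.run_id"
        ).fetchall()
        return [(rid, _dt.date.fromisoformat(d), n) for rid, d, n in rows]

    # -- history -------------------------------------------------------

    def get_history(
        self, exclude_run: str | None = None, euploid_only: bool = False
    ) -> HistoricalSet:
        """Historical samples, never including ``exclude_run``.

        With ``euploid_only``, only samples whose stored interpretation
        is normal on all of 13/18/21 are returned; uninterpreted samples
        are excluded.
        """
        rows = self._conn.execute(
            "SELECT s.run_id, r.run_date, s.payload, i.payload "
            "FROM samples s JOIN runs r ON r.run_id = s.run_id "
            "LEFT JOIN interpretations i "
            "ON i.run_id = s.run_id AND i.sample_id = s.sample_id "
            "ORDER BY r.run_date, s.run_id, s.position"
        ).fetchall()
        out = []
        for run_id, run_date, sample_json, interp_json in rows:
            if exclude_run is not None and run_id == exclude_run:
                continue
            if euploid_only:
                if interp_json is None:
                    continue
                if not _interp_from_json(interp_json).is_euploid_normal():
                    continue
            out.append(
                (
                    _sample_from_json(sample_json),
                    run_id,
                    _dt.date.fromisoformat(run_date),
                )
            )
        desc = f"exclude_run={exclude_run!r}, euploid_only={euploid_only}"
        return HistoricalSet(samples=tuple(out), filter_spec=desc)

    # -- interpretations ----------------------------------------------

    def save_interpretations(
        self, run_id: str, interps: list[Interpretation], user: str
    ) -> None:
        """Store (or replace) interpretations; one 'interpret' audit entry."""
        self.get_run(run_id)  # existence check
        try:
            self._conn.executemany(
                "INSERT OR REPLACE INTO interpretations "
                "(run_id, sample_id, payload) VALUES (?, ?, ?)",
                [
                    (run_id, itp.sample_id, _interp_to_json(itp))
                    for itp in interps
                ],
            )
            self._record(user, "interpret", run_id)
        except Exception:
            self._conn.rollback()
            raise
        self._conn.commit()

    def get_interpretations(self, run_id: str) -> list[Interpretation]:
        return [
            _interp_from_json(payload)
            for (payload,) in self._conn.execute(
                "SELECT payload FROM interpretations WHERE run_id = ? "
                "ORDER BY sample_id",
                (run_id,),
            )
        ]

    # -- other audited events -----------------------------------------

    def record_calibration(self, user: str, note: str = "") -> None:
        self._record(user, "calibrate", note)
        self._conn.commit()

    def record_export(self, user: str, run_id: str) -> None:
        self._record(user, "report_export", run_id)
        self._conn.commit()
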