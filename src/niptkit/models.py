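"""Domain types shared across the package.

A :class:`SampleRecord` carries one sample's normalized chromosome values
(NCV, Z-score-like), normalized chromosomal denominator values (NCD),
fetal fraction (stored as a fraction in [0, 1], serialized as percent),
a 24-chromosome normalized coverage profile, and pass-through vendor QC
fields.  A :class:`RunBatch` is one sequencing run of 1-16 samples whose
date is encoded in the first six characters of the source filename.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .errors import DuplicateSampleError, EmptyRunError

#: All chromosomes carried in the per-sample coverage profile, in karyotype order.
ALL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Chromosomes for which the assay reports an NCV.
NCV_CHROMS: tuple[str, ...] = ("13", "18", "21", "X", "Y")

#: Allowed sample type labels.
SAMPLE_TYPES: tuple[str, ...] = ("singleton", "control", "unknown")

#: Maximum number of samples per sequencing run.
RUN_CAPACITY: int = 16


@dataclass
class SampleRecord:
    """One sample's assay metrics.

    Parameters
    ----------
    sample_id : str
        Unique within its run.
    barcode : str
        Library barcode label.
    sample_type : str
        One of ``singleton``, ``control``, ``unknown``.
    ncv : dict
        Chromosome -> NCV for exactly {13, 18, 21, X, Y}.
    ncd : dict
        Denominator-group label -> NCD value; non-empty.
    ff : float
        Fetal fraction as a fraction in [0, 1].
    coverage : dict
        Chromosome -> normalized coverage for all 24 chromosomes;
        autosome-mean-scaled so the euploid expectation is 1.0.
    vendor_qc : dict
        Free-form pass-through fields (kept as strings).
    """

    sample_id: str
    barcode: str
    sample_type: str
    ncv: dict[str, float]
    ncd: dict[str, float]
    ff: float
    coverage: dict[str, float]
    vendor_qc: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type {self.sample_type!r} not in {SAMPLE_TYPES}"
            )
        if set(self.ncv) != set(NCV_CHROMS):
            raise ValueError(
                f"ncv must have entries for exactly {set(NCV_CHROMS)}, "
                f"got {set(self.ncv)}"
            )
        if not self.ncd:
            raise ValueError("ncd must be non-empty")
        if set(self.coverage) != set(ALL_CHROMS):
            raise ValueError("coverage must have exactly 24 chromosome entries")
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError(f"ff must be in [0, 1], got {self.ff}")
        for chrom, cov in self.coverage.items():
            if cov < 0:
                raise ValueError(f"coverage[{chrom}] must be >= 0, got {cov}")


@dataclass
class RunBatch:
    """One sequencing run: date, 1-16 samples, optional run-level QC.

    ``run_qc`` may hold ``q30_pct`` (float), ``cluster_density_k_mm2``
    (float) and ``library_conc_nM`` (list of float); all optional.
    """

    run_id: str
    run_date: _dt.date
    samples: list[SampleRecord]
    run_qc: dict = field(default_factory=dict)
    source_filename: str = ""

    def validate(self) -> None:
        if len(self.samples) == 0:
            raise EmptyRunError(f"run {self.run_id!r} has no samples")
        if len(self.samples) > RUN_CAPACITY:
            raise ValueError(
                f"run {self.run_id!r} has {len(self.samples)} samples, "
                f"capacity is {RUN_CAPACITY}"
            )
        seen: set[str] = set()
        for rec in self.samples:
            rec.validate()
            if rec.sample_id in seen:
                raise DuplicateSampleError(
                    f"duplicate sample_id {rec.sample_id!r} in run {self.run_id!r}"
                )
            seen.add(rec.sample_id)
        if self.source_filename:
            from .io import parse_run_date  # local import avoids a cycle

            if parse_run_date(self.source_filename) != self.run_date:
                raise ValueError(
                    "run_date does not match the YYMMDD prefix of "
                    f"{self.source_filename!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


@dataclass(frozen=True)
class HistoricalSet:
    """Historical samples served by the store for plotting/QC/calibration.

    ``samples`` is a list of ``(SampleRecord, run_id, run_date)`` tuples;
    ``filter_spec`` describes the inclusion rules that produced it.
    """

    samples: tuple
    filter_spec: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.samples)

    def records(self) -> list[SampleRecord]:
        return [s for s, _rid, _rd in self.samples]


EMPTY_HISTORY = HistoricalSet(samples=(), filter_spec="empty")
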