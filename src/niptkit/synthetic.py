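"""Synthetic cohort generator with known truth labels.

Generates statistically realistic run CSVs so the full pipeline can be
exercised — including a replay of the 84-sample clinical-verification
design (47 normal, 5 T13, 13 T18, 16 T21, 3 SCA over six runs, with at
most three samples of the same trisomy per run) — without any real data.

Generative model (NCVs are Z-score-like, so the euploid reference is
standard normal):

* euploid chromosome: ``NCV_c ~ Normal(0, 1)``;
* trisomy of chromosome c: ``NCV_c ~ Normal((ff/2) / cv[c], 1)`` — a
  fetal trisomy adds half an extra chromosome dose weighted by fetal
  fraction, divided by the assay's relative SD for that chromosome;
* XY fetus: ``NCV_X ~ Normal(-(ff/2)/cv[X], 1)`` and
  ``NCV_Y ~ Normal(mu_Y(ff), 1)`` with
  ``mu_Y(ff) = (ff/2)/cv[X] * |slope_true|`` (default slope -1.5), so
  male points trace the line ``NCV_Y = slope_true * NCV_X``;
* XX fetus: both ``NCV_X`` and ``NCV_Y ~ Normal(0, 1)`` at the female
  baseline (the Y scale is female-referenced by convention);
* X0: X as XY, Y as XX;  XXX: X positive-shifted, Y female;
  XXY: X female, Y male-level;  XYY: Y at twice the male level, X as XY.

Coverage for the affected chromosome is scaled by its fetal dosage
factor (1 + ff/2 for a gain, 1 - ff/2 for the X loss in X0); all other
chromosomes draw from Normal(1, 0.01).  NCDs draw from Normal(0, 1).

Note the separation this implies: the NCV > 4 call rule is meaningful at
FF >= 2% only because the per-chromosome cv values are small (defaults
0.004-0.006); at FF 2-4% trisomic means sit near the inconclusive band,
deliberately exercising the gray zone.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleDesignError
from .io import write_run_csv
from .models import ALL_CHROMS, NCV_CHROMS, RUN_CAPACITY, RunBatch, SampleRecord

TRISOMY_CLASSES = ("T13", "T18", "T21")
SCA_CLASSES = ("X0", "XXX", "XXY", "XYY")
EUPLOID_CLASSES = ("euploid_xx", "euploid_xy")
KARYOTYPE_CLASSES = EUPLOID_CLASSES + TRISOMY_CLASSES + SCA_CLASSES

DEFAULT_CV = {"13": 0.006, "18": 0.005, "21": 0.004, "X": 0.004}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort; fully reproducible from ``seed``."""

    n_normal: int = 0
    n_t13: int = 0
    n_t18: int = 0
    n_t21: int = 0
    n_sca: int = 0
    sca_subtypes: tuple[str, ...] = SCA_CLASSES
    n_runs: int = 1
    max_same_trisomy_per_run: int = 3
    ff_range_euploid: tuple[float, float] = (0.02, 0.23)
    ff_range_aneuploid: tuple[float, float] = (0.02, 0.23)
    cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CV))
    slope_true: float = -1.5
    prob_male: float = 0.5
    seed: int = 0
    start_date: _dt.date = _dt.date(2020, 11, 2)

    def validate(self) -> None:
        counts = (self.n_normal, self.n_t13, self.n_t18, self.n_t21, self.n_sca)
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be >= 0")
        if self.max_same_trisomy_per_run < 1:
            raise ValueError("max_same_trisomy_per_run must be >= 1")
        for lo, hi in (self.ff_range_euploid, self.ff_range_aneuploid):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("ff ranges must lie within [0, 1]")
        if any(sub not in SCA_CLASSES for sub in self.sca_subtypes):
            raise ValueError(f"sca_subtypes must come from {SCA_CLASSES}")

    @property
    def total(self) -> int:
        return self.n_normal + self.n_t13 + self.n_t18 + self.n_t21 + self.n_sca


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one generated sample."""

    sample_id: str
    karyotype_class: str
    ff_true: float


def verification_spec(seed: int = 20201101, margin_safe_ff: bool = True) -> CohortSpec:
    """The 84-sample clinical-verification design.

    47 normal, 5 T13, 13 T18, 16 T21 and 3 SCA samples over six runs
    with at most three same-trisomy samples per run.  With
    ``margin_safe_ff`` the aneuploid fetal fractions draw from
    [0.08, 0.23] so every trisomic mean clears the call threshold by a
    wide margin; euploid FF spans the full observed 2-23% range.
    """
    return CohortSpec(
        n_normal=47,
        n_t13=5,
        n_t18=13,
        n_t21=16,
        n_sca=3,
        sca_subtypes=("X0", "XXX", "XXY"),
        n_runs=6,
        max_same_trisomy_per_run=3,
        ff_range_euploid=(0.02, 0.23),
        ff_range_aneuploid=(0.08, 0.23) if margin_safe_ff else (0.02, 0.23),
        seed=seed,
    )


def _assign_runs(spec: CohortSpec, classes: list[str]) -> list[int]:
    """Greedy run assignment honoring capacity and the trisomy cap."""
    n_runs = spec.n_runs
    run_sizes = [0] * n_runs
    trisomy_counts = {c: [0] * n_runs for c in TRISOMY_CLASSES}
    assignment: list[int] = []
    # place trisomies first (most constrained), then the rest
    order = sorted(
        range(len(classes)),
        key=lambda i: (classes[i] not in TRISOMY_CLASSES, i),
    )
    result = [-1] * len(classes)
    for i in order:
        cls = classes[i]
        candidates = [
            r
            for r in range(n_runs)
            if run_sizes[r] < RUN_CAPACITY
            and (
                cls not in TRISOMY_CLASSES
                or trisomy_counts[cls][r] < spec.max_same_trisomy_per_run
            )
        ]
        if not candidates:
            raise InfeasibleDesignError(
                f"cannot place a {cls} sample: run capacity "
                f"({RUN_CAPACITY}/run x {n_runs}) or the "
                f"{spec.max_same_trisomy_per_run}-same-trisomy cap is exhausted"
            )
        r = min(candidates, key=lambda r: (run_sizes[r], r))
        run_sizes[r] += 1
        if cls in TRISOMY_CLASSES:
            trisomy_counts[cls][r] += 1
        result[i] = r
    assignment = result
    return assignment


def _draw_sample(
    rng: np.random.Generator,
    cls: str,
    ff: float,
    spec: CohortSpec,
    sample_id: str,
    barcode: str,
) -> SampleRecord:
    cv = spec.cv
    half_dose = ff / 2.0
    mu_x_male = -half_dose / cv["X"]
    mu_y_male = (half_dose / cv["X"]) * abs(spec.slope_true)

    ncv = {c: rng.normal(0.0, 1.0) for c in NCV_CHROMS}
    cov_factor: dict[str, float] = {}

    if cls in TRISOMY_CLASSES:
        chrom = cls[1:]
        ncv[chrom] = rng.normal(half_dose / cv[chrom], 1.0)
        cov_factor[chrom] = 1.0 + half_dose
        male = rng.random() < spec.prob_male
        if male:
            ncv["X"] = rng.normal(mu_x_male, 1.0)
            ncv["Y"] = rng.normal(mu_y_male, 1.0)
    elif cls == "euploid_xy":
        ncv["X"] = rng.normal(mu_x_male, 1.0)
        ncv["Y"] = rng.normal(mu_y_male, 1.0)
    elif cls == "euploid_xx":
        pass  # both sex NCVs stay at the female baseline
    elif cls == "X0":
        ncv["X"] = rng.normal(mu_x_male, 1.0)  # X depleted as in XY
        cov_factor["X"] = 1.0 - half_dose
    elif cls == "XXX":
        ncv["X"] = rng.normal(half_dose / cv["X"], 1.0)
        cov_factor["X"] = 1.0 + half_dose
    elif cls == "XXY":
        ncv["Y"] = rng.normal(mu_y_male, 1.0)
        cov_factor["Y"] = 1.0 + half_dose
    elif cls == "XYY":
        ncv["X"] = rng.normal(mu_x_male, 1.0)
        ncv["Y"] = rng.normal(2.0 * mu_y_male, 1.0)
        cov_factor["Y"] = 1.0 + half_dose
    else:  # pragma: no cover - guarded by CohortSpec.validate
        raise ValueError(f"unknown karyotype class {cls!r}")

    coverage = {
        c: max(0.0, rng.normal(1.0, 0.01)) * cov_factor.get(c, 1.0)
        for c in ALL_CHROMS
    }
    ncd = {"A": rng.normal(0.0, 1.0), "B": rng.normal(0.0, 1.0)}
    return SampleRecord(
        sample_id=sample_id,
        barcode=barcode,
        sample_type="singleton",
        ncv=ncv,
        ncd=ncd,
        ff=ff,
        coverage=coverage,
        vendor_qc={},
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[RunBatch], list[TruthLabel]]:
    """Simulate a cohort; returns run batches and aligned truth labels.

    Samples are assigned to runs greedily (trisomies first) honoring the
    16-sample capacity and the same-trisomy-per-run cap; raises
    :class:`InfeasibleDesignError` when the design cannot be packed.
    Byte-identical output is guaranteed for a fixed spec + seed.
    """
    spec.validate()
    if spec.total == 0:
        return [], []
    if spec.total > RUN_CAPACITY * spec.n_runs:
        raise InfeasibleDesignError(
            f"{spec.total} samples exceed {spec.n_runs} runs x {RUN_CAPACITY}"
        )

    rng = np.random.default_rng(spec.seed)

    classes: list[str] = []
    classes += ["euploid"] * spec.n_normal  # sex drawn below
    classes += ["T13"] * spec.n_t13
    classes += ["T18"] * spec.n_t18
    classes += ["T21"] * spec.n_t21
    classes += [
        spec.sca_subtypes[i % len(spec.sca_subtypes)] for i in range(spec.n_sca)
    ]
    resolved = [
        ("euploid_xy" if rng.random() < spec.prob_male else "euploid_xx")
        if cls == "euploid"
        else cls
        for cls in classes
    ]

    assignment = _assign_runs(spec, resolved)

    batches: list[RunBatch] = []
    labels: list[TruthLabel] = []
    for run_idx in range(spec.n_runs):
        members = [i for i, r in enumerate(assignment) if r == run_idx]
        if not members:
            continue
        rng.shuffle(members)
        run_date = spec.start_date + _dt.timedelta(days=7 * run_idx)
        run_id = f"{run_date:%y%m%d}_synrun{run_idx + 1}"
        samples: list[SampleRecord] = []
        for pos, i in enumerate(members):
            cls = resolved[i]
            lo, hi = (
                spec.ff_range_euploid
                if cls in EUPLOID_CLASSES
                else spec.ff_range_aneuploid
            )
            ff = float(rng.uniform(lo, hi))
            sample_id = f"SYN{spec.seed % 100000:05d}-{i + 1:04d}"
            rec = _draw_sample(rng, cls, ff, spec, sample_id, f"BC{pos + 1:02d}")
            samples.append(rec)
            labels.append(TruthLabel(sample_id, cls, ff))
        run_qc = {
            "q30_pct": float(rng.uniform(95.5, 98.5)),
            "cluster_density_k_mm2": float(rng.uniform(160.0, 230.0)),
            "library_conc_nM": [
                float(rng.uniform(20.0, 200.0)) for _ in samples
            ],
        }
        batch = RunBatch(
            run_id=run_id,
            run_date=run_date,
            samples=samples,
            run_qc=run_qc,
            source_filename=f"{run_id}.csv",
        )
        batch.validate()
        batches.append(batch)

    labels.sort(key=lambda t: t.sample_id)
    return batches, labels


def write_cohort(batches: list[RunBatch], out_dir) -> list[str]:
    """Write one canonical CSV per run; filenames sort chronologically."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for batch in batches:
        path = os.path.join(out_dir, batch.source_filename)
        write_run_csv(batch, path)
        paths.append(path)
    return paths


def write_truth(labels: list[TruthLabel], path) -> str:
    """Write truth labels as a CSV (sample_id, karyotype_class, ff_true)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,karyotype_class,ff_true\n")
        for lab in labels:
            fh.write(f"{lab.sample_id},{lab.karyotype_class},{lab.ff_true!r}\n")
    return str(path)
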