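import datetime as dt

import numpy as np
import pytest

from niptkit.calibration import SexCalibration, ThresholdConfig
from niptkit.models import ALL_CHROMS, NCV_CHROMS, RunBatch, SampleRecord


def make_sample(
    sample_id="S1",
    ncv=None,
    ncd=None,
    ff=0.05,
    coverage=None,
    sample_type="singleton",
    barcode="BC01",
    vendor_qc=None,
):
    """A valid euploid-ish SampleRecord with overridable fields."""
    base_ncv = {c: 0.0 for c in NCV_CHROMS}
    if ncv:
        base_ncv.update(ncv)
    base_cov = {c: 1.0 for c in ALL_CHROMS}
    if coverage:
        base_cov.update(coverage)
    return SampleRecord(
        sample_id=sample_id,
        barcode=barcode,
        sample_type=sample_type,
        ncv=base_ncv,
        ncd=dict(ncd or {"A": 0.1, "B": -0.2}),
        ff=ff,
        coverage=base_cov,
        vendor_qc=dict(vendor_qc or {}),
    )


def make_batch(n=3, run_id="210115_runA", run_date=dt.date(2021, 1, 15),
               run_qc=None, prefix="S"):
    samples = [make_sample(sample_id=f"{prefix}{i + 1}") for i in range(n)]
    return RunBatch(
        run_id=run_id,
        run_date=run_date,
        samples=samples,
        run_qc=dict(run_qc or {}),
        source_filename=f"{run_id}.csv",
    )


@pytest.fixture
def cfg():
    return ThresholdConfig()


@pytest.fixture
def calib():
    """A hand-set calibration: line y = -1.5x, residual SD 1."""
    return SexCalibration(
        slope=-1.5,
        intercept=0.0,
        resid_sd=1.0,
        n_fit=40,
        female_x_mean=0.0,
        female_x_sd=1.0,
        fitted_on=["210115_runA"],
    )


def calibration_samples(rng=None, n_male=40, n_female=40, slope=-1.5,
                        intercept=0.0, noise_sd=1.0):
    """Simulated calibration cloud: males on the line, females at 0."""
    rng = rng or np.random.default_rng(7)
    samples = []
    x = rng.uniform(-25.0, -5.0, size=n_male)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n_male)
    for i in range(n_male):
        samples.append(
            make_sample(f"M{i}", ncv={"X": float(x[i]), "Y": float(y[i])})
        )
    fx = rng.normal(0.0, 1.0, size=n_female)
    fy = rng.normal(0.0, 1.0, size=n_female)
    for i in range(n_female):
        samples.append(
            make_sample(f"F{i}", ncv={"X": float(fx[i]), "Y": float(fy[i])})
        )
    return samples
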