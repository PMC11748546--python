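"""Decision constants and the sex-chromosome regression fit.

All decision thresholds live in one serializable :class:`ThresholdConfig`
whose defaults are the clinically verified values: flag a trisomy at
NCV > 4 when fetal fraction is >= 2%, inconclusive on the closed span
[3, 4]; run QC requires Q30 > 95%, cluster density 140-250 K/mm2 and
library concentrations 10-250 nM.

The sex assessment relies on a regression of NCV(Y) on NCV(X) fitted on
presumed-male samples (NCV_Y >= ``male_ncvY_min``), with a constant-width
confidence band of +/- ``band_sd_mult`` (default 3) residual standard
deviations around the line.  Presumed-female samples are summarized as an
NCV_X cluster (mean/SD).  The fit sigma-clips gross outliers (e.g. sex
chromosome aneuploidies present in the calibration set) before the final
pass, so calibration does not require prior karyotype knowledge.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFitWarning, InsufficientCalibrationDataError
from .models import SampleRecord

_RESID_SD_FLOOR = 1e-6


@dataclass
class ThresholdConfig:
    """All decision constants, serializable to a human-readable JSON file."""

    ncv_call: float = 4.0
    ncv_gray_low: float = 3.0
    ff_min: float = 0.02
    band_sd_mult: float = 3.0
    ncd_limit: float = 4.0
    coverage_z_limit: float = 3.0
    q30_min_pct: float = 95.0
    cluster_density_range_k_mm2: tuple[float, float] = (140.0, 250.0)
    library_conc_range_nM: tuple[float, float] = (10.0, 250.0)
    male_ncvY_min: float = 4.0

    def validate(self) -> None:
        if not self.ncv_gray_low < self.ncv_call:
            raise ValueError("ncv_gray_low must be < ncv_call")
        if not 0.0 < self.ff_min < 1.0:
            raise ValueError("ff_min must be a fraction in (0, 1)")
        if self.band_sd_mult < 0:
            raise ValueError("band_sd_mult must be >= 0")
        for name in ("cluster_density_range_k_mm2", "library_conc_range_nM"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be (low, high) with low < high")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_density_range_k_mm2"] = list(self.cluster_density_range_k_mm2)
        d["library_conc_range_nM"] = list(self.library_conc_range_nM)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        kwargs = dict(d)
        for name in ("cluster_density_range_k_mm2", "library_conc_range_nM"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class SexCalibration:
    """Fitted NCV(X) -> NCV(Y) line plus the female NCV_X cluster summary."""

    slope: float
    intercept: float
    resid_sd: float
    n_fit: int
    female_x_mean: float
    female_x_sd: float
    fitted_on: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_fit < 3:
            raise ValueError("n_fit must be >= 3")
        if not (np.isfinite(self.resid_sd) and self.resid_sd > 0):
            raise ValueError("resid_sd must be finite and > 0")
        if not (np.isfinite(self.female_x_sd) and self.female_x_sd > 0):
            raise ValueError("female_x_sd must be finite and > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SexCalibration":
        calib = cls(**d)
        calib.validate()
        return calib


def _floored_sd(values: np.ndarray, what: str) -> float:
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    if sd < _RESID_SD_FLOOR:
        warnings.warn(
            f"{what} collapsed to ~0; flooring at {_RESID_SD_FLOOR}",
            DegenerateFitWarning,
            stacklevel=3,
        )
        sd = _RESID_SD_FLOOR
    return sd


def fit_sex_regression(
    samples: list[SampleRecord],
    cfg: ThresholdConfig,
    fitted_on: list[str] | None = None,
    trim_sd: float = 4.0,
    max_trim_iter: int = 5,
) -> SexCalibration:
    """Fit the male NCV_Y-on-NCV_X line and the female NCV_X cluster.

    Samples are split by ``ncv[Y] >= cfg.male_ncvY_min`` into presumed
    males and presumed females; both subsets need >= 3 members or
    :class:`InsufficientCalibrationDataError` names the short one.  The
    male line is ordinary least squares; ``resid_sd`` is the sample SD of
    male residuals.  Points more than ``trim_sd`` residual SDs off the
    line (or, for females, off the cluster mean) are iteratively dropped
    so gross outliers do not distort the calibration; the subset actually
    kept still must satisfy the minimum of 3.
    """
    cfg.validate()
    males = [s for s in samples if s.ncv["Y"] >= cfg.male_ncvY_min]
    females = [s for s in samples if s.ncv["Y"] < cfg.male_ncvY_min]
    if len(males) < 3:
        raise InsufficientCalibrationDataError(
            f"need >= 3 presumed-male samples (NCV_Y >= {cfg.male_ncvY_min}), "
            f"got {len(males)}"
        )
    if len(females) < 3:
        raise InsufficientCalibrationDataError(
            f"need >= 3 presumed-female samples (NCV_Y < {cfg.male_ncvY_min}), "
            f"got {len(females)}"
        )

    mx = np.array([s.ncv["X"] for s in males], dtype=float)
    my = np.array([s.ncv["Y"] for s in males], dtype=float)
    keep = np.ones(len(mx), dtype=bool)
    slope = intercept = 0.0
    for _ in range(max_trim_iter):
        slope, intercept = np.polyfit(mx[keep], my[keep], 1)
        resid = my - (slope * mx + intercept)
        sd = float(np.std(resid[keep], ddof=1))
        if sd < _RESID_SD_FLOOR:
            break
        new_keep = np.abs(resid) <= trim_sd * sd
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    resid = my[keep] - (slope * mx[keep] + intercept)
    resid_sd = _floored_sd(resid, "male residual SD")

    fx = np.array([s.ncv["X"] for s in females], dtype=float)
    fkeep = np.ones(len(fx), dtype=bool)
    for _ in range(max_trim_iter):
        mean = float(np.mean(fx[fkeep]))
        sd = float(np.std(fx[fkeep], ddof=1))
        if sd < _RESID_SD_FLOOR:
            break
        new_keep = np.abs(fx - mean) <= trim_sd * sd
        if new_keep.sum() < 3 or np.array_equal(new_keep, fkeep):
            break
        fkeep = new_keep
    female_x_mean = float(np.mean(fx[fkeep]))
    female_x_sd = _floored_sd(fx[fkeep], "female NCV_X SD")

    calib = SexCalibration(
        slope=float(slope),
        intercept=float(intercept),
        resid_sd=resid_sd,
        n_fit=int(keep.sum()),
        female_x_mean=female_x_mean,
        female_x_sd=female_x_sd,
        fitted_on=list(fitted_on or []),
    )
    calib.validate()
    return calib


def band_bounds(
    calib: SexCalibration, cfg: ThresholdConfig, ncv_x: float
) -> tuple[float, float]:
    """Confidence band around the fitted line at ``ncv_x``.

    Center is ``slope * ncv_x + intercept``; half-width is
    ``cfg.band_sd_mult * calib.resid_sd`` (constant everywhere).
    """
    center = calib.slope * ncv_x + calib.intercept
    half = cfg.band_sd_mult * calib.resid_sd
    return (center - half, center + half)


def save_config(
    cfg: ThresholdConfig, path, calib: SexCalibration | None = None
) -> str:
    """Write thresholds (and optionally a calibration) to a JSON file."""
    cfg.validate()
    payload = {
        "thresholds": cfg.to_dict(),
        "sex_calibration": calib.to_dict() if calib is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return str(path)


def load_config(path) -> tuple[ThresholdConfig, SexCalibration | None]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = ThresholdConfig.from_dict(payload["thresholds"])
    calib_d = payload.get("sex_calibration")
    calib = SexCalibration.from_dict(calib_d) if calib_d else None
    return cfg, calib
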