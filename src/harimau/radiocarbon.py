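"""Radiocarbon calibration with highest-density calendar ranges.

A conventional radiocarbon determination ``m ± s`` (in ¹⁴C yr BP) is
calibrated against a calibration curve ``(mu(t), sigma(t))`` mapping
calendar age ``t`` (cal BP, present = AD 1950) to expected ¹⁴C age. The
posterior over the calendar grid is proportional to

    L(t) = exp(-(m - mu(t))^2 / (2 (s^2 + sigma(t)^2))) / sqrt(s^2 + sigma(t)^2)

and the 95.4% highest-posterior-density region is reported as one or more
calendar intervals, oldest first, in the conventional (older, younger)
orientation.

Curve files follow the standard IntCal ``.14c`` layout: comment lines
starting with ``#``, then comma- (or whitespace-) separated columns
``CAL BP, 14C age, error, ...``. The genuine IntCal13 curve is an optional
external input; synthetic curves cover the test suite.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ValidationError

DEFAULT_MASS = 0.954


@dataclass
class CalibrationCurve:
    """Calibration curve interpolated to a 1-year calendar grid."""

    cal_bp: np.ndarray     # ascending, 1-year steps
    c14_age: np.ndarray
    error: np.ndarray
    name: str = "curve"

    def __post_init__(self):
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValidationError("calendar grid must be strictly increasing")
        if np.any(self.error <= 0):
            raise ValidationError("curve errors must be positive")

    @classmethod
    def from_grid(cls, cal_bp, c14_age, error, name="curve") -> "CalibrationCurve":
        """Interpolate arbitrary (monotonic) knots to a 1-year grid."""
        cal_bp = np.asarray(cal_bp, dtype=float)
        order = np.argsort(cal_bp)
        cal_bp = cal_bp[order]
        if np.any(np.diff(cal_bp) <= 0):
            raise ValidationError("calendar grid must be strictly monotonic")
        grid = np.arange(np.ceil(cal_bp[0]), np.floor(cal_bp[-1]) + 1)
        mu = np.interp(grid, cal_bp, np.asarray(c14_age, dtype=float)[order])
        sd = np.interp(grid, cal_bp, np.asarray(error, dtype=float)[order])
        return cls(cal_bp=grid, c14_age=mu, error=sd, name=name)


def load_curve(path) -> CalibrationCurve:
    """Read an IntCal-style ``.14c`` file and interpolate to 1-year steps."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValidationError(f"malformed curve line: {line!r}")
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if len(rows) < 2:
        raise ValidationError("curve file has fewer than 2 data rows")
    arr = np.array(rows)
    return CalibrationCurve.from_grid(arr[:, 0], arr[:, 1], arr[:, 2],
                                      name=os.path.basename(str(path)))


@dataclass(frozen=True)
class RadiocarbonDetermination:
    age: float      # measured 14C age, BP
    sigma: float
    label: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("measurement sigma must be positive")


@dataclass
class CalibratedResult:
    cal_bp: np.ndarray
    density: np.ndarray    # sums to 1
    determination: RadiocarbonDetermination

    def hpd(self, mass: float = DEFAULT_MASS) -> list[tuple[int, int]]:
        return hpd_range(self, mass=mass)


def calibrate(det: RadiocarbonDetermination,
              curve: CalibrationCurve) -> CalibratedResult:
    """Posterior density of calendar age on the curve's 1-year grid."""
    lo = det.age - 10 * det.sigma
    hi = det.age + 10 * det.sigma
    if hi < curve.c14_age.min() or lo > curve.c14_age.max():
        raise ValidationError(
            f"determination {det.age}±{det.sigma} BP lies outside the curve's "
            f"¹⁴C range [{curve.c14_age.min():.0f}, {curve.c14_age.max():.0f}]")
    var = det.sigma ** 2 + curve.error ** 2
    dens = np.exp(-0.5 * (det.age - curve.c14_age) ** 2 / var) / np.sqrt(var)
    total = dens.sum()
    if total <= 0:
        raise ValidationError("zero posterior mass on the calendar grid")
    return CalibratedResult(cal_bp=curve.cal_bp, density=dens / total,
                            determination=det)


def hpd_range(result: CalibratedResult, mass: float = DEFAULT_MASS,
              ) -> list[tuple[int, int]]:
    """Highest-density calendar intervals holding at least ``mass``.

    Grid cells are accumulated in order of decreasing density until the
    target mass is reached, then merged into maximal contiguous runs;
    intervals are returned oldest-first as (older, younger) cal BP.
    """
    order = np.argsort(result.density)[::-1]
    csum = np.cumsum(result.density[order])
    n_in = int(np.searchsorted(csum, mass) + 1)
    chosen = np.sort(order[:n_in])
    intervals = []
    start = prev = chosen[0]
    for i in chosen[1:]:
        if i == prev + 1:
            prev = i
        else:
            intervals.append((start, prev))
            start = prev = i
    intervals.append((start, prev))
    out = [(int(round(result.cal_bp[b])), int(round(result.cal_bp[a])))
           for a, b in intervals]
    return sorted(out, key=lambda t: -t[0])


def calibrate_table(dates: pd.DataFrame, curve: CalibrationCurve,
                    mass: float = DEFAULT_MASS) -> pd.DataFrame:
    """Calibrate a table with columns (label, age, sigma); returns a summary
    with the outer envelope of the HPD region per determination."""
    rows = []
    for _, r in dates.iterrows():
        det = RadiocarbonDetermination(age=float(r["age"]), sigma=float(r["sigma"]),
                                       label=str(r.get("label", "")))
        res = calibrate(det, curve)
        iv = hpd_range(res, mass=mass)
        rows.append({"label": det.label, "c14_age_bp": det.age, "sigma": det.sigma,
                     "cal_bp_older": iv[0][0], "cal_bp_younger": iv[-1][1],
                     "n_intervals": len(iv),
                     "intervals": "; ".join(f"{a}–{b}" for a, b in iv)})
    return pd.DataFrame(rows)
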