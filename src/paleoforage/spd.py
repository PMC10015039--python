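"""Radiocarbon calibration and summed probability distributions (SPDs).

A calibrated date density is obtained by scanning candidate calendar years
theta and scoring the measured radiocarbon age against the calibration
curve: density(theta) is proportional to
Normal(c14_age; mu_curve(theta), sqrt(error^2 + sigma_curve(theta)^2)) on
a 1-year grid, normalized to unit mass.  To damp over-representation of
intensively dated sites, same-site dates are binned by complete-linkage
clustering of their uncalibrated ages cut at 200 years; each bin
contributes the mean of its members' calibrated densities (total mass 1
per bin).  The SPD is the sum over bins, truncated to the study window
(22.0-9.1 kya by default) and optionally smoothed with a 200-year
centered local mean whose window shrinks at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ExtentError, InsufficientDataError, InvalidParameterError

__all__ = [
    "CalCurve",
    "CalibratedDensity",
    "SPDCurve",
    "calibrate",
    "bin_dates",
    "spd",
    "smooth",
    "spd_at",
    "STUDY_WINDOW",
]

#: default analysis window, calendar years BP (old, young)
STUDY_WINDOW = (22000.0, 9100.0)


@dataclass(frozen=True)
class CalCurve:
    """Calibration curve: calendar age -> radiocarbon age with 1-sigma error.

    Knots must be strictly ordered in calendar age; evaluation linearly
    interpolates between knots.
    """

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.cal_bp) > 0):
            raise InvalidParameterError("calibration curve calendar ages must be strictly increasing")
        if np.any(self.sigma < 0):
            raise InvalidParameterError("curve sigmas must be non-negative")

    @classmethod
    def from_intcal(cls, path) -> "CalCurve":
        """Read an IntCal-format table (calBP, 14C age, sigma in the first
        three columns; comma or whitespace separated, '#' comments)."""
        df = pd.read_csv(path, comment="#", sep=None, engine="python", header=None)
        df = df.apply(pd.to_numeric, errors="coerce").dropna(how="any", axis=0)
        df = df.sort_values(0)
        return cls(
            cal_bp=df[0].to_numpy(float),
            c14_bp=df[1].to_numpy(float),
            sigma=df[2].to_numpy(float),
        )

    def mu(self, theta):
        return np.interp(theta, self.cal_bp, self.c14_bp)

    def sig(self, theta):
        return np.interp(theta, self.cal_bp, self.sigma)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])


@dataclass(frozen=True)
class CalibratedDensity:
    """Per-calendar-year probability of one date; mass sums to 1."""

    ages: np.ndarray  # calendar years BP, ascending, step 1
    density: np.ndarray

    def median(self) -> float:
        cum = np.cumsum(self.density)
        return float(self.ages[np.searchsorted(cum, 0.5)])


def calibrate(c14_age: float, error: float, curve: CalCurve, trim: float = 1e-7) -> CalibratedDensity:
    """Calibrate one radiocarbon determination against ``curve``.

    Evaluates the likelihood of every calendar year in the curve's span
    (1-year grid, curve linearly interpolated), normalizes to unit mass
    and trims negligible tails.
    """
    if error <= 0:
        raise InvalidParameterError("radiocarbon error must be positive")
    lo, hi = curve.span
    theta = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    mu = curve.mu(theta)
    sd = np.sqrt(error**2 + curve.sig(theta) ** 2)
    z = (c14_age - mu) / sd
    # unnormalized normal likelihood; log-space for stability
    logd = -0.5 * z**2 - np.log(sd)
    logd -= logd.max()
    d = np.exp(logd)
    total = d.sum()
    if not np.isfinite(total) or total <= 0:
        raise ExtentError("date has no support on the calibration curve")
    d /= total
    keep = np.nonzero(d > trim * d.max())[0]
    i0, i1 = keep[0], keep[-1]
    if i0 == 0 or i1 == len(theta) - 1:
        # support touches the curve edge: date effectively outside coverage
        if d[[0, -1]].max() > 1e-4:
            raise ExtentError("calibrated density truncated by curve coverage")
    d = d[i0 : i1 + 1]
    return CalibratedDensity(ages=theta[i0 : i1 + 1], density=d / d.sum())


def bin_dates(dates: pd.DataFrame, bin_width: float = 200.0) -> list[pd.DataFrame]:
    """Group same-site dates into bins no wider than ``bin_width`` years.

    Within each site, uncalibrated ages are clustered by complete-linkage
    agglomeration cut at ``bin_width`` (the standard SPD binning rule);
    bins never span sites. ``dates`` needs columns ``site_id`` and
    ``c14_age``. Returns one DataFrame per bin, in deterministic
    (site, mean age) order.
    """
    bins: list[pd.DataFrame] = []
    for site, grp in dates.groupby("site_id", sort=True):
        ages = grp["c14_age"].to_numpy(float)
        if len(grp) == 1:
            bins.append(grp)
            continue
        link = hierarchy.linkage(pdist(ages[:, None]), method="complete")
        labels = hierarchy.fcluster(link, t=bin_width, criterion="distance")
        for lab in np.unique(labels):
            bins.append(grp.iloc[np.nonzero(labels == lab)[0]])
    bins.sort(key=lambda b: (str(b["site_id"].iloc[0]), float(b["c14_age"].mean())))
    return bins


@dataclass(frozen=True)
class SPDCurve:
    """Summed probability per calendar year over the analysis window."""

    ages: np.ndarray  # ascending calendar years BP
    values: np.ndarray
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.ages, "spd": self.values})

    def per_century(self) -> pd.DataFrame:
        """Aggregate yearly mass to century totals keyed by the century
        (half-up rounded) each year belongs to."""
        cent = (np.floor(self.ages / 100.0 + 0.5) * 100).astype(int)
        df = pd.DataFrame({"century": cent, "mass": self.values})
        return df.groupby("century", as_index=False)["mass"].sum()


def spd(
    bins: list[pd.DataFrame],
    curve: CalCurve,
    window: tuple[float, float] = STUDY_WINDOW,
    error_col: str = "error",
) -> SPDCurve:
    """Summed probability distribution over ``window`` (old, young) BP.

    Every bin contributes the mean of its member dates' calibrated
    densities, so each bin carries total mass 1 before truncation; the
    SPD is the straight sum over bins restricted to the window grid.
    """
    if not bins:
        raise InsufficientDataError("no bins to sum")
    old, young = max(window), min(window)
    ages = np.arange(young, old + 1.0)
    total = np.zeros_like(ages)
    n_used = 0
    for b in bins:
        dens = np.zeros_like(ages)
        for row in b.itertuples(index=False):
            cal = calibrate(row.c14_age, getattr(row, error_col), curve)
            dens += np.interp(ages, cal.ages, cal.density, left=0.0, right=0.0)
        dens /= len(b)
        if dens.sum() > 0:
            n_used += 1
        total += dens
    if total.sum() == 0:
        raise InsufficientDataError("SPD empty after truncation to the window")
    return SPDCurve(ages=ages, values=total, n_bins=n_used)


def smooth(curve: SPDCurve, window: float = 200.0) -> SPDCurve:
    """Centered local-mean smoother of total width ``window`` years.

    On a yearly grid a 200-year window spans 201 grid points (+-100 y).
    Edges shrink the window to the available points rather than padding,
    so no mass is invented.
    """
    step = float(np.median(np.diff(curve.ages)))
    if not np.isclose(round(window / step) * step, window):
        raise InvalidParameterError("grid step must divide the smoother window")
    half = int(round(window / step / 2))
    ser = pd.Series(curve.values)
    sm = ser.rolling(window=2 * half + 1, center=True, min_periods=1).mean().to_numpy()
    return SPDCurve(ages=curve.ages, values=sm, n_bins=curve.n_bins)


def spd_at(curve: SPDCurve, age) -> float | np.ndarray:
    """SPD value at arbitrary calendar age(s), linearly interpolated."""
    age = np.asarray(age, dtype=float)
    if np.any(age < curve.ages[0] - 0.5) or np.any(age > curve.ages[-1] + 0.5):
        raise ExtentError("age outside the SPD window")
    out = np.interp(age, curve.ages, curve.values)
    return float(out) if out.ndim == 0 else out


def truncate_dates_by_median(
    dates: pd.DataFrame,
    curve: CalCurve,
    window: tuple[float, float] = STUDY_WINDOW,
    error_col: str = "error",
) -> pd.DataFrame:
    """Keep dates whose median calibrated age falls inside ``window``.

    Applied before binning, mirroring the truncation of the source
    database to the study period. Adds a ``median_cal_bp`` column.
    """
    old, young = max(window), min(window)
    med = np.array(
        [calibrate(r.c14_age, getattr(r, error_col), curve).median() for r in dates.itertuples(index=False)]
    )
    out = dates.copy()
    out["median_cal_bp"] = med
    return out[(med >= young) & (med <= old)].reset_index(drop=True)
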