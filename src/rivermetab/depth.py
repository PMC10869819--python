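"""Continuous river depth, cross-sectional area and velocity from episodic
channel field measurements.

Two depth estimators are supported per site: a linear stage rating fitted to
field-measured depth (cross-sectional area / wetted width) against gage
height, and hydraulic geometry (h = c * Q**f).  Cross-sectional area gets its
own stage rating, which combined with daily discharge yields the
cross-section averaged velocity used for metabolism reach-length screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FieldMeasurement",
    "RatingCurve",
    "HydraulicCoeffs",
    "InsufficientDataError",
    "depth_from_measurement",
    "fit_rating",
    "predict_series",
    "depth_hydraulic",
    "velocity_series",
]

QUALITY_RATINGS = ("excellent", "good", "fair", "poor")
SECONDS_PER_DAY = 86400.0


class InsufficientDataError(ValueError):
    """Raised when too few usable field measurements remain to fit a rating."""


@dataclass
class FieldMeasurement:
    """One discrete USGS-style channel measurement."""

    date: object
    width: float          # wetted width, m
    area: float           # cross-sectional area, m2
    gage_height: float    # m
    discharge: float      # m3/s
    quality_rating: str = "good"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.area <= 0:
            raise ValueError("width and area must be positive")
        if self.quality_rating not in QUALITY_RATINGS:
            raise ValueError(f"quality rating must be one of {QUALITY_RATINGS}")


@dataclass
class RatingCurve:
    """Fitted linear stage relation: target = slope * GH + intercept."""

    target: str           # "depth" or "area"
    slope: float
    intercept: float
    n_points: int
    r_squared: float
    excluded_poor: bool


@dataclass
class HydraulicCoeffs:
    """Hydraulic-geometry coefficients: width B = a*Q**b, depth h = c*Q**f."""

    a: float
    b_width: float
    c: float
    f: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("depth coefficient c must be positive")


def depth_from_measurement(area: float, width: float) -> float:
    """Cross-section averaged depth: measured flow area over wetted width."""
    if np.any(np.asarray(width) <= 0):
        raise ValueError("wetted width must be positive")
    return area / width


def fit_rating(
    measurements: list[FieldMeasurement],
    target: str = "depth",
    exclude_poor: bool = True,
) -> RatingCurve:
    """Ordinary least squares of depth (or area) on gage height.

    Measurements rated "poor" are excluded when ``exclude_poor`` is true; if
    that leaves fewer than two points the fit falls back to using all
    measurements with a warning (sites where most measurements are poor are
    still usable this way).
    """
    if target not in ("depth", "area"):
        raise ValueError("target must be 'depth' or 'area'")
    usable = [m for m in measurements if not (exclude_poor and m.quality_rating == "poor")]
    used_exclusion = exclude_poor
    if len(usable) < 2 and exclude_poor:
        if len(measurements) >= 2:
            warnings.warn(
                "fewer than 2 non-poor measurements; falling back to all "
                "measurements including those rated poor",
                stacklevel=2,
            )
            usable = list(measurements)
            used_exclusion = False
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable field measurements to fit the {target} rating "
            f"(exclude_poor={exclude_poor}); got {len(usable)}"
        )
    gh = np.array([m.gage_height for m in usable], dtype=float)
    if target == "depth":
        y = np.array([depth_from_measurement(m.area, m.width) for m in usable])
    else:
        y = np.array([m.area for m in usable], dtype=float)
    if np.ptp(gh) == 0:
        raise InsufficientDataError("gage heights are all identical; rating undefined")
    res = stats.linregress(gh, y)
    return RatingCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(usable),
        r_squared=float(res.rvalue**2),
        excluded_poor=used_exclusion,
    )


def predict_series(curve: RatingCurve, gage_height) -> pd.Series:
    """Evaluate a stage rating elementwise; non-positive predictions -> NaN.

    A strongly negative intercept can imply a non-physical depth or area at
    low stage; such values are flagged missing rather than propagated.
    """
    gh = pd.Series(gage_height, dtype=float)
    pred = curve.slope * gh + curve.intercept
    bad = pred <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-physical (<= 0) {curve.target} predictions "
            "flagged missing",
            stacklevel=2,
        )
        pred[bad] = np.nan
    return pred


def depth_hydraulic(coeffs: HydraulicCoeffs, discharge) -> pd.Series:
    """Hydraulic-geometry depth h = c * Q**f; non-positive Q flagged missing."""
    q = pd.Series(discharge, dtype=float)
    out = pd.Series(np.nan, index=q.index)
    ok = q > 0
    out[ok] = coeffs.c * np.power(q[ok], coeffs.f)
    return out


def velocity_series(discharge_daily, area_curve: RatingCurve, gage_height_daily) -> pd.Series:
    """Daily cross-section averaged velocity in m/day.

    Daily average discharge divided by the rated cross-sectional area for
    that day's mean gage height, converted from m/s to m/day.
    """
    if area_curve.target != "area":
        raise ValueError("velocity needs an area rating curve")
    q = pd.Series(discharge_daily, dtype=float)
    area = predict_series(area_curve, gage_height_daily)
    area = area.reindex(q.index)
    v = (q / area) * SECONDS_PER_DAY
    v[q == 0] = 0.0
    return v
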