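"""Turn raw sensor time series into a gridded, unit-consistent, solar-time model input.

The metabolism model wants a single table on a constant 15-minute grid in mean
solar time, with dissolved oxygen (mg/L), water temperature (degC), DO
saturation (mg/L), depth (m), light (PPFD, umol m-2 s-1) and discharge
(m3/s).  Raw USGS/NOAA-style series arrive in mixed units on irregular
stamps; this module regrids them, fills short gaps by linear interpolation,
converts units, derives salinity from specific conductance, and computes the
astronomical quantities (solar time, clear-sky light, oxygen solubility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawSeries",
    "regrid_and_fill",
    "salinity_from_conductance",
    "utc_to_solar",
    "do_saturation",
    "light_ppfd",
    "assemble_input",
]

#: canonical unit per parameter kind, and accepted source units with
#: multiplicative conversion factors to the canonical unit
_CANONICAL_UNITS = {
    "do": ("mg/L", {"mg/L": 1.0}),
    "temp": ("degC", {"degC": 1.0}),
    "spc": ("uS/cm", {"uS/cm": 1.0, "mS/cm": 1000.0}),
    "sal": ("PSU", {"PSU": 1.0}),
    "discharge": ("m3/s", {"m3/s": 1.0, "ft3/s": 0.3048**3}),
    "gage_height": ("m", {"m": 1.0, "ft": 0.3048}),
    "pressure": ("mb", {"mb": 1.0, "inHg": 33.8639, "kPa": 10.0}),
}


@dataclass
class RawSeries:
    """One raw parameter series: UTC timestamps, values, kind and source units.

    ``extra`` carries any non-schema columns found alongside the series on
    read (approval codes, qualifiers, ...); they are preserved, never
    silently dropped.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    kind: str
    units: str
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in _CANONICAL_UNITS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        canonical, accepted = _CANONICAL_UNITS[self.kind]
        if self.units not in accepted:
            raise ValueError(
                f"units {self.units!r} not valid for kind {self.kind!r}; "
                f"expected one of {sorted(accepted)}"
            )
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.timestamps.tz is None:
            self.timestamps = self.timestamps.tz_localize("UTC")
        else:
            self.timestamps = self.timestamps.tz_convert("UTC")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.timestamps):
            raise ValueError("timestamps and values differ in length")

    def to_canonical(self) -> pd.Series:
        """Series in canonical units, duplicates averaged, sorted ascending."""
        canonical, accepted = _CANONICAL_UNITS[self.kind]
        s = pd.Series(self.values * accepted[self.units], index=self.timestamps)
        if s.index.has_duplicates:
            warnings.warn(f"{self.kind}: duplicate timestamps averaged", stacklevel=2)
            s = s.groupby(level=0).mean()
        return s.sort_index()


def regrid_and_fill(
    raw: RawSeries, grid_minutes: int = 15, max_gap_hours: float = 3.0
) -> pd.Series:
    """Align a raw series to a constant grid and fill short interior gaps.

    Values are converted to canonical units, timestamps snapped to the nearest
    grid instant (duplicates averaged), and interior gaps strictly shorter
    than ``max_gap_hours`` filled by linear interpolation in time.  Longer
    gaps stay missing, and nothing is extrapolated beyond the first or last
    observation.
    """
    s = raw.to_canonical().dropna()
    if len(s) == 0:
        return pd.Series(dtype=float)
    if len(s) == 1:
        idx = s.index.round(f"{grid_minutes}min")
        return pd.Series(s.to_numpy(), index=idx)

    step = pd.Timedelta(minutes=grid_minutes)
    snapped = s.index.round(step)
    s = pd.Series(s.to_numpy(), index=snapped).groupby(level=0).mean().sort_index()

    grid = pd.date_range(s.index[0], s.index[-1], freq=step)
    out = s.reindex(grid)
    filled = out.interpolate(method="time", limit_area="inside")

    # knock filled values back to NaN inside gaps >= max_gap_hours
    max_gap = pd.Timedelta(hours=max_gap_hours)
    obs_times = s.index
    gaps = obs_times[1:] - obs_times[:-1]
    for start, gap in zip(obs_times[:-1], gaps):
        if gap >= max_gap:
            inside = (grid > start) & (grid < start + gap)
            filled[inside] = np.nan
    return filled


# PSS-78 practical salinity polynomial coefficients (conductivity-ratio form)
_PSS_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_PSS_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_PSS_K = 0.0162
#: conductivity of standard seawater (S=35) at 25 degC, uS/cm
_C35_25 = 53087.0


def _pss78(rt: np.ndarray, t: float = 25.0) -> np.ndarray:
    sq = np.sqrt(rt)
    powers = [np.ones_like(rt), sq, rt, rt * sq, rt * rt, rt * rt * sq]
    s = sum(a * p for a, p in zip(_PSS_A, powers))
    ds = (t - 15.0) / (1.0 + _PSS_K * (t - 15.0)) * sum(
        b * p for b, p in zip(_PSS_B, powers)
    )
    return s + ds


def salinity_from_conductance(spc):
    """Practical salinity (PSU) from specific conductance (uS/cm at 25 degC).

    Uses the PSS-78 polynomial in the conductivity ratio relative to standard
    seawater at 25 degC, shifted so that zero conductance maps to exactly
    zero salinity (the unshifted polynomial has a small positive intercept
    outside its validity range).  Monotone non-decreasing in conductance.
    """
    spc_arr = np.asarray(spc, dtype=float)
    if np.any(spc_arr < 0):
        raise ValueError("specific conductance must be non-negative")
    rt = spc_arr / _C35_25
    sal = _pss78(rt) - _pss78(np.zeros_like(rt))
    sal = np.clip(sal, 0.0, None)
    return float(sal) if np.isscalar(spc) else sal


def utc_to_solar(t_utc, longitude: float):
    """Shift UTC timestamps to local mean solar time (24 h between solar noons)."""
    if not -180.0 <= longitude <= 180.0:
        raise ValueError("longitude must be in [-180, 180]")
    offset = pd.Timedelta(hours=longitude / 15.0)
    t = pd.DatetimeIndex(t_utc) if not isinstance(t_utc, pd.Timestamp) else t_utc
    if getattr(t, "tz", None) is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    return t + offset


# Garcia & Gordon (1992) refit of the Benson-Krause oxygen solubility data,
# mL/L form; result converted to mg/L.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7
_ML_PER_L_TO_MG_PER_L = 1.42905


def do_saturation(temp_c, pressure_mb=1013.25, salinity=0.0):
    """Equilibrium dissolved-oxygen concentration (mg/L).

    Garcia-Gordon solubility at the given temperature and salinity, scaled
    linearly by barometric pressure relative to one standard atmosphere.
    Valid for temperatures in [-1, 45] degC.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any((t < -1.0) | (t > 45.0)):
        raise ValueError("temperature out of range [-1, 45] degC")
    p = np.asarray(pressure_mb, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    s = np.asarray(salinity, dtype=float)

    ts = np.log((298.15 - t) / (273.15 + t))
    lnc = sum(a * ts**i for i, a in enumerate(_GG_A))
    lnc = lnc + s * sum(b * ts**i for i, b in enumerate(_GG_B)) + _GG_C0 * s * s
    sat = np.exp(lnc) * _ML_PER_L_TO_MG_PER_L * (p / 1013.25)
    return float(sat) if sat.ndim == 0 else sat


#: clear-sky PPFD at zero zenith angle, umol photons m-2 s-1
_PPFD_MAX = 2326.0


def _solar_geometry(solar_time: pd.DatetimeIndex, latitude: float):
    doy = solar_time.dayofyear.to_numpy()
    frac_hour = (
        solar_time.hour.to_numpy()
        + solar_time.minute.to_numpy() / 60.0
        + solar_time.second.to_numpy() / 3600.0
    )
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (doy + 10) / 365.25)
    hour_angle = np.deg2rad(15.0 * (frac_hour - 12.0))
    lat = np.deg2rad(latitude)
    cos_zenith = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(
        hour_angle
    )
    return cos_zenith


def light_ppfd(solar_time, latitude: float, longitude: float = 0.0):
    """Theoretical clear-sky photosynthetic photon flux density.

    Zero whenever the solar zenith angle is at or below the horizon, maximal
    at solar noon, symmetric about noon within a day.  Only the within-day
    *shape* matters for apportioning daily GPP (the model normalises light by
    its daily integral), so a fixed top-of-atmosphere scaling is used.
    ``solar_time`` must already be local mean solar time.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be in [-90, 90]")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError("longitude must be in [-180, 180]")
    idx = pd.DatetimeIndex(solar_time)
    cos_z = _solar_geometry(idx, latitude)
    return _PPFD_MAX * np.clip(cos_z, 0.0, None)


@dataclass
class ForcingSeries:
    """Gridded solar-time model input for one site.

    ``frame`` is indexed by solar time at a constant spacing with columns
    ``DO.obs, DO.sat, depth, temp.water, light, discharge, gage.height,
    salinity, pressure, usable``.
    """

    frame: pd.DataFrame
    latitude: float
    longitude: float
    timestep_minutes: int = 15
    meta: dict = field(default_factory=dict)

    REQUIRED = ("DO.obs", "temp.water", "depth")

    def __post_init__(self) -> None:
        idx = self.frame.index
        if len(idx) > 1:
            deltas = np.unique(np.diff(idx.view("int64")))
            if len(deltas) != 1:
                raise ValueError("forcing grid spacing is not constant")
            self.timestep_minutes = int(deltas[0] / 60e9)

    @property
    def solar_time(self) -> pd.DatetimeIndex:
        return self.frame.index

    def usable(self) -> pd.Series:
        return self.frame["usable"]


def assemble_input(
    components: dict,
    latitude: float,
    longitude: float,
    depth: pd.Series | None = None,
    timestep_minutes: int = 15,
) -> ForcingSeries:
    """Merge gridded component series into one solar-time model-input table.

    ``components`` maps kind -> gridded UTC series (output of
    :func:`regrid_and_fill`); accepted kinds are ``do, temp, sal, discharge,
    gage_height, pressure``.  ``depth`` is a gridded depth series (m) on the
    same UTC grid.  DO saturation and clear-sky light are computed here.
    Rows missing DO, temperature or depth are flagged unusable.
    """
    known = {"do", "temp", "sal", "discharge", "gage_height", "pressure"}
    unknown = set(components) - known
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    if "do" not in components or "temp" not in components:
        raise ValueError("DO and temperature components are required")

    pieces = {k: v for k, v in components.items() if len(v)}
    if depth is not None and len(depth):
        pieces["depth"] = depth
    frame = pd.DataFrame(pieces)
    if frame.empty:
        raise ValueError("component time spans are disjoint or empty")

    frame["salinity"] = frame.get("sal", pd.Series(0.0, index=frame.index)).fillna(0.0)
    frame["pressure"] = frame.get(
        "pressure", pd.Series(1013.25, index=frame.index)
    ).fillna(1013.25)

    solar = utc_to_solar(frame.index, longitude)
    with np.errstate(invalid="ignore"):
        tclip = np.clip(frame["temp"].to_numpy(), -1.0, 45.0)
    dosat = np.where(
        np.isnan(frame["temp"].to_numpy()),
        np.nan,
        do_saturation(tclip, frame["pressure"].to_numpy(), frame["salinity"].to_numpy()),
    )

    out = pd.DataFrame(
        {
            "DO.obs": frame.get("do"),
            "DO.sat": dosat,
            "depth": frame.get("depth"),
            "temp.water": frame.get("temp"),
            "light": light_ppfd(solar, latitude, longitude),
            "discharge": frame.get("discharge"),
            "gage.height": frame.get("gage_height"),
            "salinity": frame["salinity"],
            "pressure": frame["pressure"],
        }
    )
    out.index = solar
    out.index.name = "solar.time"
    usable = np.ones(len(out), dtype=bool)
    for col in ForcingSeries.REQUIRED:
        if col not in out or out[col].isna().all():
            if col == "depth":
                raise ValueError("depth series is required to assemble model input")
        usable &= out[col].notna().to_numpy()
    out["usable"] = usable
    return ForcingSeries(out, latitude=latitude, longitude=longitude,
                         timestep_minutes=timestep_minutes)
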