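"""Forward machinery of the one-station diel oxygen mass balance.

State variable is water-column dissolved oxygen O (mg/L) obeying

    dO/dt = P_t + R_t + D_t

with P_t the instantaneous volumetric photosynthesis rate (daily GPP spread
over the day proportionally to light), R_t respiration (daily ER spread
uniformly), and D_t = K2_t * (Osat_t - O_t) air-water gas exchange.  The gas
exchange constant is reported normalised to a Schmidt number of 600 (K600)
and converted to the oxygen- and temperature-specific K2 via the Schmidt
number polynomial.

All rates are per day; the integration step is the sensor interval
(15 minutes by default) expressed in days.  A "metabolic day" runs from
solar 04:00 to the next day's 04:00 so that a single night-day-night cycle
is attributed to one GPP/ER pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SCHMIDT_COEFFS",
    "schmidt_number",
    "k600_to_kgas",
    "apportion_sources",
    "forward_simulate",
    "daily_r2",
    "DayData",
    "split_metabolic_days",
    "DEFAULT_DAY_START_HOUR",
]

#: Schmidt-number polynomial coefficients for oxygen in fresh water,
#: Sc(T) = S_A + S_B*T + S_C*T^2 + S_D*T^3 with T in degC
SCHMIDT_COEFFS = (1568.0, -86.04, 2.142, -0.0216)

DEFAULT_DAY_START_HOUR = 4


def schmidt_number(temp_c):
    """Dimensionless Schmidt number of oxygen at water temperature T (degC)."""
    t = np.asarray(temp_c, dtype=float)
    if np.any((t < 0.0) | (t > 40.0)):
        raise ValueError("temperature out of range [0, 40] degC for Schmidt polynomial")
    a, b, c, d = SCHMIDT_COEFFS
    sc = a + b * t + c * t * t + d * t**3
    return float(sc) if sc.ndim == 0 else sc


def k600_to_kgas(k600, temp_c):
    """Convert K600 (d-1) to the oxygen-specific exchange constant K2 (d-1).

    K2 = K600 * (Sc(T)/600)**-0.5; at the temperature where Sc = 600 the two
    coincide.
    """
    k = np.asarray(k600, dtype=float)
    if np.any(k < 0):
        raise ValueError("K600 must be non-negative")
    out = k * (schmidt_number(temp_c) / 600.0) ** -0.5
    return float(out) if np.ndim(out) == 0 else out


def schmidt_factor(temp_c):
    """(Sc(T)/600)**-0.5 so that K2 = K600 * schmidt_factor(T)."""
    return (schmidt_number(temp_c) / 600.0) ** -0.5


def light_fractions(ppfd: np.ndarray) -> np.ndarray:
    """Fraction of the day's light falling in each interval (sums to 1)."""
    ppfd = np.asarray(ppfd, dtype=float)
    total = ppfd.sum()
    if total <= 0:
        raise ValueError("all-zero light over a day; GPP cannot be apportioned")
    return ppfd / total


def apportion_sources(gpp, er, depth, ppfd, timestep_minutes=15):
    """Instantaneous volumetric source rates P_t, R_t (mg O2 L-1 d-1).

    P_t carries the daily areal GPP (g O2 m-2 d-1) divided by depth and
    apportioned to intervals proportionally to instantaneous light, so that
    the time integral of P_t over the day equals GPP/depth.  R_t is constant
    within the day with integral ER/depth.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(np.asarray(depth) <= 0):
        raise ValueError("depth must be positive")
    if np.any(ppfd < 0):
        raise ValueError("light must be non-negative")
    dt = timestep_minutes / 1440.0
    if gpp != 0:
        frac = light_fractions(ppfd)
        p = (gpp / depth) * frac / dt
    else:
        p = np.zeros_like(ppfd)
    r = np.full_like(ppfd, er / depth, dtype=float)
    return p, r


@dataclass
class DayData:
    """Arrays for one complete metabolic day, ready for fitting.

    ``frac_rate`` is the light fraction per interval divided by the timestep
    in days, so P_t = GPP/h * frac_rate and dt * sum(frac_rate) == 1.
    """

    date: object
    index: pd.DatetimeIndex
    do_obs: np.ndarray
    do_sat: np.ndarray
    sc_fac: np.ndarray      # (Sc/600)^-0.5 per step
    frac_rate: np.ndarray   # light apportionment rate, d-1
    depth: float            # daily mean depth, m
    ln_q: float             # daily mean ln discharge
    dt_days: float
    temp: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.do_obs)


def split_metabolic_days(
    forcing, day_start_hour: int = DEFAULT_DAY_START_HOUR
) -> list[DayData]:
    """Slice a ForcingSeries into complete metabolic-day windows.

    A window covers [d day_start_hour, d+1 day_start_hour) in solar time and
    is kept only if every expected grid row is present and usable (DO,
    temperature, depth all observed).  Discharge, if absent, yields NaN lnQ
    (partial pooling then degenerates to a common mean).
    """
    frame = forcing.frame
    step = forcing.timestep_minutes
    per_day = 1440 // step
    dt_days = step / 1440.0

    shifted = frame.index - pd.Timedelta(hours=day_start_hour)
    day_label = shifted.floor("D")
    days: list[DayData] = []
    for label, sub in frame.groupby(day_label):
        if len(sub) != per_day or not sub["usable"].all():
            continue
        temp = sub["temp.water"].to_numpy()
        light = sub["light"].to_numpy()
        if light.sum() <= 0:
            continue
        q = sub["discharge"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            ln_q = float(np.log(np.nanmean(q))) if np.isfinite(q).any() else np.nan
        days.append(
            DayData(
                date=label.date(),
                index=sub.index,
                do_obs=sub["DO.obs"].to_numpy(),
                do_sat=sub["DO.sat"].to_numpy(),
                sc_fac=schmidt_factor(np.clip(temp, 0.0, 40.0)),
                frac_rate=light_fractions(light) / dt_days,
                depth=float(sub["depth"].mean()),
                ln_q=ln_q,
                dt_days=dt_days,
                temp=temp,
            )
        )
    return days


def forward_simulate(
    daily_params: pd.DataFrame,
    forcing,
    o2_init: float,
    sigma_proc: float = 0.0,
    seed=None,
    day_start_hour: int = DEFAULT_DAY_START_HOUR,
) -> pd.Series:
    """Explicit-Euler integration of the oxygen balance over complete days.

    ``daily_params`` is indexed by metabolic-day date with columns
    ``GPP, ER, K600``.  Process noise of standard deviation
    ``sigma_proc * sqrt(dt)`` (sigma_proc in mg L-1 d-1/2) is added to the
    state each step.  With ``sigma_proc=0`` the output is deterministic.
    The gas-exchange deficit is evaluated at the previous state.
    """
    days = split_metabolic_days(forcing, day_start_hour)
    days = [d for d in days if d.date in set(pd.to_datetime(daily_params.index).date)]
    if not days:
        raise ValueError("no complete metabolic days overlap the supplied parameters")
    rng = np.random.default_rng(seed)
    params = daily_params.copy()
    params.index = pd.to_datetime(params.index).date

    state = float(o2_init)
    out_idx, out_val = [], []
    for day in days:
        gpp = float(params.loc[day.date, "GPP"])
        er = float(params.loc[day.date, "ER"])
        k600 = float(params.loc[day.date, "K600"])
        k2 = k600 * day.sc_fac
        p = (gpp / day.depth) * day.frac_rate
        r = er / day.depth
        dt = day.dt_days
        noise = (
            rng.normal(0.0, sigma_proc * np.sqrt(dt), size=day.n_obs)
            if sigma_proc > 0
            else np.zeros(day.n_obs)
        )
        for i in range(day.n_obs):
            out_idx.append(day.index[i])
            out_val.append(state)
            dstate = dt * (p[i] + r + k2[i] * (day.do_sat[i] - state))
            state = state + dstate + noise[i]
        if not np.isfinite(state):
            raise FloatingPointError("oxygen state diverged (check K600 and timestep)")
    return pd.Series(out_val, index=pd.DatetimeIndex(out_idx), name="DO.mod")


def daily_r2(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Coefficient of determination of modeled vs observed DO within one day.

    1 - SS_res/SS_tot; may be negative when the model does worse than the
    day's mean.  NaN (missing) when fewer than 3 pairs or zero observation
    variance.
    """
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modeled, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(mod)
    if ok.sum() < 3:
        return float("nan")
    obs, mod = obs[ok], mod[ok]
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - np.sum((obs - mod) ** 2) / ss_tot)
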