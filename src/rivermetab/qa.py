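"""Quality assurance of daily metabolism estimates.

Four daily flags mark low signal-to-noise days and biologically or
physically unrealistic values; a five-criterion rubric rates overall
confidence in a site's record; censoring removes flagged days; summaries
aggregate sites and the whole basin.

Thresholds (all in g O2 m-2 d-1 or d-1):

* Flag 1 - a day's R2 of modeled vs observed DO below the site's 15th
  percentile, applied only when that percentile is itself negative.
* Flag 2 - GPP < -0.5 (metabolically impossible beyond error variation).
* Flag 3 - ER > +0.5.
* Flag 4 - K600 > 20 (implausibly fast gas exchange).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model.oxygen import k600_to_kgas

__all__ = [
    "FlagSet",
    "ConfidenceAssessment",
    "SiteSummary",
    "reach_length",
    "apply_flags",
    "censor",
    "assess_confidence",
    "site_summary",
    "basin_rollup",
    "FLAG2_GPP_MIN",
    "FLAG3_ER_MAX",
    "FLAG4_K600_MAX",
]

FLAG2_GPP_MIN = -0.5
FLAG3_ER_MAX = 0.5
FLAG4_K600_MAX = 20.0
R2DET_PERCENTILE = 15.0
TURNOVER_FACTOR = -math.log(1.0 - 0.8)  # 80% oxygen turnover, ~1.6094

RATINGS = ("HIGH", "MEDIUM", "LOW")


@dataclass
class FlagSet:
    date: object
    flag1_low_snr: bool
    flag2_gpp: bool
    flag3_er: bool
    flag4_k600: bool

    @property
    def any_flag(self) -> bool:
        return self.flag1_low_snr or self.flag2_gpp or self.flag3_er or self.flag4_k600


@dataclass
class ConfidenceAssessment:
    c1_gpp_rating: str
    c2_er_rating: str
    c3_k600_range_rating: str
    c4_convergence_rating: str
    c5_reach_rating: str
    overall: str
    notes: str = ""


@dataclass
class SiteSummary:
    site_id: str
    n_days: int
    n_days_unflagged: int
    pct_unflagged: float
    mean_discharge: float
    sd_discharge: float
    mean_gpp: float
    sd_gpp: float
    mean_er: float
    sd_er: float
    mean_nep: float
    sd_nep: float
    pct_autotrophic: float
    group: str = ""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reach_length(velocity_m_per_day, k_o2_per_day):
    """Metabolism reach length (m): -ln(1-0.8) * v / K_O2.

    The upstream distance over which 80% of water-column oxygen turns over
    by gas exchange; conditions farther upstream have little influence on
    the sensor.  ``k_o2_per_day`` must be positive; days with non-positive
    K_O2 yield NaN and are skipped by callers.
    """
    v = np.asarray(velocity_m_per_day, dtype=float)
    k = np.asarray(k_o2_per_day, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    out = np.where(k > 0, TURNOVER_FACTOR * v / np.where(k > 0, k, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def daily_reach_lengths(daily, velocity_daily: pd.Series, temp_daily: pd.Series) -> pd.Series:
    """Per-day reach length from daily K600, mean temperature and velocity."""
    dates = [d.date for d in daily]
    k600 = pd.Series([d.K600 for d in daily], index=dates)
    v = pd.Series(velocity_daily).reindex(dates)
    t = pd.Series(temp_daily).reindex(dates)
    k_o2 = k600_to_kgas(k600.to_numpy().clip(min=0.0), t.to_numpy())
    return pd.Series(reach_length(v.to_numpy(), k_o2), index=dates)


def apply_flags(daily) -> list[FlagSet]:
    """Daily QA flags for a site record (list of DailyMetabolism)."""
    if not daily:
        raise ValueError("empty daily record")
    r2 = np.array([d.r2_det for d in daily], dtype=float)
    finite = r2[np.isfinite(r2)]
    flag1_active = False
    threshold = np.nan
    if len(finite) > 0:
        threshold = np.percentile(finite, R2DET_PERCENTILE)
        flag1_active = threshold < 0
    out = []
    for d in daily:
        f1 = bool(
            flag1_active and np.isfinite(d.r2_det) and d.r2_det < threshold
        )
        out.append(
            FlagSet(
                date=d.date,
                flag1_low_snr=f1,
                flag2_gpp=bool(d.GPP < FLAG2_GPP_MIN),
                flag3_er=bool(d.ER > FLAG3_ER_MAX),
                flag4_k600=bool(d.K600 > FLAG4_K600_MAX),
            )
        )
    return out


def censor(daily, flags):
    """Days carrying no flag, in original order."""
    if len(daily) != len(flags):
        raise ValueError("daily record and flags are misaligned")
    return [d for d, f in zip(daily, flags) if not f.any_flag]


def _pct_rating(pct: float) -> str:
    if pct < 25.0:
        return "HIGH"
    if pct < 50.0:
        return "MEDIUM"
    return "LOW"


def _k600_range_rating(spread: float) -> str:
    if spread < 15.0:
        return "HIGH"
    if spread <= 50.0:   # the value exactly 50 sits in the MEDIUM bin
        return "MEDIUM"
    return "LOW"


def combine_ratings(ratings) -> str:
    """HIGH iff all HIGH; LOW iff any LOW; otherwise MEDIUM."""
    if any(r == "LOW" for r in ratings):
        return "LOW"
    if all(r == "HIGH" for r in ratings):
        return "HIGH"
    return "MEDIUM"


def assess_confidence(
    daily,
    flags,
    diag,
    reach_lengths=None,
    upstream_structure_distance_m: float | None = None,
) -> ConfidenceAssessment:
    """Five-criterion site confidence rating with the combination rule.

    c1/c2: percent of days with biologically unrealistic GPP (< -0.5) / ER
    (> +0.5); c3: 90th-10th percentile spread of daily K600; c4: R-hat of
    the process-error and K600-error scales both below 1.2 (HIGH/LOW only);
    c5: percent of days on which the nearest upstream flow-regulation
    structure lies beyond the metabolism reach length.
    """
    if not daily:
        raise ValueError("empty daily record")
    n = len(daily)
    pct_bad_gpp = 100.0 * sum(1 for d in daily if d.GPP < FLAG2_GPP_MIN) / n
    pct_bad_er = 100.0 * sum(1 for d in daily if d.ER > FLAG3_ER_MAX) / n
    c1 = _pct_rating(pct_bad_gpp)
    c2 = _pct_rating(pct_bad_er)

    k600 = np.array([d.K600 for d in daily], dtype=float)
    spread = float(np.percentile(k600, 90) - np.percentile(k600, 10))
    c3 = _k600_range_rating(spread)

    c4 = (
        "HIGH"
        if (diag.rhat_sigma_proc < 1.2 and diag.rhat_sigma_k600 < 1.2)
        else "LOW"
    )

    notes = ""
    if upstream_structure_distance_m is None or reach_lengths is None:
        c5 = "MISSING"
        notes = "upstream structure distance not configured; c5 missing, overall capped at MEDIUM"
        warnings.warn(notes, stacklevel=2)
        overall = combine_ratings([c1, c2, c3, c4])
        if overall == "HIGH":
            overall = "MEDIUM"
    else:
        rl = np.asarray(pd.Series(reach_lengths), dtype=float)
        rl = rl[np.isfinite(rl)]
        if len(rl) == 0:
            frac_beyond = 0.0
        else:
            frac_beyond = float(np.mean(upstream_structure_distance_m > rl))
        if frac_beyond > 0.8:
            c5 = "HIGH"
        elif frac_beyond > 0.5:
            c5 = "MEDIUM"
        else:
            c5 = "LOW"
        overall = combine_ratings([c1, c2, c3, c4, c5])
    return ConfidenceAssessment(c1, c2, c3, c4, c5, overall, notes)


def site_summary(daily, flags, discharge_daily=None, site_id: str = "", group: str = "") -> SiteSummary:
    """Means and spreads over unflagged days plus the autotrophy percentage.

    ``pct_autotrophic`` is the share of unflagged days with NEP > 0, rounded
    half-up to an integer percent.  An empty record after censoring yields a
    summary of missing values rather than an error.
    """
    if not daily:
        raise ValueError("empty daily record")
    kept = censor(daily, flags)
    n, n_kept = len(daily), len(kept)
    if discharge_daily is not None:
        q = pd.Series(discharge_daily, dtype=float)
        kept_dates = [d.date for d in kept]
        qk = q.reindex(kept_dates) if n_kept else q.iloc[:0]
        mean_q, sd_q = float(qk.mean()), float(qk.std())
    else:
        mean_q = sd_q = float("nan")
    if n_kept == 0:
        nanv = float("nan")
        return SiteSummary(site_id, n, 0, 0.0, mean_q, sd_q,
                           nanv, nanv, nanv, nanv, nanv, nanv, nanv, group)
    gpp = np.array([d.GPP for d in kept])
    er = np.array([d.ER for d in kept])
    nep = gpp + er
    return SiteSummary(
        site_id=site_id,
        n_days=n,
        n_days_unflagged=n_kept,
        pct_unflagged=100.0 * n_kept / n,
        mean_discharge=mean_q,
        sd_discharge=sd_q,
        mean_gpp=float(gpp.mean()),
        sd_gpp=float(gpp.std(ddof=1)) if n_kept > 1 else 0.0,
        mean_er=float(er.mean()),
        sd_er=float(er.std(ddof=1)) if n_kept > 1 else 0.0,
        mean_nep=float(nep.mean()),
        sd_nep=float(nep.std(ddof=1)) if n_kept > 1 else 0.0,
        pct_autotrophic=float(_round_half_up(100.0 * np.mean(nep > 0))),
        group=group,
    )


def basin_rollup(summaries: list[SiteSummary], confidences=None) -> dict:
    """Unweighted across-site aggregates of the per-site summaries.

    Returns basin means of GPP, ER and NEP, the mean percentage of flagged
    days, per-group mean autotrophy percentages (rounded half-up), and, when
    confidence assessments are supplied, the share of sites rated high or
    medium overall.
    """
    if not summaries:
        raise ValueError("at least one site summary is required")
    gpp = np.array([s.mean_gpp for s in summaries])
    er = np.array([s.mean_er for s in summaries])
    nep = np.array([s.mean_nep for s in summaries])
    pct_flagged = np.array([100.0 - s.pct_unflagged for s in summaries])
    out = {
        "n_sites": len(summaries),
        "mean_gpp": float(np.nanmean(gpp)),
        "mean_er": float(np.nanmean(er)),
        "mean_nep": float(np.nanmean(nep)),
        "mean_pct_days_flagged": float(_round_half_up(np.nanmean(pct_flagged))),
        "pct_autotrophic_by_group": {},
    }
    groups: dict[str, list[float]] = {}
    for s in summaries:
        if s.group:
            groups.setdefault(s.group, []).append(s.pct_autotrophic)
    out["pct_autotrophic_by_group"] = {
        g: float(_round_half_up(float(np.mean(v)))) for g, v in sorted(groups.items())
    }
    if confidences is not None:
        ratings = [
            c.overall if isinstance(c, ConfidenceAssessment) else str(c).upper()
            for c in confidences
        ]
        n_hm = sum(1 for r in ratings if r in ("HIGH", "MEDIUM"))
        out["confidence_counts"] = {r: ratings.count(r) for r in RATINGS}
        out["pct_high_or_medium_confidence"] = float(
            _round_half_up(100.0 * n_hm / len(ratings))
        )
    return out
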