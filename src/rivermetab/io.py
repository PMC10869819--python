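"""Readers and writers for the canonical CSV dialects plus site configuration.

File kinds mirror the deposited input/output files of the public data
release: 15-minute series (``do.csv``, ``temp.csv``, ``sal.csv``,
``barop.csv``, ``disch_gage.csv``), episodic channel field measurements,
hydraulic-geometry coefficients, the assembled model-input table, and the
flagged/censored daily metabolism outputs.  Every file written here starts
with ``#``-comment provenance lines (tool version, config hash, seed) and is
byte-identical on re-run with identical inputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import FieldMeasurement, HydraulicCoeffs
from .prep import ForcingSeries, RawSeries
from .qa import ConfidenceAssessment, SiteSummary

__all__ = [
    "SiteConfig",
    "SERIES_SCHEMAS",
    "read_series",
    "write_series",
    "read_field_measurements",
    "write_field_measurements",
    "read_hydraulic_coeffs",
    "write_model_input",
    "read_model_input",
    "write_daily_outputs",
    "daily_frame",
    "load_published_site_summaries",
]

#: kind -> (value columns, RawSeries kinds, units)
SERIES_SCHEMAS = {
    "do": (["do_mgl"], ["do"], ["mg/L"]),
    "temp": (["temp_c"], ["temp"], ["degC"]),
    "sal": (["sal_psu"], ["sal"], ["PSU"]),
    "barop": (["press_mb"], ["pressure"], ["mb"]),
    "disch_gage": (
        ["discharge_m3s", "gageheight_m"],
        ["discharge", "gage_height"],
        ["m3/s", "m"],
    ),
}
TIME_COL = "dateTime"


@dataclass
class SiteConfig:
    """Per-site metadata and file locations."""

    site_id: str
    latitude: float
    longitude: float
    depth_method: str = "rating"           # "rating" | "hydraulic"
    upstream_structure_distance_m: float | None = None
    hydraulic_coeffs: dict | None = None   # {a, b, c, f}
    paths: dict = field(default_factory=dict)
    replacement_discharge_site: str | None = None
    timestep_minutes: int = 15

    def __post_init__(self) -> None:
        if self.depth_method not in ("rating", "hydraulic"):
            raise ValueError("depth_method must be 'rating' or 'hydraulic'")
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError("coordinates out of range")

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _provenance_lines(seed=None, config_hash=None, extra=None) -> list[str]:
    lines = [f"# rivermetab: {__version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_csv(frame: pd.DataFrame, path, seed=None, config_hash=None, extra=None,
               index=False) -> None:
    buf = _io.StringIO()
    for line in _provenance_lines(seed, config_hash, extra):
        buf.write(line + "\n")
    frame.to_csv(buf, index=index)
    Path(path).write_text(buf.getvalue())


def write_series(series_map: dict[str, pd.Series | pd.DataFrame], kind: str, path,
                 seed=None, config_hash=None) -> None:
    """Write one canonical series file of the given kind.

    ``series_map`` maps RawSeries kind -> series with a UTC DatetimeIndex
    (one entry, except ``disch_gage`` which takes discharge and gage_height).
    """
    cols, kinds, _units = SERIES_SCHEMAS[kind]
    frame = pd.DataFrame(index=None)
    pieces = {}
    for col, rkind in zip(cols, kinds):
        s = series_map[rkind]
        pieces[col] = s
    frame = pd.DataFrame(pieces)
    idx = pd.DatetimeIndex(frame.index)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    frame.insert(0, TIME_COL, idx.strftime("%Y-%m-%dT%H:%M:%SZ"))
    _write_csv(frame, path, seed=seed, config_hash=config_hash)


def read_series(path, kind: str) -> dict[str, RawSeries]:
    """Read one canonical series file into typed RawSeries, one per channel.

    Out-of-order timestamps are sorted with a warning; the schema (time
    column plus the kind's value columns) is validated and unknown extra
    columns are preserved on each returned series' ``extra`` attribute.
    """
    if kind not in SERIES_SCHEMAS:
        raise ValueError(f"unknown series kind {kind!r}")
    cols, kinds, units = SERIES_SCHEMAS[kind]
    frame = pd.read_csv(path, comment="#")
    if TIME_COL not in frame.columns:
        raise ValueError(f"{path}: missing required time column {TIME_COL!r}")
    for col in cols:
        if col not in frame.columns:
            raise ValueError(
                f"{path}: missing required column {col!r} for kind {kind!r} "
                f"(expected columns {[TIME_COL] + cols})"
            )
    t = pd.DatetimeIndex(pd.to_datetime(frame[TIME_COL], utc=True))
    if not t.is_monotonic_increasing:
        warnings.warn(f"{path}: out-of-order timestamps sorted on read", stacklevel=2)
        order = np.argsort(t.values, kind="stable")
        frame = frame.iloc[order].reset_index(drop=True)
        t = t[order]
    extra_cols = [c for c in frame.columns if c not in cols and c != TIME_COL]
    extra = frame[extra_cols].copy() if extra_cols else None
    out = {}
    for col, rkind, unit in zip(cols, kinds, units):
        out[rkind] = RawSeries(
            timestamps=t, values=frame[col].to_numpy(dtype=float),
            kind=rkind, units=unit, extra=extra,
        )
    return out


FIELD_MEAS_COLS = ["date", "width_m", "area_m2", "gageheight_m", "discharge_m3s", "rating"]


def write_field_measurements(measurements: list[FieldMeasurement], path,
                             seed=None, config_hash=None) -> None:
    frame = pd.DataFrame(
        [
            {
                "date": m.date,
                "width_m": m.width,
                "area_m2": m.area,
                "gageheight_m": m.gage_height,
                "discharge_m3s": m.discharge,
                "rating": m.quality_rating,
            }
            for m in measurements
        ],
        columns=FIELD_MEAS_COLS,
    )
    _write_csv(frame, path, seed=seed, config_hash=config_hash)


def read_field_measurements(path) -> list[FieldMeasurement]:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in FIELD_MEAS_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing field-measurement columns {missing}")
    return [
        FieldMeasurement(
            date=pd.Timestamp(r["date"]).date(),
            width=float(r["width_m"]),
            area=float(r["area_m2"]),
            gage_height=float(r["gageheight_m"]),
            discharge=float(r["discharge_m3s"]),
            quality_rating=str(r["rating"]),
        )
        for _, r in frame.iterrows()
    ]


def read_hydraulic_coeffs(path, site_id: str | None = None) -> HydraulicCoeffs:
    """Read hydraulic-geometry coefficients (a, b, c, f), keyed by site."""
    frame = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    for need in ("a", "b", "c", "f"):
        if need not in cols:
            raise ValueError(f"{path}: missing hydraulic coefficient column {need!r}")
    if site_id is not None and "site_no" in cols:
        sel = frame[frame[cols["site_no"]].astype(str) == str(site_id)]
        if sel.empty:
            raise ValueError(f"{path}: no hydraulic coefficients for site {site_id}")
        row = sel.iloc[0]
    else:
        row = frame.iloc[0]
    return HydraulicCoeffs(
        a=float(row[cols["a"]]), b_width=float(row[cols["b"]]),
        c=float(row[cols["c"]]), f=float(row[cols["f"]]),
    )


MODEL_INPUT_COLS = [
    "solar.time", "DO.obs", "DO.sat", "depth", "temp.water", "light",
    "discharge", "gage.height",
]


def write_model_input(forcing: ForcingSeries, path, seed=None, config_hash=None) -> None:
    frame = forcing.frame.reset_index()
    frame = frame[[c for c in MODEL_INPUT_COLS if c in frame.columns]]
    _write_csv(
        frame, path, seed=seed, config_hash=config_hash,
        extra={"latitude": forcing.latitude, "longitude": forcing.longitude,
               "timestep_minutes": forcing.timestep_minutes},
    )


def read_model_input(path) -> ForcingSeries:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    frame = pd.read_csv(path, comment="#", parse_dates=["solar.time"])
    frame = frame.set_index("solar.time")
    for col in ("salinity", "pressure"):
        if col not in frame:
            frame[col] = np.nan
    frame["usable"] = (
        frame["DO.obs"].notna() & frame["temp.water"].notna() & frame["depth"].notna()
    )
    return ForcingSeries(
        frame,
        latitude=float(meta.get("latitude", 0.0)),
        longitude=float(meta.get("longitude", 0.0)),
        timestep_minutes=int(meta.get("timestep_minutes", 15)),
        meta=meta,
    )


def daily_frame(daily, flags=None) -> pd.DataFrame:
    """Daily metabolism (and optional flags) as the canonical output table."""
    frame = pd.DataFrame(
        {
            "date": [d.date for d in daily],
            "GPP": [d.GPP for d in daily],
            "GPP.sd": [d.gpp_sd for d in daily],
            "ER": [d.ER for d in daily],
            "ER.sd": [d.er_sd for d in daily],
            "K600": [d.K600 for d in daily],
            "K600.sd": [d.k600_sd for d in daily],
            "NEP": [d.NEP for d in daily],
            "R2_det": [d.r2_det for d in daily],
            "n_obs": [d.n_obs for d in daily],
        }
    )
    if flags is not None:
        frame["flag1_low_snr"] = [f.flag1_low_snr for f in flags]
        frame["flag2_gpp"] = [f.flag2_gpp for f in flags]
        frame["flag3_er"] = [f.flag3_er for f in flags]
        frame["flag4_k600"] = [f.flag4_k600 for f in flags]
        frame["any_flag"] = [f.any_flag for f in flags]
    return frame


def write_daily_outputs(daily, flags, site: SiteConfig, outdir, run_date: str,
                        seed=None) -> dict[str, Path]:
    """Write the flagged and censored daily CSVs following the release naming.

    Filenames embed the run date, the depth-method token and the site id:
    ``flagged_GPP_ER_K600_<date>_<depthmethod>_<site>.csv`` and the censored
    twin with flagged days removed.  A small metadata stub documenting the
    columns is written alongside.
    """
    if not daily:
        raise ValueError("no daily results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    token = "depth-hgc" if site.depth_method == "hydraulic" else "depth-rc"
    tag = f"{run_date}_{token}_{site.site_id}"
    flagged_path = outdir / f"flagged_GPP_ER_K600_{tag}.csv"
    censored_path = outdir / f"censored_GPP_ER_K600_{tag}.csv"
    ch = site.config_hash()
    _write_csv(daily_frame(daily, flags), flagged_path, seed=seed, config_hash=ch)
    kept = [(d, f) for d, f in zip(daily, flags) if not f.any_flag]
    _write_csv(
        daily_frame([d for d, _ in kept], [f for _, f in kept]),
        censored_path, seed=seed, config_hash=ch,
    )
    stub = outdir / f"metadata_{tag}.txt"
    stub.write_text(
        "Columns: date; GPP, ER, NEP (g O2 m-2 d-1); K600 (d-1); .sd columns are\n"
        "posterior standard deviations; R2_det is the within-day coefficient of\n"
        "determination of modeled vs observed DO; flag columns per the daily QA\n"
        "rubric (low SNR, GPP < -0.5, ER > +0.5, K600 > 20).\n"
    )
    return {"flagged": flagged_path, "censored": censored_path, "metadata": stub}


def write_confidence_report(assessments: dict[str, ConfidenceAssessment], path,
                            seed=None) -> None:
    frame = pd.DataFrame(
        [
            {
                "site_id": sid,
                "c1_gpp": a.c1_gpp_rating,
                "c2_er": a.c2_er_rating,
                "c3_k600_range": a.c3_k600_range_rating,
                "c4_convergence": a.c4_convergence_rating,
                "c5_reach": a.c5_reach_rating,
                "overall": a.overall,
                "notes": a.notes,
            }
            for sid, a in assessments.items()
        ]
    )
    _write_csv(frame, path, seed=seed)


def load_published_site_summaries():
    """Site summaries and overall confidence ratings of the 17-site study.

    Values come from the public USGS data release (10.5066/P9TEBOUR) summary
    tables; used for basin-level aggregation and as a regression anchor.
    Returns ``(summaries, confidences)``.
    """
    src = resources.files("rivermetab").joinpath("data/irb_site_summaries.csv")
    with resources.as_file(src) as p:
        frame = pd.read_csv(p, comment="#", dtype={"site_id": str})
    summaries, confidences = [], []
    for _, r in frame.iterrows():
        n_unflagged = int(r["n_days_unflagged"])
        pct = float(r["pct_unflagged"])
        summaries.append(
            SiteSummary(
                site_id=r["site_id"],
                n_days=int(round(n_unflagged / (pct / 100.0))),
                n_days_unflagged=n_unflagged,
                pct_unflagged=pct,
                mean_discharge=float(r["mean_discharge"]),
                sd_discharge=float(r["sd_discharge"]),
                mean_gpp=float(r["mean_gpp"]),
                sd_gpp=float(r["sd_gpp"]),
                mean_er=float(r["mean_er"]),
                sd_er=float(r["sd_er"]),
                mean_nep=float(r["mean_nep"]),
                sd_nep=float("nan"),
                pct_autotrophic=float(r["pct_autotrophic"]),
                group=str(r["group"]),
            )
        )
        confidences.append(str(r["overall_confidence"]))
    return summaries, confidences
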