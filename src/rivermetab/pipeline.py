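"""File-to-file pipeline stages: simulate -> prepare -> fit -> qa -> summarize.

Each stage reads its predecessor's outputs from disk and writes its own, so
the stages can be chained from the command line or driven individually from
the analysis scripts.  All randomness flows from one master seed per
invocation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .depth import depth_hydraulic, fit_rating, predict_series, velocity_series
from .model.bayes import DailyMetabolism, FitDiagnostics, McmcConfig, fit_with_rerun_policy
from .model.oxygen import DEFAULT_DAY_START_HOUR
from .prep import assemble_input, regrid_and_fill, utc_to_solar
from .qa import (
    apply_flags,
    assess_confidence,
    basin_rollup,
    censor,
    daily_reach_lengths,
    site_summary,
)
from .synthetic import SyntheticConfig, generate_field_measurements, simulate_site, truth_frame

log = logging.getLogger("rivermetab")

RUN_DATE_TAG = "run"   # stable tag keeps outputs byte-identical across reruns


def stage_simulate(config: SyntheticConfig, outdir, seed: int | None = None) -> rio.SiteConfig:
    """Generate one synthetic site and write the canonical raw input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    log.info("simulate: site at (%.3f, %.3f), %d days, seed=%d",
             config.latitude, config.longitude, config.n_days, config.seed)
    forcing, truth = simulate_site(config)
    frame = forcing.frame
    utc = frame.index - pd.Timedelta(hours=config.longitude / 15.0)

    rio.write_series({"do": pd.Series(frame["DO.obs"].to_numpy(), index=utc)},
                     "do", outdir / "do.csv", seed=config.seed)
    rio.write_series({"temp": pd.Series(frame["temp.water"].to_numpy(), index=utc)},
                     "temp", outdir / "temp.csv", seed=config.seed)
    rio.write_series({"sal": pd.Series(frame["salinity"].to_numpy(), index=utc)},
                     "sal", outdir / "sal.csv", seed=config.seed)
    rio.write_series({"pressure": pd.Series(frame["pressure"].to_numpy(), index=utc)},
                     "barop", outdir / "barop.csv", seed=config.seed)
    rio.write_series(
        {
            "discharge": pd.Series(frame["discharge"].to_numpy(), index=utc),
            "gage_height": pd.Series(frame["gage.height"].to_numpy(), index=utc),
        },
        "disch_gage", outdir / "disch_gage.csv", seed=config.seed,
    )
    truth_frame(truth).to_csv(outdir / "truth.csv")

    gh = frame["gage.height"]
    gh_samples = np.linspace(gh.min(), gh.max(), 24)
    m_r, b_r = config.depth_rating
    mean_width = 40.0  # nominal channel width, m; area rating = width * depth rating
    meas = generate_field_measurements(
        (m_r, b_r), (mean_width * m_r, mean_width * b_r), gh_samples,
        noise_sd=0.03, seed=config.seed + 7,
    )
    rio.write_field_measurements(meas, outdir / "field_meas.csv", seed=config.seed)

    site = rio.SiteConfig(
        site_id="synthetic-01",
        latitude=config.latitude,
        longitude=config.longitude,
        depth_method="rating",
        upstream_structure_distance_m=20_000.0,
        paths={
            "do": "do.csv", "temp": "temp.csv", "sal": "sal.csv",
            "barop": "barop.csv", "disch_gage": "disch_gage.csv",
            "field_meas": "field_meas.csv",
        },
        timestep_minutes=config.timestep,
    )
    site.to_yaml(outdir / "site.yml")
    return site


def _resolve(site_dir: Path, site: rio.SiteConfig, key: str) -> Path:
    p = Path(site.paths[key])
    return p if p.is_absolute() else site_dir / p


def stage_prepare(site: rio.SiteConfig, site_dir, outdir) -> Path:
    """Regrid/gap-fill the raw series, estimate depth, assemble model input."""
    site_dir, outdir = Path(site_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gridded = {}
    for key, kind in (("do", "do"), ("temp", "temp"), ("sal", "sal"),
                      ("barop", "barop"), ("disch_gage", "disch_gage")):
        if key not in site.paths:
            continue
        channels = rio.read_series(_resolve(site_dir, site, key), kind)
        for rkind, raw in channels.items():
            gridded[rkind] = regrid_and_fill(raw, site.timestep_minutes)
    components = {
        "do": gridded.get("do"),
        "temp": gridded.get("temp"),
        "sal": gridded.get("sal"),
        "discharge": gridded.get("discharge"),
        "gage_height": gridded.get("gage_height"),
        "pressure": gridded.get("pressure"),
    }
    components = {k: v for k, v in components.items() if v is not None}

    if site.depth_method == "hydraulic":
        coeffs = site.hydraulic_coeffs
        if coeffs is None and "hydraulic_coeffs" in site.paths:
            hc = rio.read_hydraulic_coeffs(
                _resolve(site_dir, site, "hydraulic_coeffs"), site.site_id
            )
        else:
            from .depth import HydraulicCoeffs

            hc = HydraulicCoeffs(**coeffs)
        depth = depth_hydraulic(hc, components["discharge"])
    else:
        meas = rio.read_field_measurements(_resolve(site_dir, site, "field_meas"))
        curve = fit_rating(meas, target="depth", exclude_poor=True)
        log.info("prepare: depth rating h = %.4f*GH + %.4f (n=%d, r2=%.3f)",
                 curve.slope, curve.intercept, curve.n_points, curve.r_squared)
        depth = predict_series(curve, components["gage_height"])

    forcing = assemble_input(
        components, site.latitude, site.longitude, depth=depth,
        timestep_minutes=site.timestep_minutes,
    )
    out = outdir / f"model_input_{site.site_id}.csv"
    rio.write_model_input(forcing, out, config_hash=site.config_hash())
    log.info("prepare: %d rows, %d usable", len(forcing.frame),
             int(forcing.frame['usable'].sum()))
    return out


def stage_fit(site: rio.SiteConfig, model_input_path, outdir, mcmc: McmcConfig | None = None,
              day_start_hour: int = DEFAULT_DAY_START_HOUR):
    """Run the state-space model (with the rerun policy) and write outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    forcing = rio.read_model_input(model_input_path)
    mcmc = mcmc or McmcConfig()
    daily, diag = fit_with_rerun_policy(forcing, mcmc=mcmc, day_start_hour=day_start_hour)
    log.info("fit: %d days; rhat(sigma_obs, proc, K600) = %.3f %.3f %.3f; ER-K600 R2 = %.3f",
             len(daily), diag.rhat_sigma_obs, diag.rhat_sigma_proc,
             diag.rhat_sigma_k600, diag.er_k600_r2)

    daily_path = outdir / f"daily_raw_{site.site_id}.csv"
    rio._write_csv(rio.daily_frame(daily), daily_path, seed=mcmc.seed,
                   config_hash=site.config_hash())
    perf = pd.DataFrame(
        [
            {
                "site_id": site.site_id,
                "rhat_sigma_obs": diag.rhat_sigma_obs,
                "rhat_sigma_proc": diag.rhat_sigma_proc,
                "rhat_sigma_K600": diag.rhat_sigma_k600,
                "er_k600_r2": diag.er_k600_r2,
                "n_chains": diag.n_chains,
                "n_warmup": diag.n_warmup,
                "converged": diag.converged,
            }
        ]
    )
    rio._write_csv(perf, outdir / "model_performance_summary.csv", seed=mcmc.seed)
    return daily, diag, daily_path


def read_daily_raw(path) -> list[DailyMetabolism]:
    frame = pd.read_csv(path, comment="#", parse_dates=["date"])
    return [
        DailyMetabolism(
            date=r["date"].date(), GPP=r["GPP"], ER=r["ER"], K600=r["K600"],
            gpp_sd=r["GPP.sd"], er_sd=r["ER.sd"], k600_sd=r["K600.sd"],
            r2_det=r["R2_det"], n_obs=int(r["n_obs"]),
        )
        for _, r in frame.iterrows()
    ]


def read_performance_summary(path) -> FitDiagnostics:
    row = pd.read_csv(path, comment="#").iloc[0]
    return FitDiagnostics(
        rhat_sigma_obs=float(row["rhat_sigma_obs"]),
        rhat_sigma_proc=float(row["rhat_sigma_proc"]),
        rhat_sigma_k600=float(row["rhat_sigma_K600"]),
        er_k600_r2=float(row["er_k600_r2"]),
        n_chains=int(row["n_chains"]),
        n_warmup=int(row["n_warmup"]),
    )


def _daily_means(model_input_path, day_start_hour=DEFAULT_DAY_START_HOUR):
    forcing = rio.read_model_input(model_input_path)
    frame = forcing.frame
    label = (frame.index - pd.Timedelta(hours=day_start_hour)).floor("D")
    grp = frame.groupby(label)
    return (
        grp["discharge"].mean(),
        grp["gage.height"].mean(),
        grp["temp.water"].mean(),
    )


def stage_qa(site: rio.SiteConfig, site_dir, daily, diag, model_input_path, outdir,
             seed=None):
    """Flag, censor, rate confidence, and write the release-style outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags = apply_flags(daily)
    kept = censor(daily, flags)
    log.info("qa: %d/%d days unflagged", len(kept), len(daily))

    q_daily, gh_daily, t_daily = _daily_means(model_input_path)
    q_daily.index = [ts.date() for ts in q_daily.index]
    gh_daily.index = q_daily.index
    t_daily.index = q_daily.index

    reach = None
    if "field_meas" in site.paths:
        meas = rio.read_field_measurements(_resolve(Path(site_dir), site, "field_meas"))
        try:
            area_curve = fit_rating(meas, target="area", exclude_poor=True)
            v = velocity_series(q_daily, area_curve, gh_daily)
            reach = daily_reach_lengths(daily, v, t_daily)
        except ValueError:
            reach = None
    conf = assess_confidence(
        daily, flags, diag, reach_lengths=reach,
        upstream_structure_distance_m=site.upstream_structure_distance_m,
    )
    paths = rio.write_daily_outputs(daily, flags, site, outdir, RUN_DATE_TAG, seed=seed)
    rio.write_confidence_report({site.site_id: conf},
                                outdir / f"confidence_{site.site_id}.csv", seed=seed)
    summary = site_summary(daily, flags, q_daily, site_id=site.site_id)
    return flags, conf, summary, paths


def rollup_published() -> dict:
    """Basin aggregates recomputed from the published 17-site summary table."""
    summaries, confidences = rio.load_published_site_summaries()
    return basin_rollup(summaries, confidences)


def run_all(config: SyntheticConfig, workdir, mcmc: McmcConfig | None = None):
    """simulate -> prepare -> fit -> qa on one synthetic site."""
    workdir = Path(workdir)
    site = stage_simulate(config, workdir)
    model_input = stage_prepare(site, workdir, workdir)
    mcmc = mcmc or McmcConfig(seed=config.seed)
    daily, diag, _ = stage_fit(site, model_input, workdir, mcmc)
    flags, conf, summary, paths = stage_qa(
        site, workdir, daily, diag, model_input, workdir, seed=mcmc.seed
    )
    return {
        "site": site, "daily": daily, "diag": diag, "flags": flags,
        "confidence": conf, "summary": summary, "paths": paths,
        "model_input": model_input,
    }
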