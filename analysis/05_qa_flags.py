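#!/usr/bin/env python
"""Flag, censor, and rate confidence in the fitted site.

Applies the four daily flags (low within-day signal-to-noise, GPP < -0.5,
ER > +0.5, K600 > 20), writes the flagged and censored daily output files,
computes daily metabolism reach lengths from velocity and K600, and runs
the five-criterion confidence rubric against the configured distance to the
nearest upstream flow-regulation structure.
"""

import argparse
from pathlib import Path

from rivermetab.io import SiteConfig
from rivermetab.pipeline import (
    read_daily_raw,
    read_performance_summary,
    stage_qa,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--site-dir", type=Path, default=Path("results/site01"))
    args = ap.parse_args()

    site = SiteConfig.from_yaml(args.site_dir / "site.yml")
    daily = read_daily_raw(args.site_dir / f"daily_raw_{site.site_id}.csv")
    diag = read_performance_summary(args.site_dir / "model_performance_summary.csv")
    flags, conf, summary, paths = stage_qa(
        site, args.site_dir, daily, diag,
        args.site_dir / f"model_input_{site.site_id}.csv", args.site_dir,
    )
    n_flagged = sum(1 for f in flags if f.any_flag)
    print(f"{n_flagged}/{len(flags)} days flagged "
          f"-> {paths['flagged'].name}, {paths['censored'].name}")
    print(f"confidence: c1={conf.c1_gpp_rating} c2={conf.c2_er_rating} "
          f"c3={conf.c3_k600_range_rating} c4={conf.c4_convergence_rating} "
          f"c5={conf.c5_reach_rating} -> overall {conf.overall}")
    print(f"site summary: GPP {summary.mean_gpp:.2f}±{summary.sd_gpp:.2f}, "
          f"ER {summary.mean_er:.2f}±{summary.sd_er:.2f}, "
          f"NEP {summary.mean_nep:.2f} g O2 m-2 d-1; "
          f"{summary.pct_autotrophic:.0f}% of days autotrophic")


if __name__ == "__main__":
    main()
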