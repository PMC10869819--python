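#!/usr/bin/env python
"""Basin-level aggregation of the published 17-site summary table.

Recomputes the across-site aggregates from the per-site means deposited in
the public USGS data release (10.5066/P9TEBOUR): basin mean GPP/ER/NEP,
river-group autotrophy percentages, the mean share of flagged days, and
the confidence-rating tally.  Writes results/basin_rollup.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rivermetab.pipeline import rollup_published


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/basin_rollup.csv"))
    args = ap.parse_args()

    roll = rollup_published()
    print(f"{roll['n_sites']} sites")
    print(f"  basin mean GPP {roll['mean_gpp']:.2f}, ER {roll['mean_er']:.2f}, "
          f"NEP {roll['mean_nep']:.2f} g O2 m-2 d-1 (heterotrophic overall)")
    for g, v in roll["pct_autotrophic_by_group"].items():
        print(f"  % days autotrophic, {g}: {v:.0f}")
    print(f"  mean % of days flagged: {roll['mean_pct_days_flagged']:.0f}")
    print(f"  % sites rated high or medium confidence: "
          f"{roll['pct_high_or_medium_confidence']:.0f}")

    flat = {k: v for k, v in roll.items() if not isinstance(v, dict)}
    for g, v in roll["pct_autotrophic_by_group"].items():
        flat[f"pct_autotrophic_{g}"] = v
    for r, v in roll.get("confidence_counts", {}).items():
        flat[f"n_sites_{r.lower()}"] = v
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([flat]).to_csv(args.out, index=False)
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
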