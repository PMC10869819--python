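#!/usr/bin/env python
"""Generate a synthetic study site.

Writes the canonical raw 15-minute input CSVs (dissolved oxygen,
temperature, salinity, barometric pressure, discharge + gage height),
synthetic channel field measurements, the daily generating truth, and a
site configuration under results/site01/.  Every later stage starts from
these files only.
"""

import argparse
from pathlib import Path

from rivermetab.pipeline import stage_simulate
from rivermetab.synthetic import SyntheticConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--days", type=int, default=30)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/site01"))
    args = ap.parse_args()

    cfg = SyntheticConfig(n_days=args.days, seed=args.seed)
    site = stage_simulate(cfg, args.out)
    print(f"wrote raw inputs for {site.site_id} ({args.days} days, seed {args.seed})")
    print(f"  -> {args.out}/do.csv, temp.csv, sal.csv, barop.csv, disch_gage.csv")
    print(f"  -> {args.out}/field_meas.csv (24 synthetic channel measurements)")
    print(f"  -> {args.out}/truth.csv (daily GPP/ER/K600 generating values)")


if __name__ == "__main__":
    main()
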