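#!/usr/bin/env python
"""Fit the stage ratings used for depth and velocity estimation.

Depth rating: cross-section averaged depth (measured area / wetted width)
regressed on gage height.  Area rating: measured cross-sectional area on
gage height (used with daily discharge for velocity and the metabolism
reach length).  Measurements rated "poor" are excluded where enough better
measurements exist.
"""

import argparse
from pathlib import Path

from rivermetab.depth import fit_rating
from rivermetab.io import read_field_measurements


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--site-dir", type=Path, default=Path("results/site01"))
    args = ap.parse_args()

    meas = read_field_measurements(args.site_dir / "field_meas.csv")
    print(f"{len(meas)} field measurements "
          f"({sum(1 for m in meas if m.quality_rating == 'poor')} rated poor)")
    for target in ("depth", "area"):
        c = fit_rating(meas, target=target, exclude_poor=True)
        print(f"  {target:5s} = {c.slope:.4f} * GH + {c.intercept:.4f}   "
              f"(n={c.n_points}, r2={c.r_squared:.4f})")


if __name__ == "__main__":
    main()
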