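#!/usr/bin/env python
"""MOP transfer diagnostics for each beetle's model transfer.

Rebuilds each species' calibration region from its rarefied occurrences and
compares calibration environments against the full projection extent:
per-cell environmental similarity to the nearest 10% of calibration cells,
plus the strict-extrapolation mask (any variable outside the calibration
range).  Writes both rasters under results/mop/ and reports how much of the
extent is at extrapolation risk.
"""

import argparse
import os

import numpy as np

from borerisk.grid import buffer_region, mask_stack, read_env_stack, write_asc
from borerisk.mop import mop
from borerisk.occurrences import read_occurrences_csv
from borerisk.pipeline import PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--enm", default="results/enm")
    ap.add_argument("--outdir", default="results/mop")
    args = ap.parse_args()
    config = PipelineConfig(seed=args.seed)
    os.makedirs(args.outdir, exist_ok=True)

    stack = read_env_stack(
        [os.path.join(args.study, f"env{i+1}.asc")
         for i in range(config.n_env_layers)])
    beetles = read_occurrences_csv(os.path.join(args.study, "beetles.csv"))

    for sp in beetles.species:
        occ = read_occurrences_csv(os.path.join(args.enm, f"{sp}_rarefied.csv"))
        region = buffer_region([tuple(p) for p in occ.coords()],
                               config.buffer_km, stack)
        cal = mask_stack(stack, region)
        res = mop(cal, stack, config.mobility_fraction, seed=args.seed)
        write_asc(os.path.join(args.outdir, f"{sp}_similarity.asc"),
                  res.similarity, stack.georef)
        write_asc(os.path.join(args.outdir, f"{sp}_strict_extrapolation.asc"),
                  res.strict_extrapolation.astype(float), stack.georef)
        frac_strict = res.strict_extrapolation[stack.valid_mask].mean()
        print(f"{sp}: median similarity "
              f"{np.nanmedian(res.similarity):.3f}, strict extrapolation on "
              f"{100*frac_strict:.1f}% of the projection extent")


if __name__ == "__main__":
    main()
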