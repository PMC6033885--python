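#!/usr/bin/env python
"""Fit replicated niche models for each target beetle species.

For each beetle: rarefy occurrences to 20 km, buffer them by 200 km to build
the calibration region, fit 5 replicate penalized presence-background models
(25% test points each), take the per-cell median raw output, threshold at
the minimum training presence and the 10th percentile of training values,
and transfer the median model to the full extent.  Writes median and binary
rasters plus threshold values under results/enm/, and the rarefied
occurrences and pooled replicate test points for the later evaluation steps.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from borerisk.enm import (binarize, compute_threshold, fit_replicates_median,
                          predict_raw, presence_cell_indices, SuitabilityMap)
from borerisk.grid import buffer_region, mask_stack, read_env_stack, write_asc
from borerisk.occurrences import (OccurrenceSet, rarefy, read_occurrences_csv,
                                  write_occurrences_csv)
from borerisk.pipeline import PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/enm")
    args = ap.parse_args()
    config = PipelineConfig(seed=args.seed)
    os.makedirs(args.outdir, exist_ok=True)

    stack = read_env_stack(
        [os.path.join(args.study, f"env{i+1}.asc")
         for i in range(config.n_env_layers)])
    beetles = read_occurrences_csv(os.path.join(args.study, "beetles.csv"))

    for i, sp in enumerate(beetles.species):
        occ = rarefy(beetles.for_species(sp), config.rarefy_km_beetles)
        region = buffer_region([tuple(p) for p in occ.coords()],
                               config.buffer_km, stack)
        cal = mask_stack(stack, region)
        median_cal, fitted = fit_replicates_median(
            occ, cal, config.n_replicates, config.test_frac,
            config.feature_spec(), seed=args.seed + 1000 * (i + 1))

        row, col, _ = presence_cell_indices(occ, cal)
        train_vals = median_cal.values[row, col]
        thresholds = {r: compute_threshold(train_vals, r)
                      for r in ("min_training_presence", "p10_training_presence")}

        transfer = np.nanmedian(
            np.stack([predict_raw(m, stack).values for m, _ in fitted]), axis=0)
        transfer = np.where(stack.valid_mask, transfer, np.nan)
        tmap = SuitabilityMap(transfer, "median_raw", stack.georef,
                              stack.nodata_mask.copy())

        write_asc(os.path.join(args.outdir, f"{sp}_median_calibration.asc"),
                  median_cal.values, stack.georef)
        write_asc(os.path.join(args.outdir, f"{sp}_median_transfer.asc"),
                  transfer, stack.georef)
        for rule, tag in (("min_training_presence", "mtp"),
                          ("p10_training_presence", "p10")):
            bm = binarize(tmap, thresholds[rule], rule)
            write_asc(os.path.join(args.outdir, f"{sp}_binary_{tag}.asc"),
                      bm.values.astype(float), stack.georef)
        with open(os.path.join(args.outdir, f"{sp}_thresholds.json"), "w") as fh:
            json.dump({k: float(v) for k, v in thresholds.items()}, fh,
                      indent=1, sort_keys=True)
        write_occurrences_csv(occ, os.path.join(args.outdir, f"{sp}_rarefied.csv"))
        pooled = OccurrenceSet(
            pd.concat([t.records for _, t in fitted], ignore_index=True), "test")
        write_occurrences_csv(pooled,
                              os.path.join(args.outdir, f"{sp}_test_points.csv"))

        suitable_frac = float(np.mean(
            binarize(tmap, thresholds["p10_training_presence"]).values[
                stack.valid_mask]))
        print(f"{sp}: {len(occ)} rarefied points, "
              f"calibration {cal.valid_mask.sum()} cells, "
              f"p10 threshold {thresholds['p10_training_presence']:.3e}, "
              f"{100*suitable_frac:.1f}% of extent suitable at p10")


if __name__ == "__main__":
    main()
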