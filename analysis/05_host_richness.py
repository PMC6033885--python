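#!/usr/bin/env python
"""Model host and related-beetle species and stack richness maps.

Hosts are rarefied to 5 km and kept if they have at least 15 records;
related beetles are rarefied to 20 km and kept if they have more than 3.
Each retained species gets the same replicated model + p10 threshold as the
target beetles; the binary maps are summed into per-group species-richness
rasters, and the per-group mean continuous suitability is kept for the risk
evaluation.  Writes rasters under results/richness/.
"""

import argparse
import os

import numpy as np

from borerisk.enm import stack_richness
from borerisk.grid import read_env_stack, write_asc
from borerisk.occurrences import filter_species_by_min_records, rarefy, \
    read_occurrences_csv
from borerisk.pipeline import PipelineConfig, model_species


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--outdir", default="results/richness")
    args = ap.parse_args()
    config = PipelineConfig(seed=args.seed)
    os.makedirs(args.outdir, exist_ok=True)

    stack = read_env_stack(
        [os.path.join(args.study, f"env{i+1}.asc")
         for i in range(config.n_env_layers)])

    groups = [
        ("hosts", config.rarefy_km_hosts, config.min_records_hosts,
         config.strict_hosts, args.seed + 5000),
        ("related", config.rarefy_km_beetles, config.min_records_related,
         config.strict_related, args.seed + 7000),
    ]
    for label, dist, min_rec, strict, seed in groups:
        occs = read_occurrences_csv(os.path.join(args.study, f"{label}.csv"))
        occs = rarefy(occs, dist)
        occs = filter_species_by_min_records(
            occs, {label: min_rec}, {sp: label for sp in occs.species},
            {label: strict})
        maps, suits = [], []
        for j, sp in enumerate(occs.species):
            res = model_species(occs.for_species(sp), stack, config,
                                rarefy_km=0.0, seed=seed + 10 * j)
            maps.append(res["binaries"]["p10_training_presence"])
            suits.append(res["median_transfer"].values)
        richness = stack_richness(maps) if maps else np.zeros(stack.shape, int)
        mean_suit = (np.nanmean(np.stack(suits), axis=0) if suits
                     else np.zeros(stack.shape))
        write_asc(os.path.join(args.outdir, f"{label}_richness.asc"),
                  richness.astype(float), stack.georef)
        write_asc(os.path.join(args.outdir, f"{label}_mean_suitability.asc"),
                  mean_suit, stack.georef)
        sign = ">" if strict else ">="
        print(f"{label}: {len(occs.species)} species retained "
              f"({sign} {min_rec} records after {dist:g}-km rarefaction), "
              f"max richness {int(richness.max())}")


if __name__ == "__main__":
    main()
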