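#!/usr/bin/env python
"""Combine suitability, hosts and stress into zonal invasion risk.

Evaluates the nested weighted criteria tree for each beetle — potential
distribution (0.4: continuous 0.6 / binary 0.4), vulnerable hosts and
related species (0.35), forest stress factors (0.25) — over the layers the
earlier steps produced, then summarizes the composite per production zone
into five quantile risk classes.  Writes composite rasters, tree configs and
the risk tables under results/smce/.
"""

import argparse
import os

import numpy as np
import pandas as pd

from borerisk.enm import SuitabilityMap
from borerisk.grid import read_asc, read_env_stack, read_zones_geojson, write_asc
from borerisk.occurrences import read_occurrences_csv
from borerisk.pipeline import STRESS_LAYERS, PipelineConfig, beetle_smce_tree
from borerisk.smce import evaluate_smce, zonal_risk


def load(path):
    vals, georef, nodata = read_asc(path)
    return np.where(vals == nodata, np.nan, vals), georef


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--enm", default="results/enm")
    ap.add_argument("--richness", default="results/richness")
    ap.add_argument("--outdir", default="results/smce")
    args = ap.parse_args()
    config = PipelineConfig(seed=args.seed)
    os.makedirs(args.outdir, exist_ok=True)

    hosts_suit, georef = load(os.path.join(args.richness,
                                           "hosts_mean_suitability.asc"))
    related_suit, _ = load(os.path.join(args.richness,
                                        "related_mean_suitability.asc"))
    hosts_rich, _ = load(os.path.join(args.richness, "hosts_richness.asc"))
    related_rich, _ = load(os.path.join(args.richness, "related_richness.asc"))
    base = {
        "host_suitability": hosts_suit,
        "related_suitability": related_suit,
        "binary_suitable_area": ((hosts_rich + related_rich) > 0).astype(float),
    }
    for name in STRESS_LAYERS:
        base[name], _ = load(os.path.join(args.study, f"{name}.asc"))
    zones = read_zones_geojson(os.path.join(args.study, "zones.geojson"))
    beetles = read_occurrences_csv(os.path.join(args.study, "beetles.csv"))

    import json
    for k, sp in enumerate(beetles.species):
        layers = dict(base)
        layers[f"{sp}_suitability"], _ = load(
            os.path.join(args.enm, f"{sp}_median_transfer.asc"))
        layers[f"{sp}_binary"], _ = load(
            os.path.join(args.enm, f"{sp}_binary_p10.asc"))
        tree = beetle_smce_tree(sp, with_related=(k == 0),
                                convex_a=config.convex_a)
        composite = evaluate_smce(tree, layers, georef)
        write_asc(os.path.join(args.outdir, f"{sp}_composite.asc"),
                  composite.values, georef)
        with open(os.path.join(args.outdir, f"{sp}_tree.json"), "w") as fh:
            json.dump(tree.to_dict(), fh, indent=1, sort_keys=True)
        table = zonal_risk(composite, zones, config.n_risk_classes)
        table.to_csv(os.path.join(args.outdir, f"{sp}_zonal_risk.csv"),
                     index=False, float_format="%.8f")
        high = table[table["risk_class"].isin(["high", "very high"])]
        print(f"{sp}: composite risk in "
              f"[{np.nanmin(composite.values):.3f}, "
              f"{np.nanmax(composite.values):.3f}]; "
              f"{len(high)}/{len(table)} zones at high or very high risk "
              f"(production share "
              f"{100 * high['production'].sum() / table['production'].sum():.0f}%)")


if __name__ == "__main__":
    main()
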