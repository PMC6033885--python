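#!/usr/bin/env python
"""Materialize the synthetic study: environment, species, stress, zones.

Writes the miniature study that all later analysis steps read — two target
beetle species with known environmental responses, host and related-beetle
occurrences, three forest-stress probability layers, and production zones —
under results/study/.
"""

import argparse

from borerisk.pipeline import PipelineConfig, make_fixture_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/study")
    args = ap.parse_args()

    config = PipelineConfig(seed=args.seed)
    paths = make_fixture_study(args.outdir, config)
    n_files = sum(len(v) if isinstance(v, list) else 1 for v in paths.values())
    print(f"study written under {args.outdir}: {n_files} files")
    print(f"  environment layers: {len(paths['env'])}, stress layers: 3, "
          f"zones + 3 occurrence tables")
    print(f"  grid {config.grid_shape[0]}x{config.grid_shape[1]} at "
          f"0.05 deg, seed {args.seed}")


if __name__ == "__main__":
    main()
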