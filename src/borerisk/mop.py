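"""Mobility-oriented parity (MOP) transfer diagnostics.

MOP measures, for every cell of a projection extent, the environmental
distance to the nearest fraction of calibration cells, and separately flags
*strict extrapolation*: cells where at least one variable leaves the
calibration min-max envelope.  Variables are z-scored by the calibration
mean/SD before the distance computation so that layers with incommensurable
units contribute comparably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import EnvStack


@dataclass
class MopResult:
    """Environmental-similarity surface plus strict-extrapolation mask."""

    similarity: np.ndarray  # in [0,1]; NaN off the valid projection grid
    strict_extrapolation: np.ndarray  # bool
    mobility_fraction: float
    distance_metric: str = "mean_euclidean_zscore"


def mop(calibration: EnvStack, projection: EnvStack,
        mobility_fraction: float = 0.10,
        max_calibration_cells: int | None = 20000,
        seed: int = 0) -> MopResult:
    """MOP similarity between a calibration region and a projection extent.

    For each valid projection cell, the distance is the mean Euclidean
    distance (on calibration z-scores) to its nearest
    ceil(mobility_fraction * N_cal) calibration cells; similarity is
    1 - distance / max(distance) over the projection extent.  Calibration
    backgrounds larger than ``max_calibration_cells`` are subsampled with a
    seeded RNG (pass None to disable, e.g. for exact small-grid checks).
    """
    if set(calibration.layer_names) != set(projection.layer_names):
        raise ValueError("calibration and projection stacks have different layers")
    if not 0 < mobility_fraction <= 1:
        raise ValueError("mobility_fraction must be in (0, 1]")
    cal = calibration.table()
    if cal.shape[0] == 0:
        raise ValueError("calibration stack has no valid cells")
    # projection columns follow calibration layer order
    proj = np.stack(
        [projection.layer(n)[projection.valid_mask] for n in calibration.layer_names]
    ).T

    cal_min, cal_max = cal.min(axis=0), cal.max(axis=0)
    strict_flat = ((proj < cal_min) | (proj > cal_max)).any(axis=1)

    mu, sd = cal.mean(axis=0), cal.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    cal_z = (cal - mu) / sd
    if max_calibration_cells is not None and len(cal_z) > max_calibration_cells:
        rng = np.random.default_rng(seed)
        cal_z = cal_z[rng.choice(len(cal_z), max_calibration_cells, replace=False)]
    proj_z = (proj - mu) / sd

    k = math.ceil(mobility_fraction * len(cal_z))
    tree = cKDTree(cal_z)
    d, _ = tree.query(proj_z, k=k)
    dist = d.mean(axis=1) if k > 1 else np.asarray(d, float)

    dmax = dist.max()
    sim_flat = 1.0 - dist / dmax if dmax > 0 else np.ones_like(dist)

    similarity = np.full(projection.shape, np.nan)
    similarity[projection.valid_mask] = sim_flat
    strict = np.zeros(projection.shape, bool)
    strict[projection.valid_mask] = strict_flat
    return MopResult(similarity, strict, mobility_fraction)
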