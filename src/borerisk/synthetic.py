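"""Seeded synthetic study generator.

Emulates the inputs of an invasion-risk study on a small georeferenced grid:
spatially autocorrelated environmental layers (Gaussian-smoothed white
noise, z-scored), a known ground-truth suitability surface of the same Gibbs
form as the fitted model, occurrences sampled proportionally to that
surface, stress probability layers in [0,1], and rectangular summary zones.
Every generator is a pure function of its seed.

Grids are georeferenced on a 0.05-degree WGS84 grid so that distance-based
operations (rarefaction, buffering) run on realistic coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .enm import FeatureSpec, SuitabilityMap
from .grid import EnvStack, GridGeoref, ZoneSet
from .occurrences import OccurrenceSet

DEFAULT_GEOREF = GridGeoref(x_min=-102.0, y_max=22.0, cell=0.05)


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic landscape."""

    shape: tuple[int, int] = (100, 100)
    n_layers: int = 2
    correlation_length: float = 10.0  # cells (Gaussian kernel sigma)
    true_coefficients: tuple[float, ...] = (2.0, -1.0)
    n_presences: int = 500
    seed: int = 42
    georef: GridGeoref = DEFAULT_GEOREF

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("grid shape must be positive")
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")


def gen_env_stack(spec: LandscapeSpec) -> EnvStack:
    """Spatially autocorrelated environmental layers, z-scored per layer."""
    rng = np.random.default_rng(spec.seed)
    layers = []
    for _ in range(spec.n_layers):
        z = rng.standard_normal(spec.shape)
        if spec.correlation_length > 0:
            z = gaussian_filter(z, sigma=spec.correlation_length, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers.append(z)
    names = [f"env{i + 1}" for i in range(spec.n_layers)]
    mask = np.zeros(spec.shape, bool)
    return EnvStack(names, np.stack(layers), mask, spec.georef)


def gen_true_suitability(stack: EnvStack, coefficients,
                         feature_spec: FeatureSpec | None = None) -> SuitabilityMap:
    """Ground-truth Gibbs density exp(lambda.f)/Z over the valid cells.

    Features follow the model's convention — scaled to [0,1] by the stack's
    own min/max — so fitted coefficients are directly comparable to the
    generating ones.  Defaults to linear features (one coefficient per
    layer).
    """
    lam = np.asarray(coefficients, float)
    if feature_spec is None:
        feature_spec = FeatureSpec(classes=("linear",), beta=0.0)
    X = stack.table()
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    F = feature_spec.build(np.clip((X - lo) / rng_, 0.0, 1.0))
    if F.shape[1] != lam.size:
        raise ValueError(f"{lam.size} coefficients given for {F.shape[1]} features")
    s = F @ lam
    s -= s.max()
    p = np.exp(s)
    p /= p.sum()
    out = np.full(stack.shape, np.nan)
    out[stack.valid_mask] = p
    return SuitabilityMap(out, "raw", stack.georef, stack.nodata_mask.copy())


def logistic_suitability(stack: EnvStack, coefficients) -> SuitabilityMap:
    """Misspecified (logistic, unnormalized-then-renormalized) variant.

    Useful for robustness checks: the truth is no longer in the fitted
    model family.
    """
    lam = np.asarray(coefficients, float)
    X = stack.table()
    lo, hi = X.min(axis=0), X.max(axis=0)
    u = np.clip((X - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0, 1.0)
    score = u @ lam
    s = 1.0 / (1.0 + np.exp(-(score - score.mean())))
    p = s / s.sum()
    out = np.full(stack.shape, np.nan)
    out[stack.valid_mask] = p
    return SuitabilityMap(out, "raw", stack.georef, stack.nodata_mask.copy())


def sample_occurrences(true_suit: SuitabilityMap, n: int, seed: int,
                       species_id: str = "sp1") -> OccurrenceSet:
    """Sample n points with cell probability proportional to suitability.

    Points are jittered uniformly within their cell so coordinates are
    continuous; deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    valid = true_suit.valid_mask
    p = true_suit.values[valid]
    p = p / p.sum()
    rows, cols = np.nonzero(valid)
    idx = rng.choice(len(p), size=n, replace=True, p=p)
    g = true_suit.georef
    jitter_x = rng.uniform(0, 1, n)
    jitter_y = rng.uniform(0, 1, n)
    lon = g.x_min + (cols[idx] + jitter_x) * g.cell
    lat = g.y_max - (rows[idx] + jitter_y) * g.cell
    df = pd.DataFrame({"species": species_id, "lon": lon, "lat": lat})
    return OccurrenceSet(df, source_tag=f"synthetic seed={seed}")


def gen_stress_layers(shape: tuple[int, int], seed: int,
                      correlation_length: float = 8.0,
                      georef: GridGeoref = DEFAULT_GEOREF) -> EnvStack:
    """Three stress probability layers in [0,1].

    Emulates the forest-stress inputs of the risk evaluation: probability of
    plague insects on trees, probability of standing dead trees, and an
    anthropogenic-impact index.  Independent autocorrelated fields squashed
    through a logistic transform.
    """
    names = ["plague_insects", "standing_dead_trees", "anthropogenic_impact"]
    layers = []
    for i in range(3):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        z = rng.standard_normal(shape)
        if correlation_length > 0:
            z = gaussian_filter(z, sigma=correlation_length, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers.append(1.0 / (1.0 + np.exp(-z)))
    return EnvStack(names, np.stack(layers), np.zeros(shape, bool), georef)


def gen_zones(georef: GridGeoref, shape: tuple[int, int], n_zones: int,
              seed: int) -> ZoneSet:
    """Rectangular 'municipality' zones tiling the grid, with production."""
    from shapely.geometry import box

    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    per_side = int(np.ceil(np.sqrt(n_zones)))
    w = ncols / per_side * georef.cell
    h = nrows / per_side * georef.cell
    zones = []
    k = 0
    for i in range(per_side):
        for j in range(per_side):
            if k >= n_zones:
                break
            x0 = georef.x_min + j * w
            y1 = georef.y_max - i * h
            geom = box(x0, y1 - h, x0 + w, y1)
            production = float(np.round(rng.lognormal(mean=7.0, sigma=1.0), 1))
            zones.append((f"mun{k:03d}", geom, {"production": production}))
            k += 1
    return ZoneSet(zones)


def write_zones_geojson(zones: ZoneSet, path) -> None:
    from shapely.geometry import mapping

    feats = []
    for zid, geom, attrs in zones.zones:
        props = {"zone_id": zid}
        props.update(attrs)
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh,
                  sort_keys=True)
        fh.write("\n")
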