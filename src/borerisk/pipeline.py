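"""Config-driven orchestration of the full invasion-risk analysis.

Stages, per target (beetle) species: spatial rarefaction of occurrences,
calibration-region buffering, replicated presence-background model fitting
with a per-cell median raw map, thresholding (minimum training presence and
10-percentile), transfer to the full extent, MOP transfer diagnostics, and
partial-ROC evaluation on held-out points.  Host and related-beetle species
are modelled the same way, thresholded and stacked into richness layers.
Finally a nested weighted multi-criteria tree combines beetle suitability,
host/related suitability and forest-stress layers into a composite risk
surface summarised over production zones.

Every artifact is a text file (ESRI ASCII raster, CSV, JSON) and every
random choice derives from the single configured seed, so a re-run with an
unchanged config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .enm import (FeatureSpec, binarize, compute_threshold, fit_replicates_median,
                  predict_raw, presence_cell_indices, stack_richness)
from .evaluation import discretize_suitability, partial_roc, suitability_at_points
from .grid import (EnvStack, buffer_region, mask_stack, read_env_stack,
                   read_zones_geojson, write_asc)
from .mop import mop
from .occurrences import (OccurrenceSet, filter_species_by_min_records, rarefy,
                          read_occurrences_csv, write_occurrences_csv)
from .smce import SmceNode, evaluate_smce, zonal_risk
from .synthetic import (LandscapeSpec, gen_env_stack, gen_stress_layers, gen_zones,
                        gen_true_suitability, sample_occurrences,
                        write_zones_geojson)

logger = logging.getLogger(__name__)

STRESS_LAYERS = ["plague_insects", "standing_dead_trees", "anthropogenic_impact"]


@dataclass
class PipelineConfig:
    """Study settings; defaults follow the modelled protocol.

    5 replicates with 25% test points, 200-km calibration buffers, 20-km
    (beetles) and 5-km (hosts/related species) rarefaction, partial ROC with
    E = 0.05 over 500 bootstraps resampling 50% of test points, and 5
    quantile risk classes.
    """

    # synthetic study
    grid_shape: tuple[int, int] = (60, 60)
    n_env_layers: int = 2
    correlation_length: float = 8.0
    n_beetle_presences: int = 80
    n_host_presences: int = 40
    n_hosts: int = 3
    n_related: int = 2
    n_zones: int = 16
    # ENM
    n_replicates: int = 5
    test_frac: float = 0.25
    rarefy_km_beetles: float = 20.0
    rarefy_km_hosts: float = 5.0
    buffer_km: float = 200.0
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    beta: float = 0.1
    # richness record filters (related beetles: > 3; hosts: >= 15)
    min_records_related: int = 3
    min_records_hosts: int = 15
    strict_related: bool = True
    strict_hosts: bool = False
    # evaluation
    E: float = 0.05
    n_boot: int = 500
    resample_frac: float = 0.5
    # MOP / SMCE
    mobility_fraction: float = 0.10
    convex_a: float = 2.0
    n_risk_classes: int = 5
    seed: int = 0

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(classes=tuple(self.feature_classes), beta=self.beta)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["feature_classes"] = list(self.feature_classes)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return human-readable invariant violations (empty list iff valid)."""
    v = []
    for name in ("test_frac", "E", "resample_frac"):
        x = getattr(config, name)
        if not 0 < x < 1:
            v.append(f"{name} must be in (0, 1), got {x}")
    if not 0 < config.mobility_fraction <= 1:
        v.append(f"mobility_fraction must be in (0, 1], got {config.mobility_fraction}")
    for name in ("rarefy_km_beetles", "rarefy_km_hosts"):
        if getattr(config, name) < 0:
            v.append(f"{name} must be >= 0")
    if config.buffer_km <= 0:
        v.append("buffer_km must be > 0")
    if config.n_replicates < 1:
        v.append("n_replicates must be >= 1")
    if config.n_boot < 1:
        v.append("n_boot must be >= 1")
    if config.beta < 0:
        v.append("beta must be >= 0")
    if config.n_risk_classes < 2:
        v.append("n_risk_classes must be >= 2")
    if min(config.grid_shape) <= 0:
        v.append("grid_shape must be positive")
    allowed = {"linear", "quadratic", "product"}
    if not set(config.feature_classes) <= allowed or not config.feature_classes:
        v.append(f"feature_classes must be a non-empty subset of {sorted(allowed)}")
    return v


# ---------------------------------------------------------------------------
# Fixture study

def make_fixture_study(outdir, config: PipelineConfig) -> dict:
    """Materialize a miniature synthetic study on disk.

    Two target beetles with distinct environmental responses, host and
    related-beetle species, three stress layers, and production zones — in
    the same text formats the real pipeline reads.
    """
    os.makedirs(outdir, exist_ok=True)
    seed = config.seed
    spec = LandscapeSpec(shape=tuple(config.grid_shape),
                         n_layers=config.n_env_layers,
                         correlation_length=config.correlation_length,
                         seed=seed)
    stack = gen_env_stack(spec)
    paths = {"env": []}
    for i, name in enumerate(stack.layer_names):
        p = os.path.join(outdir, f"{name}.asc")
        write_asc(p, stack.values[i], stack.georef)
        paths["env"].append(p)

    def linear_coeffs(rng):
        c = rng.uniform(1.0, 3.0, config.n_env_layers)
        c[1::2] *= -1
        return c

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    frames = []
    beetle_species = ["beetle_A", "beetle_B"]
    for k, sp in enumerate(beetle_species):
        coeffs = (2.0, -1.0)[:config.n_env_layers] if k == 0 else tuple(linear_coeffs(rng))
        suit = gen_true_suitability(stack, np.resize(coeffs, config.n_env_layers))
        occ = sample_occurrences(suit, config.n_beetle_presences,
                                 seed=seed * 1000 + 11 + k, species_id=sp)
        frames.append(occ.records)
    beetles = OccurrenceSet(pd.concat(frames, ignore_index=True), "fixture beetles")
    paths["beetles"] = os.path.join(outdir, "beetles.csv")
    write_occurrences_csv(beetles, paths["beetles"])

    frames = []
    for k in range(config.n_hosts):
        suit = gen_true_suitability(stack, linear_coeffs(rng))
        frames.append(sample_occurrences(
            suit, config.n_host_presences, seed=seed * 1000 + 31 + k,
            species_id=f"host_{k + 1}").records)
    hosts = OccurrenceSet(pd.concat(frames, ignore_index=True), "fixture hosts")
    paths["hosts"] = os.path.join(outdir, "hosts.csv")
    write_occurrences_csv(hosts, paths["hosts"])

    frames = []
    for k in range(config.n_related):
        suit = gen_true_suitability(stack, linear_coeffs(rng))
        frames.append(sample_occurrences(
            suit, config.n_host_presences, seed=seed * 1000 + 61 + k,
            species_id=f"related_{k + 1}").records)
    related = OccurrenceSet(pd.concat(frames, ignore_index=True), "fixture related")
    paths["related"] = os.path.join(outdir, "related.csv")
    write_occurrences_csv(related, paths["related"])

    stress = gen_stress_layers(tuple(config.grid_shape), seed=seed * 1000 + 91,
                               georef=stack.georef)
    paths["stress"] = []
    for i, name in enumerate(stress.layer_names):
        p = os.path.join(outdir, f"{name}.asc")
        write_asc(p, stress.values[i], stress.georef)
        paths["stress"].append(p)

    zones = gen_zones(stack.georef, tuple(config.grid_shape), config.n_zones,
                      seed=seed * 1000 + 97)
    paths["zones"] = os.path.join(outdir, "zones.geojson")
    write_zones_geojson(zones, paths["zones"])
    return paths


# ---------------------------------------------------------------------------
# SMCE trees (nested weighted criteria, two levels)

def beetle_smce_tree(species: str, with_related: bool, convex_a: float) -> SmceNode:
    """The two-level risk tree for one beetle species.

    Level 1: potential distribution (0.4), vulnerable hosts and related
    species (0.35), forest/ecosystem stress (0.25).  Level 2 under the
    distribution node: continuous suitability (0.6, convex) and thresholded
    binary suitability (0.4, goal).  Under the hosts node the printed
    sub-weights (hosts 0.2, related 0.3, binary area 0.2) are renormalized;
    without related species the node keeps hosts and binary area equally.
    Stress factors share their node equally.
    """
    conv = {"a": convex_a}
    dist = SmceNode("potential_distribution", 0.4, children=[
        SmceNode("beetle_continuous", 0.6, layer=f"{species}_suitability",
                 standardization="convex", params=conv),
        SmceNode("beetle_binary", 0.4, layer=f"{species}_binary",
                 standardization="goal", params={"min": 0.0, "max": 1.0}),
    ])
    if with_related:
        hosts = SmceNode("hosts_and_related", 0.35, children=[
            SmceNode("host_suitability", 0.2 / 0.7, layer="host_suitability",
                     standardization="convex", params=conv),
            SmceNode("related_suitability", 0.3 / 0.7, layer="related_suitability",
                     standardization="convex", params=conv),
            SmceNode("binary_suitable_area", 0.2 / 0.7, layer="binary_suitable_area",
                     standardization="goal", params={"min": 0.0, "max": 1.0}),
        ])
    else:
        hosts = SmceNode("hosts_and_related", 0.35, children=[
            SmceNode("host_suitability", 0.5, layer="host_suitability",
                     standardization="convex", params=conv),
            SmceNode("binary_suitable_area", 0.5, layer="binary_suitable_area",
                     standardization="goal", params={"min": 0.0, "max": 1.0}),
        ])
    stress = SmceNode("forest_stress", 0.25, children=[
        SmceNode(name, 1.0 / 3.0, layer=name, standardization="goal")
        for name in STRESS_LAYERS
    ])
    return SmceNode(f"{species}_risk", 1.0, children=[dist, hosts, stress])


# ---------------------------------------------------------------------------
# Pipeline stages

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def model_species(occ: OccurrenceSet, stack: EnvStack, config: PipelineConfig,
                  rarefy_km: float, seed: int):
    """Rarefy, buffer, fit replicates, threshold, transfer, evaluate.

    Returns a dict with the calibration/transfer median maps, binary maps,
    MOP result, partial-ROC result and intermediate objects.
    """
    occ = rarefy(occ, rarefy_km)
    region = buffer_region(
        [tuple(p) for p in occ.coords()], config.buffer_km, stack,
        description=f"{config.buffer_km} km around occurrences")
    cal = mask_stack(stack, region)
    spec = config.feature_spec()
    median_cal, fitted = fit_replicates_median(
        occ, cal, config.n_replicates, config.test_frac, spec, seed)

    row, col, _ = presence_cell_indices(occ, cal)
    train_vals = median_cal.values[row, col]
    thr = {rule: compute_threshold(train_vals, rule)
           for rule in ("min_training_presence", "p10_training_presence")}

    transfer_maps = [predict_raw(m, stack).values for m, _ in fitted]
    med = np.nanmedian(np.stack(transfer_maps), axis=0)
    med = np.where(stack.valid_mask, med, np.nan)
    from .enm import SuitabilityMap
    median_transfer = SuitabilityMap(med, "median_raw", stack.georef,
                                     stack.nodata_mask.copy())
    binaries = {rule: binarize(median_transfer, t, rule) for rule, t in thr.items()}

    mop_result = mop(cal, stack, config.mobility_fraction, seed=seed)

    test_frames = [t.records for _, t in fitted]
    test_pooled = OccurrenceSet(pd.concat(test_frames, ignore_index=True), "test")
    disc = discretize_suitability(median_transfer)
    tv = suitability_at_points(disc, test_pooled, stack.georef, stack.shape)
    roc = partial_roc(disc, tv, config.E, config.n_boot, config.resample_frac,
                      seed=seed)
    return {
        "occurrences": occ, "region": region, "calibration": cal,
        "median_calibration": median_cal, "median_transfer": median_transfer,
        "thresholds": thr, "binaries": binaries, "models": fitted,
        "mop": mop_result, "partial_roc": roc,
    }


def _roc_json(roc) -> dict:
    return {
        "mean_ratio": round(roc.mean_ratio, 10),
        "p_proportion": roc.p_proportion,
        "p_welch": round(roc.p_welch, 12) if np.isfinite(roc.p_welch) else None,
        "E": roc.E, "n_boot": roc.n_boot, "resample_frac": roc.resample_frac,
        "seed": roc.seed,
        "auc_ratios": [round(float(r), 10) for r in roc.auc_ratios],
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis into ``outdir``; returns the manifest dict.

    Inputs are materialized (synthetic fixture study) under
    ``outdir/inputs``, then read back through the standard readers so the
    file-based code path is always exercised.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = str(outdir)
    t0 = time.time()
    inputs_dir = os.path.join(outdir, "inputs")
    paths = make_fixture_study(inputs_dir, config)
    logger.info("stage=fixtures seed=%d elapsed=%.1fs", config.seed, time.time() - t0)

    stack = read_env_stack(paths["env"])
    stress = read_env_stack(paths["stress"])
    zones = read_zones_geojson(paths["zones"])
    beetles = read_occurrences_csv(paths["beetles"])
    hosts = read_occurrences_csv(paths["hosts"])
    related = read_occurrences_csv(paths["related"])

    artifacts: list[str] = []

    def save_grid(name, values):
        p = os.path.join(outdir, name)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        write_asc(p, np.asarray(values, float), stack.georef)
        artifacts.append(name)

    def save_json(name, obj):
        p = os.path.join(outdir, name)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")
        artifacts.append(name)

    # --- target beetles -----------------------------------------------------
    beetle_results = {}
    for i, sp in enumerate(beetles.species):
        t = time.time()
        res = model_species(beetles.for_species(sp), stack, config,
                            config.rarefy_km_beetles, seed=config.seed + 1000 * (i + 1))
        beetle_results[sp] = res
        save_grid(f"enm/{sp}_median_calibration.asc", res["median_calibration"].values)
        save_grid(f"enm/{sp}_median_transfer.asc", res["median_transfer"].values)
        for rule, bm in res["binaries"].items():
            tag = "mtp" if rule.startswith("min") else "p10"
            save_grid(f"enm/{sp}_binary_{tag}.asc", bm.values)
        save_grid(f"mop/{sp}_similarity.asc", res["mop"].similarity)
        save_grid(f"mop/{sp}_strict_extrapolation.asc",
                  res["mop"].strict_extrapolation.astype(float))
        save_json(f"eval/{sp}_partial_roc.json", _roc_json(res["partial_roc"]))
        save_json(f"enm/{sp}_thresholds.json",
                  {k: round(float(v), 12) for k, v in res["thresholds"].items()})
        logger.info("stage=enm species=%s elapsed=%.1fs mean_ratio=%.3f",
                    sp, time.time() - t, res["partial_roc"].mean_ratio)

    # --- host / related richness --------------------------------------------
    def group_richness(occs, rarefy_km, min_rec, strict, label, seed):
        occs = rarefy(occs, rarefy_km)
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
        return richness, mean_suit, occs.species

    hosts_rich, hosts_suit, host_kept = group_richness(
        hosts, config.rarefy_km_hosts, config.min_records_hosts,
        config.strict_hosts, "hosts", config.seed + 5000)
    related_rich, related_suit, related_kept = group_richness(
        related, config.rarefy_km_beetles, config.min_records_related,
        config.strict_related, "related", config.seed + 7000)
    save_grid("richness/hosts_richness.asc", hosts_rich.astype(float))
    save_grid("richness/related_richness.asc", related_rich.astype(float))
    logger.info("stage=richness hosts=%d related=%d", len(host_kept), len(related_kept))

    # --- SMCE risk surfaces ---------------------------------------------------
    binary_area = ((hosts_rich + related_rich) > 0).astype(float)
    base_layers = {
        "host_suitability": hosts_suit,
        "related_suitability": related_suit,
        "binary_suitable_area": binary_area,
    }
    for i, name in enumerate(stress.layer_names):
        base_layers[name] = stress.values[i]

    risk_tables = {}
    for k, (sp, res) in enumerate(beetle_results.items()):
        with_related = k == 0  # the second target species has no related group
        tree = beetle_smce_tree(sp, with_related, config.convex_a)
        layers = dict(base_layers)
        layers[f"{sp}_suitability"] = res["median_transfer"].values
        layers[f"{sp}_binary"] = res["binaries"]["p10_training_presence"].values.astype(float)
        composite = evaluate_smce(tree, layers, stack.georef)
        save_grid(f"smce/{sp}_composite.asc", composite.values)
        save_json(f"smce/{sp}_tree.json", tree.to_dict())
        table = zonal_risk(composite, zones, config.n_risk_classes)
        p = os.path.join(outdir, f"risk/{sp}_zonal_risk.csv")
        os.makedirs(os.path.dirname(p), exist_ok=True)
        table.to_csv(p, index=False, float_format="%.8f")
        artifacts.append(f"risk/{sp}_zonal_risk.csv")
        risk_tables[sp] = table
        logger.info("stage=smce species=%s zones=%d", sp, len(table))

    # --- manifest -------------------------------------------------------------
    input_files = sorted(
        os.path.join("inputs", f) for f in os.listdir(inputs_dir))
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {f: _sha256(os.path.join(outdir, f)) for f in input_files},
        "artifacts": {f: _sha256(os.path.join(outdir, f)) for f in sorted(artifacts)},
        "species": {
            "beetles": list(beetle_results),
            "hosts_modelled": host_kept,
            "related_modelled": related_kept,
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d artifacts in %.1fs",
                len(artifacts), time.time() - t0)
    return manifest
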