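"""Occurrence ingestion, spatial rarefaction, filtering and splitting.

Occurrence records are (species, lon, lat) triples in WGS84 decimal degrees.
Spatial rarefaction thins records so that all retained pairs are at least a
minimum great-circle distance apart, reducing sampling-density bias before
presence-background model fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import haversine_km

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Point records of one or more species with a provenance tag."""

    records: pd.DataFrame  # columns: species, lon, lat
    source_tag: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["species", "lon", "lat"]) \
            if not isinstance(self.records, pd.DataFrame) else self.records
        df = df[["species", "lon", "lat"]].copy()
        df["lon"] = df["lon"].astype(float)
        df["lat"] = df["lat"].astype(float)
        if len(df):
            if not np.isfinite(df[["lon", "lat"]].to_numpy()).all():
                raise ValueError("non-finite coordinates")
            if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
                raise ValueError("coordinates outside valid lon/lat ranges")
        # exact duplicates carry no information for presence-background fitting
        df = df.drop_duplicates(subset=["species", "lon", "lat"], keep="first")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return list(pd.unique(self.records["species"]))

    def for_species(self, species_id: str) -> "OccurrenceSet":
        sub = self.records[self.records["species"] == species_id]
        return OccurrenceSet(sub.reset_index(drop=True), self.source_tag)

    def coords(self) -> np.ndarray:
        return self.records[["lon", "lat"]].to_numpy()


def read_occurrences_csv(path, source_tag: str | None = None) -> OccurrenceSet:
    """Read a species,lon,lat CSV; extra columns are dropped with a warning."""
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("ignoring extra occurrence columns: %s", extra)
    return OccurrenceSet(df[["species", "lon", "lat"]],
                         source_tag or str(path))


def write_occurrences_csv(occs: OccurrenceSet, path) -> None:
    occs.records.to_csv(path, index=False, float_format="%.8f")


def rarefy(occs: OccurrenceSet, min_dist_km: float, seed: int = 0,
           shuffle_first: bool = False) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise great-circle distance.

    Points are scanned in input order (optionally shuffled first) and
    retained iff at least ``min_dist_km`` from every previously retained
    point of the same species.  The result is maximal for the scan order:
    no removed point can be re-added without violating the distance.
    """
    if min_dist_km < 0:
        raise ValueError("min_dist_km must be >= 0")
    if len(occs) == 0 or min_dist_km == 0:
        return OccurrenceSet(occs.records.copy(), occs.source_tag)
    kept_frames = []
    for sp in occs.species:
        df = occs.for_species(sp).records
        if shuffle_first:
            rng = np.random.default_rng(seed)
            df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        lon = df["lon"].to_numpy()
        lat = df["lat"].to_numpy()
        kept: list[int] = []
        for i in range(len(df)):
            if not kept:
                kept.append(i)
                continue
            d = haversine_km(lon[kept], lat[kept], lon[i], lat[i])
            if np.all(d >= min_dist_km):
                kept.append(i)
        kept_frames.append(df.iloc[kept])
    out = pd.concat(kept_frames, ignore_index=True) if kept_frames else occs.records
    return OccurrenceSet(out, occs.source_tag)


def filter_species_by_min_records(
    occs: OccurrenceSet,
    min_records: dict[str, int],
    species_groups: dict[str, str] | None = None,
    strict: dict[str, bool] | None = None,
) -> OccurrenceSet:
    """Drop species whose record count fails their group's minimum.

    ``min_records`` maps group name -> count.  ``strict[group]`` True means
    the count must exceed the minimum (">"), False means ">=" (the default).
    Species not assignable to a group raise an error listing them.
    """
    if any(v < 0 for v in min_records.values()):
        raise ValueError("minimum record counts must be >= 0")
    strict = strict or {}
    if species_groups is None:
        if len(min_records) != 1:
            raise ValueError("species_groups required with multiple groups")
        only = next(iter(min_records))
        species_groups = {sp: only for sp in occs.species}
    unassigned = [sp for sp in occs.species if sp not in species_groups]
    if unassigned:
        raise ValueError(f"species without a group assignment: {unassigned}")
    counts = occs.records["species"].value_counts()
    keep = []
    for sp in occs.species:
        grp = species_groups[sp]
        n, thr = int(counts[sp]), min_records[grp]
        ok = n > thr if strict.get(grp, False) else n >= thr
        if ok:
            keep.append(sp)
    out = occs.records[occs.records["species"].isin(keep)]
    return OccurrenceSet(out.reset_index(drop=True), occs.source_tag)


def split_train_test(occs: OccurrenceSet, test_frac: float,
                     seed: int) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint train/test partition with |test| = round(test_frac*n).

    Rounding is half-up so 25% of a multiple of four is exact.  Reproducible
    under a fixed seed.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    n = len(occs)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(math.floor(test_frac * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    df = occs.records
    return (
        OccurrenceSet(df.iloc[train_idx].reset_index(drop=True), occs.source_tag),
        OccurrenceSet(df.iloc[test_idx].reset_index(drop=True), occs.source_tag),
    )
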