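"""Raster grid data model and spatial primitives.

An :class:`EnvStack` holds a set of co-registered environmental layers on a
regular grid (cell-centre registration, row-major, origin at the top-left
corner).  Rasters are read from and written to the ESRI ASCII grid format,
which keeps every artifact human-readable.  Distances on geographic grids
use the haversine great-circle formula (Earth radius 6371 km); projected
grids use planar distance.  The package never reprojects: inputs are assumed
to share one grid.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import nearest_points
from sklearn.decomposition import PCA

EARTH_RADIUS_KM = 6371.0


class AlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridGeoref:
    """Affine georeferencing of a north-up regular grid.

    ``x_min``/``y_max`` locate the outer corner of the top-left cell;
    ``cell`` is the (square) cell size in CRS units.  ``geographic`` selects
    great-circle distance semantics (degrees) versus planar (metres/km).
    """

    x_min: float
    y_max: float
    cell: float
    crs_id: str = "EPSG:4326"
    geographic: bool = True

    def __post_init__(self) -> None:
        if not self.cell > 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of cell centres, each of `shape`."""
        nrows, ncols = shape
        x = self.x_min + (np.arange(ncols) + 0.5) * self.cell
        y = self.y_max - (np.arange(nrows) + 0.5) * self.cell
        return np.broadcast_to(x, (nrows, ncols)).copy(), np.broadcast_to(
            y[:, None], (nrows, ncols)
        ).copy()

    def index_of(self, lon: np.ndarray, lat: np.ndarray, shape: tuple[int, int]):
        """Map coordinates to (row, col); points off the grid get index -1."""
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        col = np.floor((lon - self.x_min) / self.cell).astype(int)
        row = np.floor((self.y_max - lat) / self.cell).astype(int)
        nrows, ncols = shape
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class EnvStack:
    """Aligned multi-layer environmental grid with a shared nodata mask."""

    layer_names: list[str]
    values: np.ndarray  # (n_layers, nrows, ncols) float
    nodata_mask: np.ndarray  # (nrows, ncols) bool, True = missing
    georef: GridGeoref

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.nodata_mask = np.asarray(self.nodata_mask, bool)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.layer_names):
            raise ValueError("values must be (n_layers, nrows, ncols) matching layer_names")
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise ValueError("nodata_mask shape must match the grid")
        self.values[:, self.nodata_mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def table(self) -> np.ndarray:
        """Valid cells as an (n_valid, n_layers) matrix (row-major cell order)."""
        return self.values[:, self.valid_mask].T

    def copy(self) -> "EnvStack":
        return EnvStack(list(self.layer_names), self.values.copy(),
                        self.nodata_mask.copy(), self.georef)


@dataclass
class RegionMask:
    """Boolean calibration-region mask aligned to an EnvStack grid."""

    mask: np.ndarray
    georef: GridGeoref
    origin_description: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("region mask has no true cells")


@dataclass
class ZoneSet:
    """Polygonal summary zones (e.g. municipalities) with attributes."""

    zones: list[tuple[str, BaseGeometry, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [z[0] for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone_ids must be unique")
        repaired = []
        for zid, geom, attrs in self.zones:
            if not geom.is_valid:
                geom = geom.buffer(0)
            repaired.append((zid, geom, dict(attrs)))
        self.zones = repaired

    def __len__(self) -> int:
        return len(self.zones)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_asc(path) -> tuple[np.ndarray, GridGeoref, float]:
    """Read a single-band ESRI ASCII raster; returns (values, georef, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:]).reshape(nrows, ncols)
    georef = GridGeoref(
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + nrows * header["cellsize"],
        cell=header["cellsize"],
    )
    return data, georef, nodata


def write_asc(path, values: np.ndarray, georef: GridGeoref,
              nodata: float = -9999.0, fmt: str = "%.10g") -> None:
    """Write a single-band ESRI ASCII raster (NaN cells become nodata)."""
    values = np.asarray(values, float)
    nrows, ncols = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {georef.x_min:.10g}\n")
        fh.write(f"yllcorner {georef.y_max - nrows * georef.cell:.10g}\n")
        fh.write(f"cellsize {georef.cell:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


def read_env_stack(paths, layer_names: list[str] | None = None) -> EnvStack:
    """Assemble an EnvStack from single-band rasters sharing one grid.

    The union of per-layer nodata becomes the stack mask.  Grids that do not
    align raise :class:`AlignmentError` naming the offending layer.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no raster paths given")
    if layer_names is None:
        import os
        layer_names = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    layers, georef0 = [], None
    mask = None
    for name, p in zip(layer_names, paths):
        vals, georef, nodata = read_asc(p)
        if georef0 is None:
            georef0, shape0 = georef, vals.shape
        elif vals.shape != shape0 or not np.allclose(
            [georef.x_min, georef.y_max, georef.cell],
            [georef0.x_min, georef0.y_max, georef0.cell],
        ):
            raise AlignmentError(f"layer '{name}' does not align with '{layer_names[0]}'")
        missing = ~np.isfinite(vals) | (vals == nodata)
        vals = np.where(missing, np.nan, vals)
        mask = missing if mask is None else (mask | missing)
        layers.append(vals)
    return EnvStack(layer_names, np.stack(layers), mask, georef0)


def write_env_stack(stack: EnvStack, outdir, prefix: str = "") -> list[str]:
    import os
    paths = []
    for i, name in enumerate(stack.layer_names):
        p = os.path.join(str(outdir), f"{prefix}{name}.asc")
        write_asc(p, stack.values[i], stack.georef)
        paths.append(p)
    return paths


def read_zones_geojson(path) -> ZoneSet:
    """Read summary zones from a GeoJSON FeatureCollection.

    Each feature needs a ``zone_id`` property; ``production`` (tons) is
    optional and carried through to the risk table.
    """
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for feat in gj["features"]:
        props = dict(feat.get("properties") or {})
        zid = str(props.pop("zone_id"))
        zones.append((zid, shapely_shape(feat["geometry"]), props))
    return ZoneSet(zones)


# ---------------------------------------------------------------------------
# Operations

def mask_stack(stack: EnvStack, region: RegionMask) -> EnvStack:
    """Restrict a stack to a calibration region: outside cells become nodata."""
    if region.mask.shape != stack.shape:
        raise AlignmentError("region mask shape does not match stack")
    inside = region.mask & stack.valid_mask
    if not inside.any():
        raise ValueError("region does not intersect any valid cells")
    new_mask = ~inside
    vals = stack.values.copy()
    vals[:, new_mask] = np.nan
    return EnvStack(list(stack.layer_names), vals, new_mask, stack.georef)


def buffer_region(seed_geometry, buffer_km: float, template: EnvStack,
                  description: str = "buffered seed") -> RegionMask:
    """Mask of cells whose centre lies within ``buffer_km`` of the seed.

    ``seed_geometry`` is a sequence of (lon, lat) points and/or shapely
    geometries.  Geographic grids use haversine distance to points and to the
    nearest point of each polygon; projected grids use planar distance with
    ``buffer_km`` interpreted in CRS units.
    """
    if not buffer_km > 0:
        raise ValueError("buffer_km must be > 0")
    xs, ys = template.georef.cell_centers(template.shape)
    within = np.zeros(template.shape, bool)
    seeds = seed_geometry if isinstance(seed_geometry, (list, tuple)) else [seed_geometry]
    for seed in seeds:
        if isinstance(seed, BaseGeometry):
            if template.georef.geographic:
                from shapely.geometry import Point
                flat_d = np.empty(xs.size)
                for i, (x, y) in enumerate(zip(xs.ravel(), ys.ravel())):
                    pt = Point(x, y)
                    if seed.contains(pt) or seed.touches(pt):
                        flat_d[i] = 0.0
                    else:
                        q = nearest_points(seed, pt)[0]
                        flat_d[i] = haversine_km(x, y, q.x, q.y)
                d = flat_d.reshape(template.shape)
            else:
                from shapely import distance as shp_distance
                from shapely.geometry import Point
                d = np.array([
                    shp_distance(seed, Point(x, y))
                    for x, y in zip(xs.ravel(), ys.ravel())
                ]).reshape(template.shape)
            within |= d <= buffer_km
        else:
            lon, lat = float(seed[0]), float(seed[1])
            if template.georef.geographic:
                d = haversine_km(xs, ys, lon, lat)
            else:
                d = np.hypot(xs - lon, ys - lat)
            within |= d <= buffer_km
    if not within.any():
        raise ValueError("seed geometry lies entirely outside the template extent")
    return RegionMask(within, template.georef, description)


def pca_summarize(stack: EnvStack, n_components: int) -> tuple[EnvStack, np.ndarray]:
    """PCA summarisation of an environmental stack.

    Layers are z-scored over jointly valid cells before the decomposition;
    the returned stack holds component-score layers ordered by decreasing
    explained variance, together with the variance fractions.
    """
    if n_components > stack.n_layers:
        raise ValueError("n_components exceeds number of layers")
    X = stack.table()
    sd = X.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"layer '{stack.layer_names[j]}' has zero variance")
    Xz = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xz)
    out = np.full((n_components,) + stack.shape, np.nan)
    for k in range(n_components):
        out[k][stack.valid_mask] = scores[:, k]
    names = [f"pc{k + 1}" for k in range(n_components)]
    comp_stack = EnvStack(names, out, stack.nodata_mask.copy(), stack.georef)
    return comp_stack, pca.explained_variance_ratio_.copy()


def region_from_full(stack: EnvStack, description: str = "full extent") -> RegionMask:
    return RegionMask(stack.valid_mask.copy(), stack.georef, description)
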