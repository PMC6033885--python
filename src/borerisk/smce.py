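"""Spatial multi-criteria evaluation (SMCE).

Risk factors (beetle suitability, host suitability/richness, forest-stress
probabilities) are standardized to [0,1] and combined through a nested tree
of weighted criteria: each internal node returns the weighted sum of its
children (weights summing to one), so the composite is a convex combination
of standardized leaves and itself lies in [0,1].  Two standardizations are
supported: a *goal* (linear min-max) function and a *convex* (exponential,
endpoint-anchored) function that de-emphasises the many near-zero cells of a
raw niche-model output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .enm import SuitabilityMap
from .grid import ZoneSet

RISK_LABELS_5 = ["very low", "low", "medium", "high", "very high"]


def standardize_goal(layer: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Linear min-max rescaling to [0,1], clipped at the endpoints."""
    if not vmax > vmin:
        raise ValueError("max must exceed min")
    return np.clip((np.asarray(layer, float) - vmin) / (vmax - vmin), 0.0, 1.0)


def standardize_convex(layer: np.ndarray, a: float, vmin: float,
                       vmax: float) -> np.ndarray:
    """Convex exponential rescaling (exp(a*u)-1)/(exp(a)-1) on the unit scale.

    ``a`` > 0 controls curvature; as a -> 0 this converges to the goal
    (linear) function.  Anchored at 0 and 1 at the endpoints.
    """
    if not a > 0:
        raise ValueError("shape parameter a must be > 0")
    u = standardize_goal(layer, vmin, vmax)
    return np.expm1(a * u) / np.expm1(a)


@dataclass
class SmceNode:
    """Node of the weighted criteria tree.

    Internal nodes carry children whose weights sum to 1 (+-1e-9).  Leaves
    reference one named layer and a standardization: ``goal`` with optional
    (min, max) — defaulting to the layer's own range — or ``convex`` with a
    shape parameter ``a`` (default 2).
    """

    name: str
    weight: float = 1.0
    children: list["SmceNode"] = field(default_factory=list)
    layer: str | None = None
    standardization: str = "goal"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"node '{self.name}': weight must be non-negative")
        if self.children and self.layer is not None:
            raise ValueError(f"node '{self.name}': internal nodes carry no layer")
        if not self.children and self.layer is None:
            raise ValueError(f"leaf '{self.name}' must reference a layer")
        if self.children:
            s = sum(c.weight for c in self.children)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"node '{self.name}': child weights sum to {s}, not 1")
        if not self.children and self.standardization not in {"goal", "convex"}:
            raise ValueError(f"leaf '{self.name}': unknown standardization "
                             f"'{self.standardization}'")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SmceNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def flat_weights(self) -> dict[str, float]:
        """Effective leaf weights: product of weights along root-to-leaf paths."""
        out: dict[str, float] = {}

        def walk(node: "SmceNode", w: float) -> None:
            if node.is_leaf:
                out[node.name] = out.get(node.name, 0.0) + w
            else:
                for c in node.children:
                    walk(c, w * c.weight)

        walk(self, 1.0)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SmceNode":
        children = [cls.from_dict(c) for c in d.get("children", [])]
        return cls(name=d["name"], weight=float(d.get("weight", 1.0)),
                   children=children, layer=d.get("layer"),
                   standardization=d.get("standardization", "goal"),
                   params=dict(d.get("params", {})))

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "weight": self.weight}
        if self.is_leaf:
            d["layer"] = self.layer
            d["standardization"] = self.standardization
            if self.params:
                d["params"] = dict(self.params)
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d


def load_tree(path) -> SmceNode:
    with open(path) as fh:
        text = fh.read()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        import yaml
        obj = yaml.safe_load(text)
    return SmceNode.from_dict(obj)


def _standardize_leaf(leaf: SmceNode, layer: np.ndarray) -> np.ndarray:
    finite = np.isfinite(layer)
    if not finite.any():
        raise ValueError(f"leaf '{leaf.name}': layer '{leaf.layer}' has no data")
    vmin = leaf.params.get("min", float(np.nanmin(layer)))
    vmax = leaf.params.get("max", float(np.nanmax(layer)))
    if vmax <= vmin:  # constant layer (e.g. an all-one binary map)
        return np.where(finite, np.clip(layer, 0.0, 1.0), np.nan)
    if leaf.standardization == "goal":
        std = standardize_goal(layer, vmin, vmax)
    else:
        std = standardize_convex(layer, float(leaf.params.get("a", 2.0)), vmin, vmax)
    return np.where(finite, std, np.nan)


def evaluate_smce(tree: SmceNode, layers: dict[str, np.ndarray],
                  georef=None) -> SuitabilityMap:
    """Evaluate the weighted criteria tree over named layers.

    Leaves are standardized per their spec; internal nodes return the
    weighted sum of their children.  Cells missing in any required leaf
    become nodata in the composite.
    """
    missing = [lf.name for lf in tree.leaves() if lf.layer not in layers]
    if missing:
        raise KeyError(f"leaves reference missing layers: {missing}")
    shapes = {layers[lf.layer].shape for lf in tree.leaves()}
    if len(shapes) > 1:
        raise ValueError("leaf layers are not aligned")

    def evaluate(node: SmceNode) -> np.ndarray:
        if node.is_leaf:
            return _standardize_leaf(node, np.asarray(layers[node.layer], float))
        return sum(c.weight * evaluate(c) for c in node.children)

    comp = evaluate(tree)
    nodata = ~np.isfinite(comp)
    comp = np.where(nodata, np.nan, np.clip(comp, 0.0, 1.0))
    return SuitabilityMap(comp, "composite", georef, nodata)


def classify_means(means: pd.Series, n_classes: int,
                   labels: list[str] | None = None) -> pd.Series:
    """Equal-frequency (quantile) classes over zone means, low to high.

    Degenerate distributions collapse duplicate quantile breaks, yielding
    fewer distinct classes; labels are then assigned from the low end.
    """
    if labels is None:
        labels = RISK_LABELS_5 if n_classes == 5 else [str(i) for i in range(n_classes)]
    valid = means.dropna()
    if valid.nunique() == 1:
        out = pd.Series(pd.NA, index=means.index, dtype="object")
        out[valid.index] = labels[0]
        return out
    codes = pd.qcut(valid, q=n_classes, labels=False, duplicates="drop")
    out = pd.Series(pd.NA, index=means.index, dtype="object")
    out[valid.index] = [labels[int(c)] for c in codes]
    return out


def zonal_risk(composite: SuitabilityMap, zones: ZoneSet,
               n_classes: int = 5) -> pd.DataFrame:
    """Per-zone mean composite risk with quantile risk classes.

    Zone means average the composite over cell centres falling inside each
    polygon; zones intersecting no valid cell get a missing mean and are
    flagged.  Returns a table with zone_id, mean_risk, risk_class, optional
    production, and a no_valid_cells flag.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    xs, ys = composite.georef.cell_centers(composite.values.shape)
    rows = []
    for zid, geom, attrs in zones.zones:
        inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(xs.shape)
        sel = inside & composite.valid_mask
        mean = float(composite.values[sel].mean()) if sel.any() else np.nan
        rows.append({"zone_id": zid, "mean_risk": mean,
                     "no_valid_cells": not sel.any(),
                     "production": attrs.get("production", np.nan)})
    table = pd.DataFrame(rows)
    table["risk_class"] = classify_means(table["mean_risk"], n_classes)
    return table[["zone_id", "mean_risk", "risk_class", "production",
                  "no_valid_cells"]]
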