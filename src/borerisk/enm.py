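"""Presence-background maximum-entropy suitability model.

The model is the penalized Gibbs density that underlies Maxent's "raw
output": over the N background cells of a calibration region, suitability at
cell x is

    P(x) = exp(lambda . f(x)) / Z,     Z = sum_x' exp(lambda . f(x')),

where f(x) are environmental features scaled to [0, 1] by their background
min/max.  The coefficients lambda maximize the mean presence score minus
log Z minus an l1 penalty sum_j beta_j |lambda_j|.  The optimization is a
deterministic convex minimization (L-BFGS-B on the smoothed-l1 objective,
epsilon = 1e-8), so refitting on identical inputs is bit-reproducible.

Raw output sums to one over the calibration background.  On transfer the
same lambda and Z are applied to new environments with feature clamping;
transferred values may sum to anything.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid import EnvStack
from .occurrences import OccurrenceSet, split_train_test

logger = logging.getLogger(__name__)

L1_SMOOTH_EPS = 1e-8


@dataclass(frozen=True)
class FeatureSpec:
    """Feature classes and their l1 regularization multipliers.

    classes: subset of {"linear", "quadratic", "product"}; at least one.
    beta: non-negative regularization multiplier applied to every feature of
    every class (per-class overrides via ``beta_by_class``).  The effective
    penalty weight on feature j is ``beta * s_j / sqrt(m)`` with s_j the
    feature's standard deviation over the m presence samples — the usual
    presence-background convention, which keeps the penalty commensurate
    with the sampling error of the presence means it guards against.
    """

    classes: tuple[str, ...] = ("linear", "quadratic")
    beta: float = 0.1
    beta_by_class: dict | None = None

    def __post_init__(self) -> None:
        allowed = {"linear", "quadratic", "product"}
        if not self.classes or not set(self.classes) <= allowed:
            raise ValueError(f"classes must be a non-empty subset of {allowed}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def feature_names(self, layer_names: list[str]) -> list[str]:
        names = []
        if "linear" in self.classes:
            names += list(layer_names)
        if "quadratic" in self.classes:
            names += [f"{n}^2" for n in layer_names]
        if "product" in self.classes:
            names += [
                f"{a}*{b}"
                for i, a in enumerate(layer_names)
                for b in layer_names[i + 1:]
            ]
        return names

    def betas(self, layer_names: list[str]) -> np.ndarray:
        per_class = self.beta_by_class or {}
        out = []
        p = len(layer_names)
        if "linear" in self.classes:
            out += [per_class.get("linear", self.beta)] * p
        if "quadratic" in self.classes:
            out += [per_class.get("quadratic", self.beta)] * p
        if "product" in self.classes:
            out += [per_class.get("product", self.beta)] * (p * (p - 1) // 2)
        return np.asarray(out, float)

    def build(self, scaled: np.ndarray) -> np.ndarray:
        """Feature matrix from [0,1]-scaled layer values (n, n_layers)."""
        cols = []
        if "linear" in self.classes:
            cols.append(scaled)
        if "quadratic" in self.classes:
            cols.append(scaled ** 2)
        if "product" in self.classes:
            p = scaled.shape[1]
            cols.append(np.column_stack(
                [scaled[:, i] * scaled[:, j] for i in range(p) for j in range(i + 1, p)]
            ) if p > 1 else np.empty((len(scaled), 0)))
        return np.hstack(cols)


@dataclass
class GibbsModel:
    """Fitted presence-background Gibbs model."""

    feature_spec: FeatureSpec
    layer_names: list[str]
    lam: np.ndarray
    scale_min: np.ndarray  # per layer, over calibration background
    scale_max: np.ndarray
    log_z: float
    n_background: int
    background_reference: str = ""

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def _scaled(self, stack: EnvStack, clamp: bool = True) -> np.ndarray:
        missing = [n for n in self.layer_names if n not in stack.layer_names]
        if missing:
            raise ValueError(f"stack is missing model layers: {missing}")
        X = np.stack([stack.layer(n)[stack.valid_mask] for n in self.layer_names]).T
        rng_ = np.where(self.scale_max > self.scale_min,
                        self.scale_max - self.scale_min, 1.0)
        u = (X - self.scale_min) / rng_
        if clamp:
            u = np.clip(u, 0.0, 1.0)
        return u

    def features(self, stack: EnvStack, clamp: bool = True) -> np.ndarray:
        return self.feature_spec.build(self._scaled(stack, clamp))

    def to_json(self, path, seed: int | None = None) -> None:
        obj = {
            "classes": list(self.feature_spec.classes),
            "beta": self.feature_spec.beta,
            "layer_names": self.layer_names,
            "lambda": self.lam.tolist(),
            "scale_min": self.scale_min.tolist(),
            "scale_max": self.scale_max.tolist(),
            "log_z": self.log_z,
            "n_background": self.n_background,
            "background_reference": self.background_reference,
            "seed": seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SuitabilityMap:
    """Per-cell suitability grid; kind 'raw' sums to 1 over valid cells."""

    values: np.ndarray
    kind: str  # raw | median_raw | composite
    georef: object
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        v = self.values[~self.nodata_mask]
        if len(v) and np.nanmin(v) < -1e-12:
            raise ValueError("suitability values must be non-negative")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class BinaryMap:
    """Thresholded presence/absence grid."""

    values: np.ndarray  # {0,1} int
    threshold_value: float
    threshold_rule: str
    georef: object
    nodata_mask: np.ndarray


def presence_cell_indices(occs: OccurrenceSet, stack: EnvStack):
    """(row, col) of presences on valid cells; off-grid/nodata points dropped."""
    lon, lat = occs.records["lon"].to_numpy(), occs.records["lat"].to_numpy()
    row, col = stack.georef.index_of(lon, lat, stack.shape)
    on_grid = row >= 0
    valid = np.zeros(len(row), bool)
    valid[on_grid] = stack.valid_mask[row[on_grid], col[on_grid]]
    dropped = int((~valid).sum())
    if dropped:
        warnings.warn(f"{dropped} presence point(s) fall outside the valid grid "
                      "and were dropped", stacklevel=2)
    return row[valid], col[valid], valid


def _fit_lambda(F_pres: np.ndarray, F_bg: np.ndarray, betas: np.ndarray,
                tol: float = 1e-6, maxiter: int = 10000) -> tuple[np.ndarray, float]:
    """Minimize -(mean presence score - log Z) + sum beta_j |lam_j| (smoothed)."""
    mean_f = F_pres.mean(axis=0)

    def objective(lam):
        scores = F_bg @ lam
        log_z = logsumexp(scores)
        pen = float(np.sum(betas * np.sqrt(lam ** 2 + L1_SMOOTH_EPS)))
        val = -(mean_f @ lam) + log_z + pen
        w = np.exp(scores - log_z)
        grad = -mean_f + F_bg.T @ w + betas * lam / np.sqrt(lam ** 2 + L1_SMOOTH_EPS)
        return val, grad

    x0 = np.zeros(F_bg.shape[1])
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-14})
    lam = res.x
    log_z = float(logsumexp(F_bg @ lam))
    return lam, log_z


def fit_gibbs(presences: OccurrenceSet, background: EnvStack,
              spec: FeatureSpec = FeatureSpec()) -> GibbsModel:
    """Fit the penalized presence-background Gibbs model.

    ``background`` is the environmental stack already masked to the
    calibration region; every valid cell is a background sample.  Requires at
    least two presence records on valid cells.
    """
    row, col, _ = presence_cell_indices(presences, background)
    if len(row) < 2:
        raise ValueError("fewer than 2 presence records fall on valid background cells")
    X_bg = background.table()
    scale_min = X_bg.min(axis=0)
    scale_max = X_bg.max(axis=0)
    rng_ = np.where(scale_max > scale_min, scale_max - scale_min, 1.0)
    U_bg = np.clip((X_bg - scale_min) / rng_, 0.0, 1.0)
    F_bg = spec.build(U_bg)
    X_pres = background.values[:, row, col].T
    U_pres = np.clip((X_pres - scale_min) / rng_, 0.0, 1.0)
    F_pres = spec.build(U_pres)
    s = np.maximum(F_pres.std(axis=0, ddof=0), 1e-3)
    betas = spec.betas(background.layer_names) * s / np.sqrt(F_pres.shape[0])
    lam, log_z = _fit_lambda(F_pres, F_bg, betas)
    return GibbsModel(spec, list(background.layer_names), lam,
                      scale_min, scale_max, log_z, F_bg.shape[0])


def predict_raw(model: GibbsModel, stack: EnvStack) -> SuitabilityMap:
    """Per-cell exp(lambda.f)/Z with Z from the calibration background.

    Transfer outside the training range is clamped per feature; extrapolation
    risk is reported separately by the MOP diagnostic, not here.
    """
    F = model.features(stack, clamp=True)
    raw = np.exp(F @ model.lam - model.log_z)
    out = np.full(stack.shape, np.nan)
    out[stack.valid_mask] = raw
    return SuitabilityMap(out, "raw", stack.georef, stack.nodata_mask.copy())


def training_gain(model: GibbsModel, presences: OccurrenceSet,
                  background: EnvStack) -> float:
    """Mean presence log raw output minus the uniform-model log(1/N)."""
    row, col, _ = presence_cell_indices(presences, background)
    raw = predict_raw(model, background).values[row, col]
    return float(np.mean(np.log(raw)) - np.log(1.0 / model.n_background))


def fit_replicates_median(
    occs: OccurrenceSet, stack: EnvStack, n_replicates: int = 5,
    test_frac: float = 0.25, spec: FeatureSpec = FeatureSpec(), seed: int = 0,
) -> tuple[SuitabilityMap, list[tuple[GibbsModel, OccurrenceSet]]]:
    """Repeated random-subsample replicates; per-cell median of raw maps.

    Each replicate r holds out ``test_frac`` of the points (seed ``seed+r``),
    fits on the remainder, and returns its model with its test set for
    partial-ROC evaluation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    maps, fitted = [], []
    for r in range(n_replicates):
        train, test = split_train_test(occs, test_frac, seed + r)
        model = fit_gibbs(train, stack, spec)
        maps.append(predict_raw(model, stack).values)
        fitted.append((model, test))
    med = np.nanmedian(np.stack(maps), axis=0) if n_replicates > 1 else maps[0]
    med = np.where(stack.valid_mask, med, np.nan)
    return SuitabilityMap(med, "median_raw", stack.georef,
                          stack.nodata_mask.copy()), fitted


def compute_threshold(train_suitabilities, rule: str) -> float:
    """Binarization threshold from training-presence suitabilities.

    ``min_training_presence``: the minimum training value (zero omission).
    ``p10_training_presence``: the largest training value t whose strictly-
    below-t training fraction is <= 0.10, i.e. the (floor(0.1 n)+1)-th order
    statistic — binarizing at it omits at most 10% of training points.
    """
    vals = np.asarray(list(train_suitabilities), float)
    if vals.size == 0:
        raise ValueError("empty training suitability list")
    if rule == "min_training_presence":
        return float(vals.min())
    if rule == "p10_training_presence":
        n = vals.size
        best = vals.min()
        for t in np.unique(vals):
            if np.mean(vals < t) <= 0.10:
                best = max(best, t)
        return float(best)
    raise ValueError(f"unknown threshold rule: {rule}")


def binarize(suit: SuitabilityMap, threshold: float,
             rule: str = "custom") -> BinaryMap:
    """1 where suitability >= threshold on valid cells, else 0."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.where(suit.valid_mask & (suit.values >= threshold), 1, 0).astype(int)
    return BinaryMap(vals, float(threshold), rule, suit.georef,
                     suit.nodata_mask.copy())


def jackknife_importance(occs: OccurrenceSet, stack: EnvStack,
                         spec: FeatureSpec = FeatureSpec(),
                         seed: int = 0) -> dict[str, tuple[float, float]]:
    """Per-layer (gain_alone, gain_without) variable screening.

    gain_alone fits on that layer only; gain_without on all other layers;
    gain is the penalized model's training gain over the uniform null.
    """
    if stack.n_layers < 2:
        raise ValueError("jackknife needs at least 2 layers")
    out = {}
    for name in stack.layer_names:
        alone = _substack(stack, [name])
        without = _substack(stack, [n for n in stack.layer_names if n != name])
        m_alone = fit_gibbs(occs, alone, spec)
        m_without = fit_gibbs(occs, without, spec)
        out[name] = (training_gain(m_alone, occs, alone),
                     training_gain(m_without, occs, without))
    return out


def _substack(stack: EnvStack, names: list[str]) -> EnvStack:
    idx = [stack.layer_names.index(n) for n in names]
    return EnvStack(list(names), stack.values[idx].copy(),
                    stack.nodata_mask.copy(), stack.georef)


def stack_richness(binary_maps: list[BinaryMap]) -> np.ndarray:
    """Per-cell sum of aligned binary presence maps (species richness)."""
    if not binary_maps:
        raise ValueError("no binary maps given")
    shape = binary_maps[0].values.shape
    for bm in binary_maps[1:]:
        if bm.values.shape != shape:
            raise ValueError("binary maps are not aligned")
    return np.sum([bm.values for bm in binary_maps], axis=0)
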