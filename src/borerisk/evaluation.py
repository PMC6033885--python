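"""Partial ROC evaluation of niche-model predictions.

Presence-only models are evaluated against held-out occurrence points by the
AUC-ratio form of partial ROC: the ROC curve is built over all integer
suitability thresholds with the x-axis as the proportion of the study area
predicted present and the y-axis as sensitivity (1 - omission) of the test
points; only the high-sensitivity band (sensitivity >= 1 - E) is integrated,
and the statistic is the ratio of the model's partial area to that of the
1:1 line of no discrimination over the same band.  Ratios above 1 indicate
better-than-random discrimination.  Bootstrapping resamples test points with
replacement; significance is summarised by the proportion of bootstrap
ratios <= 1 and by a t-test of the ratios against 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enm import SuitabilityMap


@dataclass
class PartialRocResult:
    auc_ratios: np.ndarray
    mean_ratio: float
    p_proportion: float  # fraction of bootstrap ratios <= 1
    p_welch: float  # one-sample t-test of ratios vs 1 (greater)
    E: float
    n_boot: int
    resample_frac: float
    seed: int


def discretize_suitability(suit: SuitabilityMap) -> np.ndarray:
    """Rescale to [0,1] by the map maximum, multiply by 1000, floor to int.

    Raw Gibbs outputs are of order 1/N; rescaling by the maximum before the
    x1000 integer conversion preserves ranks (all ROC uses) while keeping
    the integer grid informative.  NaN cells map to -1 (invalid).
    """
    vals = suit.values
    finite = np.isfinite(vals)
    if not finite.any() or np.nanmax(vals) <= 0:
        raise ValueError("suitability map is all zero or empty")
    vmax = np.nanmax(vals)
    out = np.full(vals.shape, -1, dtype=int)
    out[finite] = np.floor(1000.0 * vals[finite] / vmax).astype(int)
    return np.clip(out, -1, 1000)


def _curves(area_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proportion-of-area-predicted-present for thresholds 0..1000.

    Returns (thresholds, area) with area[c] = P(cell value >= c).
    """
    counts = np.bincount(area_values, minlength=1001)
    ge = np.cumsum(counts[::-1])[::-1]  # ge[c] = #cells with value >= c
    return np.arange(1001), ge / len(area_values)


def _ratio(area: np.ndarray, sens: np.ndarray, E: float) -> float:
    """Partial AUC ratio over the band sensitivity >= 1 - E.

    ``area`` and ``sens`` are indexed by threshold 0..1000; both are
    non-increasing in the threshold.  Integration is trapezoidal over the
    kept thresholds, ordered by increasing area.
    """
    keep = sens >= (1.0 - E)
    x = area[keep][::-1]  # ascending area
    y = sens[keep][::-1]
    if len(x) < 2 or x[-1] == x[0]:
        return float("nan")
    auc_model = float(np.trapezoid(y, x))
    auc_random = float(np.trapezoid(x, x))
    return auc_model / auc_random if auc_random > 0 else float("nan")


def partial_roc(discrete_suit: np.ndarray, test_values: np.ndarray,
                E: float = 0.05, n_boot: int = 500,
                resample_frac: float = 0.5, seed: int = 0) -> PartialRocResult:
    """Bootstrap partial-ROC AUC ratios.

    ``discrete_suit`` is the integer suitability grid (invalid cells < 0);
    ``test_values`` the integer suitability at each test point (obtained via
    :func:`suitability_at_points`).  Each bootstrap replicate resamples
    ceil(resample_frac * n) test points with replacement and recomputes the
    ratio against the fixed area curve.
    """
    if not 0 < E < 1:
        raise ValueError("E must be in (0, 1)")
    grid_vals = np.asarray(discrete_suit).ravel()
    grid_vals = grid_vals[grid_vals >= 0]
    test_values = np.asarray(test_values, int)
    test_values = test_values[test_values >= 0]
    n = len(test_values)
    if n < 2:
        raise ValueError("need at least 2 test points on valid cells")
    _, area = _curves(grid_vals)

    rng = np.random.default_rng(seed)
    m = math.ceil(resample_frac * n)
    degenerate = n_boot == 1 and resample_frac == 1.0  # point estimate, no resampling
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = test_values if degenerate else test_values[rng.integers(0, n, size=m)]
        counts = np.bincount(sample, minlength=1001)
        sens = np.cumsum(counts[::-1])[::-1] / m
        ratios[b] = _ratio(area, sens, E)

    finite = ratios[np.isfinite(ratios)]
    mean_ratio = float(finite.mean()) if len(finite) else float("nan")
    p_prop = float(np.mean(finite <= 1.0)) if len(finite) else float("nan")
    if len(finite) > 1 and np.std(finite) > 0:
        p_welch = float(stats.ttest_1samp(finite, 1.0, alternative="greater").pvalue)
    else:
        p_welch = float("nan") if not len(finite) else (0.0 if finite[0] > 1 else 1.0)
    return PartialRocResult(ratios, mean_ratio, p_prop, p_welch,
                            E, n_boot, resample_frac, seed)


def suitability_at_points(discrete_suit: np.ndarray, occs, georef, shape) -> np.ndarray:
    """Integer suitability at each test point; off-grid points get -1."""
    lon = occs.records["lon"].to_numpy()
    lat = occs.records["lat"].to_numpy()
    row, col = georef.index_of(lon, lat, shape)
    vals = np.full(len(row), -1, int)
    on = row >= 0
    vals[on] = np.asarray(discrete_suit)[row[on], col[on]]
    return vals


def compare_ratio_distributions(ratios_a: np.ndarray,
                                ratios_b: np.ndarray) -> float:
    """Welch's two-sample t-test p-value between two bootstrap ratio sets.

    Used to compare a model's ratio distribution against a null (randomized)
    one; unequal variances are not assumed.
    """
    return float(stats.ttest_ind(ratios_a, ratios_b, equal_var=False).pvalue)
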