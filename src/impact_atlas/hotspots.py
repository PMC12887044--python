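"""Normalization, impact classes, top-decile hotspots and composite maps.

Impact layers for different indicators live on wildly different scales
(t CO2e vs PDF·yr vs years of water debt), so each indicator layer is
min–max normalized over its own valid global cells before any comparison.
Cells are then classed low / medium / high by the 0.10 and 0.90 empirical
quantiles of the valid values (strict inequalities; linear-interpolation
quantile estimator), hotspots are the top decile of cells by value, and
two composites summarise the stack: the dominant indicator per cell and
the summed normalized total. A bivariate quantile classification (e.g.
harvested area x species richness) supports trade-off maps.

All tie-breaking is deterministic: stable row-major cell order for ranks,
canonical indicator order (GHG < LND < Nit < Pho < WAT) for indicators.
No randomness enters this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grid import IndicatorKind, Layer, Semantics, assert_aligned
from .impacts import ImpactLayerSet

__all__ = [
    "NormalizedStack",
    "ImpactClassLayer",
    "BivariateClassLayer",
    "LOW",
    "MEDIUM",
    "HIGH",
    "minmax_normalize",
    "normalize_stack",
    "classify_three",
    "top_decile_mask",
    "dominant_indicator",
    "total_impact",
    "bivariate_classify",
]

LOW, MEDIUM, HIGH = 1, 2, 3


@dataclass
class NormalizedStack:
    """Aligned min–max-normalized impact layers for one crop."""

    crop_id: str
    layers: dict[IndicatorKind, Layer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a NormalizedStack needs at least one layer")
        assert_aligned(list(self.layers.values()))
        for kind, layer in self.layers.items():
            vals = layer.valid_values()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"{kind} layer is not normalized to [0, 1]")

    def __getitem__(self, kind: IndicatorKind) -> Layer:
        return self.layers[kind]

    def indicators(self) -> tuple[IndicatorKind, ...]:
        return tuple(sorted(self.layers))


@dataclass
class ImpactClassLayer:
    """Low/medium/high class codes plus the quantile thresholds used."""

    layer: Layer
    q_low: float
    q_high: float
    threshold_low: float
    threshold_high: float

    def counts(self) -> dict[int, int]:
        vals = self.layer.valid_values().astype(int)
        return {c: int((vals == c).sum()) for c in (LOW, MEDIUM, HIGH)}


@dataclass
class BivariateClassLayer:
    """Joint quantile classes for two layers; code = (x_bin-1)*bins + y_bin."""

    layer: Layer
    bins: int
    x_edges: np.ndarray
    y_edges: np.ndarray

    def decode(self, code: int) -> tuple[int, int]:
        return ((code - 1) // self.bins + 1, (code - 1) % self.bins + 1)


def minmax_normalize(layer: Layer) -> Layer:
    """Rescale valid values to [0, 1] by (v - min) / (max - min).

    A constant layer maps to all zeros (degenerate rule: the spread is
    zero, so every cell sits at the minimum).
    """
    vals = layer.valid_values()
    if vals.size == 0:
        raise ValueError("cannot normalize a layer with no valid cells")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out = np.zeros_like(layer.values)
    else:
        out = (layer.values - lo) / (hi - lo)
    out = np.where(layer.valid, out, 0.0)
    return Layer(layer.spec, out, layer.valid.copy(), Semantics.NORMALIZED_IMPACT)


def normalize_stack(impact_set: ImpactLayerSet) -> NormalizedStack:
    """Min–max normalize every indicator layer of a crop independently.

    Normalization scope is per crop x per indicator over all valid cells
    of that layer, which is what makes indicators comparable in the
    composites below.
    """
    return NormalizedStack(
        crop_id=impact_set.crop.crop_id,
        layers={k: minmax_normalize(v) for k, v in impact_set.layers.items()},
    )


def _quantile(vals: np.ndarray, q: float) -> float:
    # linear interpolation of order statistics; fixed so results are
    # reproducible across versions
    return float(np.quantile(vals, q, method="linear"))


def classify_three(
    layer: Layer,
    q_low: float = 0.10,
    q_high: float = 0.90,
    *,
    mode: str = "quantile",
) -> ImpactClassLayer:
    """Class cells low (< q_low), medium, high (> q_high).

    mode="quantile" (default): thresholds are empirical quantiles of the
    valid values; mode="value": q_low/q_high are absolute thresholds on
    the value scale (useful on normalized layers). Comparisons are strict
    on both sides, so a constant layer is all medium.
    """
    if not (0.0 < q_low < q_high < 1.0) and mode == "quantile":
        raise ValueError(f"need 0 < q_low < q_high < 1, got {q_low}, {q_high}")
    vals = layer.valid_values()
    if vals.size == 0:
        raise ValueError("cannot classify a layer with no valid cells")
    if mode == "quantile":
        t_low, t_high = _quantile(vals, q_low), _quantile(vals, q_high)
    elif mode == "value":
        t_low, t_high = float(q_low), float(q_high)
    else:
        raise ValueError(f"mode must be 'quantile' or 'value', got {mode!r}")
    codes = np.full(layer.spec.shape, MEDIUM, dtype=np.float64)
    codes[layer.values < t_low] = LOW
    codes[layer.values > t_high] = HIGH
    codes = np.where(layer.valid, codes, 0.0)
    out = Layer(layer.spec, codes, layer.valid.copy(), Semantics.CATEGORY_CODE)
    return ImpactClassLayer(out, q_low, q_high, t_low, t_high)


def top_decile_mask(layer: Layer, fraction: float = 0.10) -> Layer:
    """Flag exactly ceil(fraction * n_valid) highest-value cells.

    Ties at the cut are broken by row-major cell order (earlier cells
    win), so the flag count is exact and the result deterministic.
    """
    n_valid = layer.n_valid
    if n_valid == 0:
        raise ValueError("cannot rank a layer with no valid cells")
    k = int(np.ceil(fraction * n_valid))
    flat_idx = np.flatnonzero(layer.valid.ravel())
    vals = layer.values.ravel()[flat_idx]
    # primary key: value descending; secondary: row-major position ascending
    order = np.lexsort((flat_idx, -vals))
    chosen = flat_idx[order[:k]]
    mask = np.zeros(layer.spec.shape, dtype=np.float64)
    mask.ravel()[chosen] = 1.0
    return Layer(layer.spec, mask, layer.valid.copy(), Semantics.MASK)


def dominant_indicator(stack: NormalizedStack) -> Layer:
    """Per cell, the indicator with the highest normalized value.

    Only indicators valid in the cell compete; ties go to the smallest
    indicator in canonical order; cells where no indicator is valid are
    invalid. Codes are the IndicatorKind integer values.
    """
    kinds = stack.indicators()
    spec = stack.layers[kinds[0]].spec
    vals = np.stack([stack.layers[k].values for k in kinds])
    valid = np.stack([stack.layers[k].valid for k in kinds])
    vals = np.where(valid, vals, -np.inf)
    any_valid = valid.any(axis=0)
    # argmax over axis 0 returns the first (lowest canonical) max
    winner = np.argmax(vals, axis=0)
    codes = np.asarray([int(k) for k in kinds])[winner].astype(np.float64)
    codes = np.where(any_valid, codes, 0.0)
    return Layer(spec, codes, any_valid, Semantics.CATEGORY_CODE)


def total_impact(stack: NormalizedStack) -> Layer:
    """Sum of normalized values over the indicators valid in each cell."""
    kinds = stack.indicators()
    spec = stack.layers[kinds[0]].spec
    total = np.zeros(spec.shape, dtype=np.float64)
    any_valid = np.zeros(spec.shape, dtype=bool)
    for k in kinds:
        lyr = stack.layers[k]
        total += np.where(lyr.valid, lyr.values, 0.0)
        any_valid |= lyr.valid
    total = np.where(any_valid, total, 0.0)
    return Layer(spec, total, any_valid, Semantics.IMPACT)


def _axis_bins(vals_all: np.ndarray, layer: Layer, bins: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.array([_quantile(vals_all, j / bins) for j in range(1, bins)])
    # value <= edge falls in the lower bin
    b = np.digitize(layer.values, edges, right=True) + 1
    return b, edges


def bivariate_classify(x: Layer, y: Layer, bins: int = 3) -> BivariateClassLayer:
    """Joint quantile classification of two layers.

    Each axis is independently split into ``bins`` quantile classes over
    its own valid cells; the output code is (x_bin - 1) * bins + y_bin,
    valid only where both inputs are.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    assert_aligned([x, y])
    xv, yv = x.valid_values(), y.valid_values()
    if xv.size == 0 or yv.size == 0:
        raise ValueError("both layers need at least one valid cell")
    xb, x_edges = _axis_bins(xv, x, bins)
    yb, y_edges = _axis_bins(yv, y, bins)
    valid = x.valid & y.valid
    codes = ((xb - 1) * bins + yb).astype(np.float64)
    codes = np.where(valid, codes, 0.0)
    layer = Layer(x.spec, codes, valid, Semantics.CATEGORY_CODE)
    return BivariateClassLayer(layer, bins, x_edges, y_edges)
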