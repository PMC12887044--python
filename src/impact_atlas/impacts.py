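"""Per-cell, per-crop impact layers from intensity and production surfaces.

The pipeline multiplies per-tonne environmental-intensity surfaces (GHG in
t CO2e/t; LND, Nit, Pho in PDF·yr/t) by dry-weight production per cell to
obtain impact-per-cell layers. Water debt (WAT, in years) is different in
kind: it is a sustainability ratio of crop water footprint to renewable
water, so it enters the pipeline as the debt surface itself — filtered to
its unsustainable part (values strictly greater than one) — and is never
multiplied by production. Zeros in impact layers are treated as missing
(they arise over water bodies, not as genuine zero impacts) and are
dropped after multiplication so that zero-production cells fall out.

Sugar is the union-overlay of the sugarcane and sugar-beet surfaces:
where both occupy a cell the values are summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grid import IndicatorKind, Layer, Semantics, assert_aligned

__all__ = [
    "CropSpec",
    "ImpactLayerSet",
    "DEFAULT_CROPS",
    "dry_weight",
    "per_cell_impact",
    "water_debt_filter",
    "merge_sum",
    "zeros_to_nodata",
    "build_impact_set",
]

ALL_INDICATORS = tuple(IndicatorKind)

#: default water-debt cutoff: values <= 1 year are sustainable and removed
WAT_CUTOFF = 1.0


@dataclass(frozen=True)
class CropSpec:
    """Configuration for one crop.

    dry_matter_fraction converts fresh production tonnes to dry-weight
    tonnes so crops are compared without their differing water content.
    The shipped defaults are typical dry-matter fractions for these crops
    and are meant to be overridden from config for real analyses.
    available_indicators restricts which impact layers can be built (for
    cocoa only GHG and LND intensity data exist).
    """

    crop_id: str
    dry_matter_fraction: float = 1.0
    available_indicators: tuple[IndicatorKind, ...] = ALL_INDICATORS

    def __post_init__(self) -> None:
        if not 0.0 < self.dry_matter_fraction <= 1.0:
            raise ValueError(
                f"dry_matter_fraction must be in (0, 1], got {self.dry_matter_fraction}"
            )


DEFAULT_CROPS: dict[str, CropSpec] = {
    "wheat": CropSpec("wheat", 0.87),
    "sugarcane": CropSpec("sugarcane", 0.27),
    "sugarbeet": CropSpec("sugarbeet", 0.21),
    "sugar": CropSpec("sugar", 0.24),
    "oilpalm": CropSpec("oilpalm", 0.53),
    "cocoa": CropSpec(
        "cocoa", 0.90, available_indicators=(IndicatorKind.GHG, IndicatorKind.LND)
    ),
}


@dataclass
class ImpactLayerSet:
    """Aligned impact layers for one crop, keyed by indicator."""

    crop: CropSpec
    layers: dict[IndicatorKind, Layer]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.layers:
            assert_aligned(list(self.layers.values()))
        wat = self.layers.get(IndicatorKind.WAT)
        if wat is not None and wat.n_valid and np.any(wat.valid_values() <= WAT_CUTOFF):
            raise ValueError("WAT layer contains valid values <= 1 (sustainable debt)")

    def __getitem__(self, kind: IndicatorKind) -> Layer:
        return self.layers[kind]

    def indicators(self) -> tuple[IndicatorKind, ...]:
        return tuple(sorted(self.layers))


def dry_weight(production: Layer, fraction: float) -> Layer:
    """Convert fresh production tonnes to dry-weight tonnes."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"dry-matter fraction must be in (0, 1], got {fraction}")
    values = np.where(production.valid, production.values * fraction, 0.0)
    return production.with_(values=values, semantics=Semantics.DRY_PRODUCTION_T)


def per_cell_impact(intensity: Layer, dry_production: Layer) -> Layer:
    """Cellwise product of a per-tonne intensity and dry production.

    A cell is valid iff both inputs are valid there.
    """
    assert_aligned([intensity, dry_production])
    valid = intensity.valid & dry_production.valid
    values = np.where(valid, intensity.values * dry_production.values, 0.0)
    return Layer(intensity.spec, values, valid, Semantics.IMPACT)


def water_debt_filter(wat: Layer, cutoff: float = WAT_CUTOFF) -> Layer:
    """Keep only unsustainable water-debt cells (value strictly > cutoff).

    A debt of exactly one year means use equals renewal, which is still
    sustainable, so the comparison is strict: 1.0 is removed.
    """
    valid = wat.valid & (wat.values > cutoff)
    values = np.where(valid, wat.values, 0.0)
    return Layer(wat.spec, values, valid, wat.semantics)


def merge_sum(a: Layer, b: Layer) -> Layer:
    """Union overlay: sum where both valid, pass through where one valid."""
    assert_aligned([a, b])
    valid = a.valid | b.valid
    values = (
        np.where(a.valid, a.values, 0.0) + np.where(b.valid, b.values, 0.0)
    )
    values = np.where(valid, values, 0.0)
    return Layer(a.spec, values, valid, a.semantics)


def zeros_to_nodata(layer: Layer) -> Layer:
    """Mark valid cells that are exactly zero as missing.

    In the source impact surfaces zeros sit over water bodies (terrestrial
    impacts were measured), so they are absence-of-data, not zero impact.
    """
    valid = layer.valid & (layer.values != 0.0)
    values = np.where(valid, layer.values, 0.0)
    return Layer(layer.spec, values, valid, layer.semantics)


def build_impact_set(
    crop: CropSpec,
    intensities: Mapping[IndicatorKind, Layer],
    production: Layer,
    *,
    wat_cutoff: float = WAT_CUTOFF,
) -> ImpactLayerSet:
    """Compose the preprocessing chain into one impact-layer set.

    For GHG/LND/Nit/Pho: intensity × dry-weight production, zeros dropped.
    For WAT: the debt surface itself, filtered to > cutoff, zeros dropped
    (zeros are gone after the filter anyway; kept for uniformity).
    """
    missing = [k for k in crop.available_indicators if k not in intensities]
    if missing:
        raise KeyError(
            f"crop {crop.crop_id!r} lists indicators {[str(m) for m in missing]} "
            "but no intensity layer was supplied"
        )
    layers_in = [intensities[k] for k in crop.available_indicators] + [production]
    assert_aligned(layers_in)

    dry = dry_weight(production, crop.dry_matter_fraction)
    out: dict[IndicatorKind, Layer] = {}
    for kind in crop.available_indicators:
        if kind is IndicatorKind.WAT:
            out[kind] = zeros_to_nodata(water_debt_filter(intensities[kind], wat_cutoff))
        else:
            out[kind] = zeros_to_nodata(per_cell_impact(intensities[kind], dry))
    return ImpactLayerSet(
        crop=crop,
        layers=out,
        provenance=f"impacts for {crop.crop_id}, dm={crop.dry_matter_fraction}",
    )
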