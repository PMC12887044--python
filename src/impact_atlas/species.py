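"""Species-range stacking, richness, and range/cropland overlap fractions.

Each species arrives as a boolean occupancy mask on the analysis grid,
with an IUCN Red List category. Richness is the per-cell count of ranges
(assuming presence across the whole range). The overlap fraction for a
species is the share of its range cells that fall in producing areas of a
crop — cells where the crop's physical area exceeds a threshold (default:
strictly greater than 0 ha). Overlap is cell-count based, which is exact
on an equal-area grid; real longitude/latitude grids approximate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Layer, Semantics, assert_aligned
from .countries import CountryMask

__all__ = [
    "IUCN_CATEGORIES",
    "SpeciesRange",
    "richness",
    "overlap_fraction",
    "rank_by_overlap",
    "harvest_in_range",
]

#: Red List categories, most to least threatened
IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC")


@dataclass
class SpeciesRange:
    """A species' occupancy mask and Red List category."""

    species_id: str
    category: str
    mask: Layer

    def __post_init__(self) -> None:
        if self.category not in IUCN_CATEGORIES:
            raise ValueError(
                f"category must be one of {IUCN_CATEGORIES}, got {self.category!r}"
            )

    def occupied(self) -> np.ndarray:
        """Boolean grid of occupied cells (valid and nonzero)."""
        return self.mask.valid & (self.mask.values != 0)

    @property
    def n_cells(self) -> int:
        return int(self.occupied().sum())


def richness(ranges: list[SpeciesRange], spec=None) -> Layer:
    """Per-cell count of overlapping species ranges.

    An empty list yields an all-zero layer (``spec`` must then be given).
    """
    if not ranges:
        if spec is None:
            raise ValueError("richness of an empty range list needs an explicit spec")
        return Layer.full(spec, 0.0, Semantics.RICHNESS_COUNT)
    assert_aligned([r.mask for r in ranges])
    grid_spec = ranges[0].mask.spec
    counts = np.zeros(grid_spec.shape, dtype=np.float64)
    for r in ranges:
        counts += r.occupied()
    return Layer(grid_spec, counts, np.ones(grid_spec.shape, bool), Semantics.RICHNESS_COUNT)


def overlap_fraction(
    sp_range: SpeciesRange,
    crop_area: Layer,
    min_area: float = 0.0,
    clip: tuple[CountryMask, str] | None = None,
) -> dict:
    """Share of a species' range cells that are crop-producing.

    A cell is producing iff crop_area is valid there and strictly exceeds
    ``min_area``. With ``clip=(mask, country)`` both the range and the
    producing set are restricted to that country's cells (the in-country
    denominator variant); the default denominator is the whole range.
    """
    assert_aligned([sp_range.mask, crop_area])
    occupied = sp_range.occupied()
    if clip is not None:
        mask, country = clip
        assert_aligned([sp_range.mask, mask.layer])
        occupied = occupied & mask.cells_of(country)
    range_cells = int(occupied.sum())
    if range_cells == 0:
        raise ValueError(
            f"range of {sp_range.species_id!r} is empty"
            + (" after clipping" if clip is not None else "")
        )
    producing = crop_area.valid & (crop_area.values > min_area)
    in_range = int((occupied & producing).sum())
    return {
        "species_id": sp_range.species_id,
        "category": sp_range.category,
        "range_cells": range_cells,
        "producing_cells_in_range": in_range,
        "overlap_fraction": in_range / range_cells,
    }


def rank_by_overlap(results: list[dict], category: str | None = None) -> pd.DataFrame:
    """Overlap rows for one category, largest fraction first.

    Equal fractions are ordered lexicographically by species id so the
    ranking is deterministic.
    """
    rows = [r for r in results if category is None or r["category"] == category]
    df = pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "category",
            "range_cells",
            "producing_cells_in_range",
            "overlap_fraction",
        ],
    )
    return df.sort_values(
        ["overlap_fraction", "species_id"], ascending=[False, True]
    ).reset_index(drop=True)


def harvest_in_range(crop: Layer, sp_range: SpeciesRange) -> Layer:
    """Crop values inside the species' range; invalid elsewhere."""
    assert_aligned([crop, sp_range.mask])
    keep = crop.valid & sp_range.occupied()
    values = np.where(keep, crop.values, 0.0)
    return Layer(crop.spec, values, keep, crop.semantics)
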