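"""Zonal aggregation of impact layers within country masks.

Supports the country-comparison stage: for each source country and each
indicator, the total standardised (normalized) impact summed over the
country's producing cells, and the same total per tonne of production.
Cells are wholly assigned to a single country — no fractional border
cells — which is adequate at the grid resolutions the pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Layer, assert_aligned
from .hotspots import NormalizedStack

__all__ = ["CountryMask", "zonal_sum", "country_profile"]


@dataclass
class CountryMask:
    """Layer of integer country codes plus a code -> name registry."""

    layer: Layer
    registry: dict[int, str]

    def __post_init__(self) -> None:
        codes = set(np.unique(self.layer.valid_values()).astype(int))
        unknown = codes - set(self.registry)
        if unknown:
            raise ValueError(f"mask holds codes missing from registry: {sorted(unknown)}")

    @property
    def countries(self) -> list[str]:
        return sorted(self.registry.values())

    def code_of(self, country: str) -> int:
        for code, name in self.registry.items():
            if name == country:
                return code
        raise KeyError(f"unknown country {country!r}")

    def cells_of(self, country: str) -> np.ndarray:
        """Boolean grid of the cells assigned to a country."""
        return self.layer.valid & (self.layer.values == self.code_of(country))


def zonal_sum(layer: Layer, mask: CountryMask, country: str) -> float:
    """Sum of valid layer values over the cells assigned to a country."""
    assert_aligned([layer, mask.layer])
    zone = mask.cells_of(country) & layer.valid
    return float(layer.values[zone].sum())


def country_profile(
    stack: NormalizedStack,
    mask: CountryMask,
    production: Layer,
    countries: list[str] | None = None,
) -> pd.DataFrame:
    """Total and per-tonne standardised impact per (country, indicator).

    per_tonne is total / production tonnes within the country; recorded as
    NaN where the country has zero production. Indicators missing for a
    crop simply do not appear as rows (cocoa has only GHG and LND).
    """
    layers = list(stack.layers.values())
    assert_aligned(layers + [mask.layer, production])
    if countries is None:
        countries = mask.countries
    rows = []
    for country in countries:
        prod = zonal_sum(production, mask, country)
        for kind in stack.indicators():
            total = zonal_sum(stack.layers[kind], mask, country)
            rows.append(
                {
                    "country": country,
                    "crop": stack.crop_id,
                    "indicator": str(kind),
                    "total_impact": total,
                    "production_t": prod,
                    "per_tonne": total / prod if prod > 0 else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["country", "crop", "indicator", "total_impact", "production_t", "per_tonne"],
    )
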