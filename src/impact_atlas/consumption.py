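"""Product-level consumption arithmetic linking recipes to crop supply.

The simplest sustainability bridge to consumers: take a product's annual
consumption count and per-unit ingredient masses, convert to national
ingredient tonnages, and express those as shares of domestic supply or of
imports. The shipped defaults describe the UK biscuit case study — twelve
billion biscuits a year, 4.4 g sugar and roughly 5 g chocolate per dark
chocolate digestive, and a given 96,000 t of wheat — against supply totals
from the UK supplier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ProductProfile",
    "SupplyContext",
    "UK_BISCUITS",
    "UK_SUPPLY",
    "ingredient_mass_tonnes",
    "share_of_supply",
    "fraction_of_imports",
    "consumption_table",
]


@dataclass(frozen=True)
class ProductProfile:
    """A consumed product: annual unit count and per-unit ingredient grams."""

    name: str
    units_per_year: float
    grams_per_unit: dict[str, float] = field(default_factory=dict)
    #: ingredient tonnages known directly rather than via per-unit grams
    given_tonnes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units_per_year < 0:
            raise ValueError("units_per_year must be non-negative")
        for ing, g in self.grams_per_unit.items():
            if g < 0:
                raise ValueError(f"negative grams per unit for {ing!r}")
        for ing, t in self.given_tonnes.items():
            if t < 0:
                raise ValueError(f"negative given tonnage for {ing!r}")

    def ingredient_tonnes(self) -> dict[str, float]:
        out = {
            ing: ingredient_mass_tonnes(self.units_per_year, g)
            for ing, g in self.grams_per_unit.items()
        }
        out.update(self.given_tonnes)
        return out


@dataclass(frozen=True)
class SupplyContext:
    """Per-crop supply totals (tonnes), labelled domestic or imported."""

    domestic_production: dict[str, float] = field(default_factory=dict)
    imports: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, d in (("production", self.domestic_production), ("imports", self.imports)):
            for crop, t in d.items():
                if t < 0:
                    raise ValueError(f"negative {label} for {crop!r}")


#: UK biscuit case-study defaults: 12e9 biscuits/yr; 4.4 g sugar and ~5 g
#: chocolate per dark chocolate digestive; wheat enters as a given 96,000 t.
UK_BISCUITS = ProductProfile(
    name="biscuits",
    units_per_year=12e9,
    grams_per_unit={"sugar": 4.4, "chocolate": 5.0},
    given_tonnes={"wheat": 96_000.0},
)

#: UK supply totals from the averaged, origin-corrected supplier analysis:
#: domestic wheat and sugar-beet production, and total cocoa imports from
#: the four major origin countries.
UK_SUPPLY = SupplyContext(
    domestic_production={"wheat": 14_030_964.0, "sugar": 7_276_708.0},
    imports={"cocoa": 65_916.0 + 64_620.0 + 19_292.0 + 12_280.0},
)


def ingredient_mass_tonnes(units: float, grams_per_unit: float) -> float:
    """Annual ingredient mass in tonnes from unit count and grams per unit."""
    if units < 0 or grams_per_unit < 0:
        raise ValueError("units and grams_per_unit must be non-negative")
    return units * grams_per_unit / 1e6


def share_of_supply(mass_t: float, supply_t: float, decimals: int = 1) -> tuple[float, float]:
    """Percentage of a supply total, rounded half-up for presentation.

    Returns (rounded, raw) percentages; the raw value is exact.
    """
    if supply_t <= 0:
        raise ValueError(f"supply must be positive, got {supply_t}")
    raw = 100.0 * mass_t / supply_t
    rounded = float(
        Decimal(repr(raw)).quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_UP)
    )
    return rounded, raw


def fraction_of_imports(mass_t: float, import_total_t: float, conversion: float = 1.0) -> float:
    """Fraction of an import total, after a product->crop conversion factor.

    conversion=1 treats product and crop mass as equivalent (e.g. the
    default chocolate:cocoa ratio of 1:1).
    """
    if import_total_t <= 0:
        raise ValueError(f"import total must be positive, got {import_total_t}")
    return mass_t * conversion / import_total_t


#: which crop each default ingredient draws on, and from which pool
_INGREDIENT_CROP = {
    "sugar": ("sugar", "domestic"),
    "wheat": ("wheat", "domestic"),
    "chocolate": ("cocoa", "imports"),
}


def consumption_table(
    profile: ProductProfile = UK_BISCUITS,
    supply: SupplyContext = UK_SUPPLY,
    ingredient_crop: dict[str, tuple[str, str]] | None = None,
    conversion: dict[str, float] | None = None,
) -> list[dict]:
    """Tonnage and supply-share rows for every ingredient of a product.

    For ingredients backed by domestic production the share is a rounded
    percentage; for imported crops it is an unrounded fraction of imports
    (with an optional product-to-crop mass conversion).
    """
    ingredient_crop = ingredient_crop or _INGREDIENT_CROP
    conversion = conversion or {}
    rows = []
    for ing, tonnes in profile.ingredient_tonnes().items():
        crop, pool = ingredient_crop.get(ing, (ing, "domestic"))
        row = {
            "product": profile.name,
            "ingredient": ing,
            "crop": crop,
            "mass_tonnes": tonnes,
            "supply_pool": pool,
        }
        if pool == "domestic" and crop in supply.domestic_production:
            rounded, raw = share_of_supply(tonnes, supply.domestic_production[crop])
            row["share_pct"] = rounded
            row["share_pct_raw"] = raw
        elif pool == "imports" and crop in supply.imports:
            frac = fraction_of_imports(
                tonnes, supply.imports[crop], conversion.get(ing, 1.0)
            )
            row["import_fraction"] = frac
        rows.append(row)
    return rows
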