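"""Bilateral trade flows, re-export correction, and supplier tables.

A country's imports often include goods its trade partner merely
re-exported, so bilateral flow matrices overstate the partner's role as a
producer. The origin-tracing step here re-assigns every traded tonne to
the country that actually produced it: each country's total supply (own
production plus imports) has an origin composition, its exports inherit
that composition proportionally, and the attribution is propagated through
the trade network to a fixed point. The result is an origin matrix giving,
for each consumer, the tonnes of its apparent consumption
(production + imports - exports) attributable to each producing country.

Flows are averaged over a year window before tracing (missing records
count as zero over the full window length), and sugar-crop items are
combined beforehand because many traded sugar products do not identify
the source crop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TradeTensor",
    "OriginMatrix",
    "ConvergenceError",
    "average_flows",
    "combine_sugar_items",
    "trace_origins",
    "supplier_table",
    "major_suppliers",
    "read_faostat_csv",
]

FLOW_COLS = ["year", "item", "exporter", "importer", "tonnes"]
PROD_COLS = ["year", "item", "country", "tonnes"]

#: default items folded into "sugar"
SUGAR_ITEMS = ("sugarcane", "sugarbeet", "sugar_raw", "sugar_refined")


class ConvergenceError(RuntimeError):
    """Origin tracing failed to reach its fixed point within the cap."""


@dataclass
class TradeTensor:
    """Bilateral flows plus per-country production totals.

    flows: DataFrame [year, item, exporter, importer, tonnes];
    production: DataFrame [year, item, country, tonnes].
    Domestic supply is never stored as a flow (exporter != importer);
    it is derived from production during tracing. A ``year`` of -1 marks
    a window-averaged (single-period) tensor.
    """

    flows: pd.DataFrame
    production: pd.DataFrame

    def __post_init__(self) -> None:
        self.flows = pd.DataFrame(self.flows, columns=FLOW_COLS).reset_index(drop=True)
        self.production = pd.DataFrame(self.production, columns=PROD_COLS).reset_index(
            drop=True
        )
        if len(self.flows) and (self.flows["tonnes"] < 0).any():
            raise ValueError("negative flow tonnage")
        if len(self.production) and (self.production["tonnes"] < 0).any():
            raise ValueError("negative production tonnage")
        if len(self.flows) and (self.flows["exporter"] == self.flows["importer"]).any():
            raise ValueError("flow records must have exporter != importer")

    @property
    def countries(self) -> list[str]:
        names = set(self.production["country"])
        names |= set(self.flows["exporter"]) | set(self.flows["importer"])
        return sorted(names)

    def items(self) -> list[str]:
        return sorted(set(self.flows["item"]) | set(self.production["item"]))


@dataclass
class OriginMatrix:
    """Consumer x origin attributed tonnes after re-export correction."""

    item: str
    countries: list[str]
    attributed: np.ndarray  # [consumer, origin] tonnes
    production: np.ndarray  # [origin] tonnes
    consumption: np.ndarray  # [consumer] apparent consumption
    iterations: int
    residual: float
    warnings: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.attributed, index=self.countries, columns=self.countries
        ).rename_axis(index="consumer", columns="origin")

    def consumer_row(self, consumer: str) -> pd.Series:
        return self.as_frame().loc[consumer]


def average_flows(t: TradeTensor, years: tuple[int, int]) -> TradeTensor:
    """Average flows and production over an inclusive year window.

    Records absent in a year count as zero, so the denominator is the
    full window length (11 for 2003-2013) regardless of coverage.
    """
    y0, y1 = years
    if y1 < y0:
        raise ValueError(f"empty year window {years}")
    n_years = y1 - y0 + 1
    fl = t.flows[(t.flows["year"] >= y0) & (t.flows["year"] <= y1)]
    pr = t.production[(t.production["year"] >= y0) & (t.production["year"] <= y1)]
    fl = (
        fl.groupby(["item", "exporter", "importer"], as_index=False)["tonnes"]
        .sum()
        .assign(tonnes=lambda d: d["tonnes"] / n_years, year=-1)
    )
    pr = (
        pr.groupby(["item", "country"], as_index=False)["tonnes"]
        .sum()
        .assign(tonnes=lambda d: d["tonnes"] / n_years, year=-1)
    )
    return TradeTensor(fl[FLOW_COLS], pr[PROD_COLS])


def combine_sugar_items(
    t: TradeTensor, sugar_items: Sequence[str] = SUGAR_ITEMS, target: str = "sugar"
) -> TradeTensor:
    """Fold all sugar-tagged items into a single "sugar" item by summation."""
    sugar = set(sugar_items) | {target}

    def _fold(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        df = df.copy()
        df.loc[df["item"].isin(sugar), "item"] = target
        return df.groupby(keys, as_index=False)["tonnes"].sum()

    fl = _fold(t.flows, ["year", "item", "exporter", "importer"])
    pr = _fold(t.production, ["year", "item", "country"])
    return TradeTensor(fl[FLOW_COLS], pr[PROD_COLS])


def _single_period_matrices(
    t: TradeTensor, item: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    fl = t.flows[t.flows["item"] == item]
    pr = t.production[t.production["item"] == item]
    if fl["year"].nunique() > 1 or pr["year"].nunique() > 1:
        raise ValueError("trace_origins needs a single-period tensor; average first")
    countries = sorted(
        set(pr["country"]) | set(fl["exporter"]) | set(fl["importer"])
    )
    idx = {c: i for i, c in enumerate(countries)}
    n = len(countries)
    T = np.zeros((n, n))
    for _, row in fl.iterrows():
        T[idx[row["exporter"]], idx[row["importer"]]] += row["tonnes"]
    P = np.zeros(n)
    for _, row in pr.iterrows():
        P[idx[row["country"]]] += row["tonnes"]
    return countries, T, P


def trace_origins(
    t: TradeTensor,
    item: str,
    *,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> OriginMatrix:
    """Re-assign trade flows to their origin producers.

    Fixed-point model: let ``s_c = P_c + imports_c`` be country c's total
    supply and ``X[o, c]`` the tonnes of origin o inside that supply. Each
    country's exports carry its supply mix proportionally, so

        X[o, c] = P_c * 1[o == c] + sum_e (X[o, e] / s_e) * T[e, c]

    is iterated from ``X = diag(P)`` until the largest absolute change is
    below ``tol`` tonnes. The attribution to consumption is the supply mix
    scaled by apparent consumption ``s_c - exports_c``.

    Countries whose exports exceed their supply (a real artefact of
    mirror-reported trade data) have their export flows clipped
    proportionally, with a warning recorded in the result.
    """
    countries, T, P = _single_period_matrices(t, item)
    n = len(countries)
    warn_log: list[str] = []

    # proportional export clipping until exports fit within supply
    for _ in range(n + 1):
        supply = P + T.sum(axis=0)
        exports = T.sum(axis=1)
        bad = exports > supply * (1 + 1e-12)
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            scale = supply[i] / exports[i] if exports[i] > 0 else 0.0
            warn_log.append(
                f"{countries[i]}: exports {exports[i]:.6g} t exceed supply "
                f"{supply[i]:.6g} t; flows scaled by {scale:.6g}"
            )
            T[i, :] *= scale
        warnings.warn(warn_log[-1], stacklevel=2)

    supply = P + T.sum(axis=0)
    exports = T.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_s = np.where(supply > 0, 1.0 / supply, 0.0)

    X = np.diag(P).astype(float)
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        M = X * inv_s[np.newaxis, :]  # supply mix per holder country
        X_new = np.diag(P) + M @ T
        residual = float(np.abs(X_new - X).max())
        X = X_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"origin tracing did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} t)"
        )

    M = X * inv_s[np.newaxis, :]
    consumption = supply - exports
    attributed = (M * consumption[np.newaxis, :]).T  # [consumer, origin]
    attributed[attributed < 0] = 0.0
    return OriginMatrix(
        item=item,
        countries=countries,
        attributed=attributed,
        production=P,
        consumption=consumption,
        iterations=iteration,
        residual=residual,
        warnings=warn_log,
    )


def supplier_table(om: OriginMatrix, consumer: str) -> pd.DataFrame:
    """Origins of one consumer's supply, with consumption/production shares.

    One row per origin with positive attributed tonnage, including the
    consumer itself (domestic production). ``consumption_share`` is the
    origin's fraction of the consumer's attributed consumption;
    ``production_share`` is the attributed tonnage as a fraction of the
    origin's own production.
    """
    if consumer not in om.countries:
        raise KeyError(f"unknown consumer {consumer!r}")
    ci = om.countries.index(consumer)
    row = om.attributed[ci]
    total = row.sum()
    rows = []
    for oi, origin in enumerate(om.countries):
        tonnes = row[oi]
        if tonnes <= 0:
            continue
        prod = om.production[oi]
        rows.append(
            {
                "country": origin,
                "attributed_tonnes": tonnes,
                "consumption_share": tonnes / total if total > 0 else np.nan,
                "production_share": tonnes / prod if prod > 0 else np.nan,
            }
        )
    df = pd.DataFrame(
        rows, columns=["country", "attributed_tonnes", "consumption_share", "production_share"]
    )
    return df.sort_values(
        ["consumption_share", "country"], ascending=[False, True]
    ).reset_index(drop=True)


def major_suppliers(table: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Rows supplying at least ``threshold`` of consumption, largest first."""
    keep = table[table["consumption_share"] >= threshold]
    return keep.sort_values(
        ["consumption_share", "country"], ascending=[False, True]
    ).reset_index(drop=True)


def read_faostat_csv(path: str | Path) -> TradeTensor:
    """Read a FAOSTAT trade-matrix-dialect CSV into a TradeTensor.

    Expected columns: Reporter, Partner, Item, Element, Year, Unit, Value.
    'Export Quantity' rows become flows Reporter -> Partner; 'Production'
    rows become production totals for Reporter (Partner ignored). Units
    must be tonnes.
    """
    df = pd.read_csv(path)
    required = {"Reporter", "Partner", "Item", "Element", "Year", "Unit", "Value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not df["Unit"].isin(["tonnes", "t"]).all():
        raise ValueError(f"{path}: all units must be tonnes")
    exp = df[df["Element"] == "Export Quantity"]
    prod = df[df["Element"] == "Production"]
    flows = pd.DataFrame(
        {
            "year": exp["Year"].astype(int),
            "item": exp["Item"],
            "exporter": exp["Reporter"],
            "importer": exp["Partner"],
            "tonnes": exp["Value"].astype(float),
        }
    )
    production = pd.DataFrame(
        {
            "year": prod["Year"].astype(int),
            "item": prod["Item"],
            "country": prod["Reporter"],
            "tonnes": prod["Value"].astype(float),
        }
    )
    return TradeTensor(flows, production)
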