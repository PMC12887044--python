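"""Seeded generators for synthetic inputs with known ground truth.

These stand in for the real input families of the analysis — gridded crop
production/area surfaces, per-tonne environmental-intensity surfaces,
country partitions, bilateral trade networks, and species-range masks —
with the statistical structure the pipeline assumes: zero-inflated and
spatially autocorrelated crop surfaces, lognormal-like intensities, a
water-debt surface with mass on both sides of one, contiguous country
regions, re-export chains with known true origins, and blob-shaped ranges
with exactly known crop overlap.

Every generator is a pure function of its config: randomness comes from
one numpy Generator (PCG64) seeded from ``cfg.seed``, so identical configs
give identical outputs across runs and platforms. Spatial autocorrelation
is kernel-smoothed white noise (a Gaussian filter), which is cheap and
adequate for structure emulation; it is not a calibrated Gaussian random
field.
"""

from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .countries import CountryMask
from .grid import GridSpec, IndicatorKind, Layer, Semantics
from .species import IUCN_CATEGORIES, SpeciesRange
from .trade import TradeTensor, FLOW_COLS, PROD_COLS

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "gen_crop_surface",
    "gen_intensity_layers",
    "gen_country_partition",
    "gen_trade_network",
    "gen_species_ranges",
    "gen_known_hotspot_layer",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all generators; defaults are the study-sized conditions.

    zero_inflation is the fraction of cells with no crop (global crop
    rasters are mostly empty outside growing regions);
    autocorrelation_scale is the Gaussian smoothing sigma in cells;
    intensity_log_params gives (mean, sd) of log-values per indicator;
    wat_exceed_prob is the target fraction of water-debt values above one.
    """

    grid: GridSpec = GridSpec(100, 100)
    seed: int = 0
    zero_inflation: float = 0.5
    autocorrelation_scale: float = 3.0
    intensity_log_params: dict = field(
        default_factory=lambda: {
            IndicatorKind.GHG: (0.0, 1.0),
            IndicatorKind.LND: (-6.0, 1.5),
            IndicatorKind.Nit: (-8.0, 1.5),
            IndicatorKind.Pho: (-10.0, 1.5),
        }
    )
    wat_exceed_prob: float = 0.3
    n_countries: int = 6
    n_species: int = 30
    range_cells_min: int = 20
    range_cells_max: int = 400
    category_probs: dict = field(
        default_factory=lambda: {"CR": 0.2, "EN": 0.2, "VU": 0.2, "NT": 0.2, "LC": 0.2}
    )
    n_trade_countries: int = 8
    reexport_depth: int = 2
    flow_prob: float = 0.5
    production_scale: float = 1e5

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if not 0.0 <= self.wat_exceed_prob <= 1.0:
            raise ValueError("wat_exceed_prob must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator per named stream, derived from the seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SynthTruth:
    """Ground truth recorded at generation time for recovery tests."""

    origin_attribution: pd.DataFrame | None = None  # consumer x origin tonnes
    overlap_fractions: dict[str, float] = field(default_factory=dict)
    top_decile_cells: set[int] = field(default_factory=set)


def _smooth_standard_normal(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Kernel-smoothed white noise, re-standardised to mean 0, sd 1."""
    g = rng.standard_normal(shape)
    if sigma > 0:
        g = ndimage.gaussian_filter(g, sigma=sigma, mode="reflect")
    sd = g.std()
    if sd == 0:  # pragma: no cover - degenerate 1x1 grid
        return np.zeros(shape)
    return (g - g.mean()) / sd


def gen_crop_surface(cfg: SynthConfig, stream: str = "crop") -> tuple[Layer, Layer, Layer]:
    """Production (t), harvested area (ha), physical area (ha) surfaces.

    All three share a spatially clustered zero set covering a
    ``zero_inflation`` fraction of cells; positive values are lognormal
    over a smoothed field, so neighbouring cells are correlated. Distinct
    ``stream`` names give independent surfaces (e.g. one per crop).
    """
    if cfg.grid.nrows * cfg.grid.ncols < 1:
        raise ValueError("degenerate grid")
    rng = cfg.rng(stream)
    shape = cfg.grid.shape

    magnitude = _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale)
    presence = _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale)
    # threshold the presence field at its own empirical quantile so the
    # realised zero fraction tracks the target closely
    if cfg.zero_inflation >= 1.0:
        grown = np.zeros(shape, bool)
    elif cfg.zero_inflation <= 0.0:
        grown = np.ones(shape, bool)
    else:
        thr = np.quantile(presence, cfg.zero_inflation)
        grown = presence > thr

    production = np.where(grown, np.exp(3.0 + 1.2 * magnitude), 0.0)
    # yield (t/ha) varies smoothly and positively
    yld = np.exp(0.5 + 0.3 * _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale))
    harvested = production / yld
    # physical area <= harvested area (multi-cropping factor >= 1)
    multi = 1.0 + np.abs(0.3 * _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale))
    physical = harvested / multi

    valid = np.ones(shape, bool)
    return (
        Layer(cfg.grid, production, valid, Semantics.PRODUCTION_T),
        Layer(cfg.grid, harvested, valid, Semantics.HARVESTED_AREA_HA),
        Layer(cfg.grid, physical, valid, Semantics.PHYSICAL_AREA_HA),
    )


def gen_intensity_layers(
    cfg: SynthConfig, stream: str = "intensity"
) -> dict[IndicatorKind, Layer]:
    """Per-tonne intensity surfaces plus a water-debt surface.

    GHG/LND/Nit/Pho are strictly positive with log-values matching the
    configured (mean, sd) exactly over the grid; WAT is constructed so the
    fraction of cells exceeding one equals ``wat_exceed_prob`` (up to grid
    granularity).
    """
    rng = cfg.rng(stream)
    shape = cfg.grid.shape
    valid = np.ones(shape, bool)
    out: dict[IndicatorKind, Layer] = {}
    for kind, (log_mean, log_sd) in sorted(cfg.intensity_log_params.items()):
        g = _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale)
        out[kind] = Layer(
            cfg.grid, np.exp(log_mean + log_sd * g), valid, Semantics.INTENSITY_PER_T
        )
    w = _smooth_standard_normal(rng, shape, cfg.autocorrelation_scale)
    if cfg.wat_exceed_prob <= 0.0:
        wat = np.exp(w - w.max() - 1.0)  # everything at most e^-1 < 1
    elif cfg.wat_exceed_prob >= 1.0:
        wat = np.exp(w - w.min() + 1.0)
    else:
        # shift so the (1 - p) quantile of log-debt sits at zero
        wat = np.exp(w - np.quantile(w, 1.0 - cfg.wat_exceed_prob))
    out[IndicatorKind.WAT] = Layer(cfg.grid, wat, valid, Semantics.INTENSITY_PER_T)
    return out


_NEIGHBOURS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def gen_country_partition(cfg: SynthConfig) -> CountryMask:
    """Partition the grid into contiguous country regions by BFS growth.

    Multi-source breadth-first flood fill from random seed cells: every
    cell is assigned the region it is first reached from, so each region
    is 4-connected by construction.
    """
    nr, nc = cfg.grid.shape
    n_cells = nr * nc
    if cfg.n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    if cfg.n_countries > n_cells:
        raise ValueError(f"n_countries {cfg.n_countries} exceeds {n_cells} cells")
    rng = cfg.rng("countries")
    codes = np.full((nr, nc), -1, dtype=np.int64)
    seeds = rng.choice(n_cells, size=cfg.n_countries, replace=False)
    queue: deque[tuple[int, int, int]] = deque()
    for code, flat in enumerate(seeds, start=1):
        r, c = divmod(int(flat), nc)
        codes[r, c] = code
        queue.append((r, c, code))
    while queue:
        r, c, code = queue.popleft()
        nbrs = list(_NEIGHBOURS)
        rng.shuffle(nbrs)
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and codes[rr, cc] < 0:
                codes[rr, cc] = code
                queue.append((rr, cc, code))
    layer = Layer(
        cfg.grid, codes.astype(np.float64), np.ones((nr, nc), bool), Semantics.CATEGORY_CODE
    )
    registry = {i: f"C{i:02d}" for i in range(1, cfg.n_countries + 1)}
    return CountryMask(layer, registry)


def gen_trade_network(cfg: SynthConfig, item: str = "crop") -> tuple[TradeTensor, SynthTruth]:
    """Origin-first trade network with re-export chains and exact truth.

    Construction: countries split into exporters (produce, retain a share,
    ship parcels; import nothing) and consumers (produce for themselves
    and import; export nothing). A parcel travels directly or through a
    chain of dedicated pass-through hubs (zero production, all inflow
    forwarded to a single onward destination), with random depth up to
    ``reexport_depth``. Under proportional supply-mix tracing this layout
    is exactly origin-pure at every node — an exporter's supply is all its
    own production, a hub forwards its whole (known-origin) inflow to one
    destination, and a terminal consumer re-exports nothing — so tracing
    recovers the construction attribution exactly; that attribution is the
    stored truth. Production and consumption balance exactly.
    """
    n = cfg.n_trade_countries
    if n < 2:
        raise ValueError("need at least two trading countries")
    rng = cfg.rng("trade")
    countries = [f"P{i:02d}" for i in range(n)]
    exporters = countries[: n // 2]
    consumers = countries[n // 2 :]
    flows: list[tuple] = []
    production: dict[str, float] = {}
    attribution: dict[str, dict[str, float]] = {c: {} for c in countries}
    hub_counter = 0

    for c in consumers:
        own = float(cfg.production_scale * rng.lognormal(0.0, 0.5))
        production[c] = own
        attribution[c][c] = own  # consumers retain all own production

    for o in exporters:
        out_total = float(cfg.production_scale * rng.lognormal(0.0, 0.5))
        production[o] = out_total
        partners = [c for c in consumers if rng.random() < cfg.flow_prob]
        # shares: domestic retention plus one share per destination
        shares = rng.dirichlet(np.ones(len(partners) + 1))
        attribution[o][o] = float(shares[0]) * out_total
        for c, share in zip(partners, shares[1:]):
            q = float(share) * out_total
            if q <= 0.0:
                continue
            depth = int(rng.integers(0, cfg.reexport_depth + 1))
            chain = [o]
            for _ in range(depth):
                hub = f"H{hub_counter:03d}"
                hub_counter += 1
                chain.append(hub)
            chain.append(c)
            for a, b in zip(chain[:-1], chain[1:]):
                flows.append((-1, item, a, b, q))
            attribution[c][o] = attribution[c].get(o, 0.0) + q

    hubs = [f"H{i:03d}" for i in range(hub_counter)]
    all_countries = countries + hubs
    prod_rows = [(-1, item, c, production.get(c, 0.0)) for c in all_countries]
    # merge parallel flows on the same dyad (several parcels can share an
    # origin->hub edge only if hubs were reused; they are not, but origin->
    # consumer direct edges can repeat)
    fl = (
        pd.DataFrame(flows, columns=FLOW_COLS)
        .groupby(["year", "item", "exporter", "importer"], as_index=False)["tonnes"]
        .sum()
    )
    tensor = TradeTensor(fl[FLOW_COLS], pd.DataFrame(prod_rows, columns=PROD_COLS))
    truth = pd.DataFrame(0.0, index=all_countries, columns=all_countries)
    for consumer, origins in attribution.items():
        for origin, tonnes in origins.items():
            truth.loc[consumer, origin] = tonnes
    truth = truth.rename_axis(index="consumer", columns="origin")
    return tensor, SynthTruth(origin_attribution=truth)


def _grow_blob(
    rng: np.random.Generator, shape: tuple[int, int], size: int
) -> np.ndarray:
    """Random connected blob of ``size`` cells grown from a random seed."""
    nr, nc = shape
    mask = np.zeros(shape, bool)
    start = int(rng.integers(0, nr * nc))
    r, c = divmod(start, nc)
    mask[r, c] = True
    frontier = [(r, c)]
    count = 1
    while count < size and frontier:
        i = int(rng.integers(0, len(frontier)))
        r, c = frontier[i]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in _NEIGHBOURS
            if 0 <= r + dr < nr and 0 <= c + dc < nc and not mask[r + dr, c + dc]
        ]
        if not nbrs:
            frontier.pop(i)
            continue
        rr, cc = nbrs[int(rng.integers(0, len(nbrs)))]
        mask[rr, cc] = True
        frontier.append((rr, cc))
        count += 1
    return mask


def gen_species_ranges(
    cfg: SynthConfig, crop: Layer, min_area: float = 0.0
) -> tuple[list[SpeciesRange], SynthTruth]:
    """Blob-shaped species ranges with exact stored crop-overlap truth.

    Range sizes are uniform on [range_cells_min, range_cells_max]; Red
    List categories are drawn from ``category_probs``. The truth overlap
    for each species is the fraction of its range cells where ``crop`` is
    valid and strictly exceeds ``min_area``, counted directly at
    generation time.
    """
    if crop.spec != cfg.grid:
        raise ValueError("crop layer grid does not match config grid")
    rng = cfg.rng("species")
    cats = list(cfg.category_probs)
    probs = np.array([cfg.category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    producing = crop.valid & (crop.values > min_area)
    ranges: list[SpeciesRange] = []
    truth = SynthTruth()
    for i in range(cfg.n_species):
        size = int(rng.integers(cfg.range_cells_min, cfg.range_cells_max + 1))
        blob = _grow_blob(rng, cfg.grid.shape, size)
        category = cats[int(rng.choice(len(cats), p=probs))]
        mask_layer = Layer(
            cfg.grid, blob.astype(np.float64), np.ones(cfg.grid.shape, bool), Semantics.MASK
        )
        sp = SpeciesRange(f"sp{i:03d}", category, mask_layer)
        ranges.append(sp)
        truth.overlap_fractions[sp.species_id] = float(
            (blob & producing).sum() / blob.sum()
        )
    return ranges, truth


def gen_known_hotspot_layer(cfg: SynthConfig) -> tuple[Layer, SynthTruth]:
    """Layer of distinct values whose true top-decile cell set is known.

    Values are a random permutation of 1..n, so ranks are unambiguous and
    the top ``ceil(0.1 n)`` cells are recorded exactly.
    """
    rng = cfg.rng("hotspot")
    n = cfg.grid.nrows * cfg.grid.ncols
    values = rng.permutation(np.arange(1, n + 1)).astype(np.float64)
    k = int(np.ceil(0.1 * n))
    top = set(np.argsort(-values)[:k].tolist())
    layer = Layer(
        cfg.grid, values.reshape(cfg.grid.shape), np.ones(cfg.grid.shape, bool), Semantics.IMPACT
    )
    return layer, SynthTruth(top_decile_cells=top)
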