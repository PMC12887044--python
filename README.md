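# impact-atlas

Spatial environmental-impact assessment of crop production, built as a
tested, reusable pipeline. It answers three kinds of question about crops
such as wheat, sugar (cane + beet), oil palm and cocoa:

1. **Where are the environmental hotspots of a crop?** Per-cell impact
   layers are built by multiplying per-tonne intensity surfaces — GHG
   emissions (t CO₂e/t), land-use biodiversity loss (LND), nitrogen (Nit)
   and phosphorus (Pho) fertiliser impacts (all PDF·yr/t, Potentially
   Disappeared Fraction of species) — by dry-weight production per cell,
   then min–max normalized, classed low/medium/high at the 0.10/0.90
   empirical quantiles, and reduced to top-decile hotspot masks,
   dominant-indicator and summed-total composites, and bivariate
   (harvested area × species richness) maps. Water debt (WAT, years) is a
   sustainability ratio: it enters as the debt surface itself, filtered to
   its unsustainable part (WD > 1), never multiplied by production.
2. **Who really supplies a consumer country?** Bilateral trade flows are
   averaged over a year window and corrected for re-exports by tracing
   each traded tonne back to its producer: every country's exports carry
   the origin mix of its total supply `s_c = P_c + imports_c`, iterated to
   the fixed point `X[o,c] = P_c·1[o=c] + Σ_e (X[o,e]/s_e)·T[e,c]`. The
   resulting origin matrix gives attributed tonnes per (consumer, origin),
   from which supplier tables with a ≥ 5 % consumption-share cut are
   derived.
3. **Which threatened species sit in the producing areas?** Species range
   masks are stacked into richness maps, and each species' overlap
   fraction — the share of its range cells where crop physical area is
   positive — is computed and ranked within IUCN categories (CR/EN/VU).

A consumption module links products to crops with simple, exact
arithmetic (annual units × grams per unit → tonnes → share of supply),
and a seeded synthetic-data module generates every input family with
known ground truth, so the whole pipeline is testable end to end without
external downloads.

## Worked example

```python
from impact_atlas import (
    SynthConfig, ingredient_mass_tonnes, share_of_supply,
    trace_origins, supplier_table, major_suppliers,
)
from impact_atlas.synth import gen_trade_network

# product arithmetic: 12e9 biscuits a year at 4.4 g sugar each
sugar_t = ingredient_mass_tonnes(12e9, 4.4)
pct, raw = share_of_supply(sugar_t, 7_276_708)
print(f"{sugar_t:.0f} t of sugar = {pct}% of domestic supply")

# origin tracing on a synthetic network with re-export chains
tensor, truth = gen_trade_network(SynthConfig(seed=1))
om = trace_origins(tensor, "crop")
print(major_suppliers(supplier_table(om, "P05"), 0.05))
```

prints

```
52800 t of sugar = 0.7% of domestic supply
  country  attributed_tonnes  consumption_share  production_share
0     P05      188003.182247           0.892042          1.000000
1     P03       17074.203803           0.081014          0.120096
```

— the biscuit sugar tonnage and its 0.7 % share of supply, and the
origin-corrected major suppliers of consumer `P05`: mostly domestic, the
rest attributed to the true producing country even though its parcels may
have moved through re-export hubs (origins below the 5 % cut are in the
unfiltered table).

The full pipeline runs from one config via the CLI:

```bash
impact-atlas run --out out --seed 1            # all stages
impact-atlas hotspots --out out --seed 1       # one stage
impact-atlas synth --out fixtures --seed 1     # write a fixture directory
```

Each run writes class rasters, hotspot masks, composite maps, supplier
and origin-matrix CSVs, overlap and richness outputs, a consumption
table, and a `manifest.json` with a config hash; outputs are
byte-reproducible for a fixed config and seed.

## Layout

| module | contents |
| --- | --- |
| `impact_atlas.grid` | `GridSpec`, `Layer`, text-grid I/O, alignment, block aggregation |
| `impact_atlas.impacts` | dry-weight conversion, per-cell impact, WAT filter, sugar overlay, zero→NA |
| `impact_atlas.hotspots` | min–max normalization, 3-class quantile classification, top-decile masks, composites, bivariate classes |
| `impact_atlas.trade` | trade tensors, window averaging, sugar-item combining, origin tracing, supplier tables, FAOSTAT-dialect CSV reader |
| `impact_atlas.countries` | country masks, zonal sums, total/per-tonne country profiles |
| `impact_atlas.species` | range masks, richness, overlap fractions, harvest-in-range |
| `impact_atlas.consumption` | product→crop arithmetic with shipped UK biscuit defaults |
| `impact_atlas.synth` | seeded generators with ground truth for every input family |
| `impact_atlas.pipeline` / `impact_atlas.cli` | config, orchestration, manifest, `impact-atlas` CLI |

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
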