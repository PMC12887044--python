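"""End-to-end orchestration of the analysis stages from one config.

Stages and their dependency order:

  impacts (implicit)  -> hotspots, country
  trade               -> supplier tables (and the country list they imply)
  overlap             -> range/cropland overlap, richness, harvest-in-range
  consumption         -> product-level arithmetic

The pipeline is synth-backed here: every spatial and trade input is drawn
from the seeded generators, so a config plus seed fully determines every
output file (CSV outputs are byte-reproducible). Real rasters in the
package's text-grid format and FAOSTAT-dialect trade CSVs can be
substituted per input via config paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import consumption as cons
from . import hotspots as hs
from . import impacts as imp
from . import species as sp
from . import trade as tr
from .countries import country_profile
from .grid import GridSpec, IndicatorKind, write_raster
from .synth import SynthConfig, gen_country_partition, gen_crop_surface, \
    gen_intensity_layers, gen_species_ranges, gen_trade_network

__all__ = ["PipelineConfig", "ConfigError", "RunManifest", "run_pipeline"]

log = logging.getLogger("impact_atlas")

ALL_STAGES = ("hotspots", "trade", "country", "overlap", "consumption")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every failure."""


@dataclass
class PipelineConfig:
    """Everything a run needs, with the analysis constants as named keys."""

    output_dir: str = "out"
    seed: int = 0
    nrows: int = 100
    ncols: int = 100
    crops: tuple[str, ...] = ("wheat", "sugar", "oilpalm", "cocoa")
    q_low: float = 0.10
    q_high: float = 0.90
    supplier_threshold: float = 0.05
    wat_cutoff: float = 1.0
    min_area: float = 0.0
    years: tuple[int, int] = (2003, 2013)
    consumer: str = "P00"
    item: str = "crop"
    n_countries: int = 6
    n_species: int = 30
    n_trade_countries: int = 8
    reexport_depth: int = 2
    zero_inflation: float = 0.5
    trade_csv: str | None = None
    bivariate_bins: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("crops", "years"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        errors = []
        if not 0.0 < self.q_low < self.q_high < 1.0:
            errors.append(f"need 0 < q_low < q_high < 1, got {self.q_low}, {self.q_high}")
        if not 0.0 < self.supplier_threshold < 1.0:
            errors.append(f"supplier_threshold must be in (0, 1), got {self.supplier_threshold}")
        if self.nrows < 1 or self.ncols < 1:
            errors.append(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")
        if not 0.0 <= self.zero_inflation <= 1.0:
            errors.append(f"zero_inflation must be in [0, 1], got {self.zero_inflation}")
        if self.min_area < 0:
            errors.append(f"min_area must be >= 0, got {self.min_area}")
        unknown = [c for c in self.crops if c not in imp.DEFAULT_CROPS]
        if unknown:
            errors.append(f"unknown crops {unknown}; known: {sorted(imp.DEFAULT_CROPS)}")
        if self.years[1] < self.years[0]:
            errors.append(f"empty year window {self.years}")
        if self.trade_csv is not None and not Path(self.trade_csv).exists():
            errors.append(f"trade_csv does not exist: {self.trade_csv}")
        if errors:
            raise ConfigError("; ".join(errors))

    def synth(self) -> SynthConfig:
        return SynthConfig(
            grid=GridSpec(self.nrows, self.ncols),
            seed=self.seed,
            zero_inflation=self.zero_inflation,
            n_countries=self.n_countries,
            n_species=self.n_species,
            n_trade_countries=self.n_trade_countries,
            reexport_depth=self.reexport_depth,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """What a run produced: config hash, outputs per stage, warnings."""

    config_hash: str
    package_version: str
    outputs: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    durations_s: dict[str, float] = field(default_factory=dict)

    def add(self, stage: str, *paths: Path) -> None:
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def all_outputs_exist(self) -> bool:
        return all(Path(p).exists() for ps in self.outputs.values() for p in ps)


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _build_impact_sets(cfg: PipelineConfig) -> dict[str, dict]:
    """Synth production + intensities -> impact set per configured crop.

    Sugar is built by union-overlay of separately generated sugarcane and
    sugar-beet production and impact layers.
    """
    scfg = cfg.synth()
    out: dict[str, dict] = {}
    for crop_id in cfg.crops:
        spec = imp.DEFAULT_CROPS[crop_id]
        intensities = {
            k: v
            for k, v in gen_intensity_layers(scfg, stream=f"intensity:{crop_id}").items()
            if k in spec.available_indicators
        }
        if crop_id == "sugar":
            cane_prod, cane_harv, cane_phys = gen_crop_surface(scfg, stream="crop:sugarcane")
            beet_prod, beet_harv, beet_phys = gen_crop_surface(scfg, stream="crop:sugarbeet")
            cane_set = imp.build_impact_set(
                imp.DEFAULT_CROPS["sugarcane"], intensities, cane_prod, wat_cutoff=cfg.wat_cutoff
            )
            beet_set = imp.build_impact_set(
                imp.DEFAULT_CROPS["sugarbeet"], intensities, beet_prod, wat_cutoff=cfg.wat_cutoff
            )
            layers = {
                k: imp.merge_sum(cane_set[k], beet_set[k])
                for k in spec.available_indicators
            }
            # re-apply the water-debt rule: summing two debt surfaces can
            # only increase values, but filter defensively for config cutoffs
            if IndicatorKind.WAT in layers:
                layers[IndicatorKind.WAT] = imp.water_debt_filter(
                    layers[IndicatorKind.WAT], cfg.wat_cutoff
                )
            impact_set = imp.ImpactLayerSet(spec, layers, provenance="sugar union overlay")
            production = imp.merge_sum(cane_prod, beet_prod)
            harvested = imp.merge_sum(cane_harv, beet_harv)
            physical = imp.merge_sum(cane_phys, beet_phys)
        else:
            production, harvested, physical = gen_crop_surface(scfg, stream=f"crop:{crop_id}")
            impact_set = imp.build_impact_set(spec, intensities, production, wat_cutoff=cfg.wat_cutoff)
        out[crop_id] = {
            "impact_set": impact_set,
            "production": production,
            "harvested": harvested,
            "physical": physical,
        }
    return out


def _stage_hotspots(cfg: PipelineConfig, data: dict, outdir: Path, manifest: RunManifest) -> None:
    scfg = cfg.synth()
    summary_rows = []
    for crop_id, d in data.items():
        stack = hs.normalize_stack(d["impact_set"])
        total = hs.total_impact(stack)
        dominant = hs.dominant_indicator(stack)
        top = hs.top_decile_mask(total, 1.0 - cfg.q_high)
        for kind in stack.indicators():
            cl = hs.classify_three(stack.layers[kind], cfg.q_low, cfg.q_high)
            counts = cl.counts()
            summary_rows.append(
                {"crop": crop_id, "indicator": str(kind), "n_valid": cl.layer.n_valid,
                 "n_low": counts[hs.LOW], "n_medium": counts[hs.MEDIUM], "n_high": counts[hs.HIGH]}
            )
            p = outdir / f"classes_{crop_id}_{kind}.grid"
            write_raster(cl.layer, p)
            manifest.add("hotspots", p)
        # bivariate harvested area x species richness
        ranges, _ = gen_species_ranges(scfg, d["physical"], cfg.min_area)
        rich = sp.richness(ranges)
        bi = hs.bivariate_classify(d["harvested"], rich, cfg.bivariate_bins)
        for name, layer in (
            ("total", total), ("dominant", dominant), ("top_decile", top), ("bivariate", bi.layer)
        ):
            p = outdir / f"{name}_{crop_id}.grid"
            write_raster(layer, p)
            manifest.add("hotspots", p)
    p = _write_csv(pd.DataFrame(summary_rows), outdir / "class_summary.csv")
    manifest.add("hotspots", p)


def _stage_trade(cfg: PipelineConfig, outdir: Path, manifest: RunManifest) -> tr.OriginMatrix:
    if cfg.trade_csv:
        tensor = tr.read_faostat_csv(cfg.trade_csv)
        tensor = tr.average_flows(tensor, cfg.years)
    else:
        tensor, _ = gen_trade_network(cfg.synth(), item=cfg.item)
    tensor = tr.combine_sugar_items(tensor)
    om = tr.trace_origins(tensor, cfg.item)
    manifest.warnings.extend(om.warnings)
    table = tr.supplier_table(om, cfg.consumer)
    majors = tr.major_suppliers(table, cfg.supplier_threshold)
    p1 = _write_csv(table, outdir / "suppliers_all.csv")
    p2 = _write_csv(majors, outdir / "suppliers_major.csv")
    p3 = _write_csv(
        om.as_frame().reset_index(), outdir / "origin_matrix.csv"
    )
    manifest.add("trade", p1, p2, p3)
    return om


def _stage_country(cfg: PipelineConfig, data: dict, outdir: Path, manifest: RunManifest) -> None:
    mask = gen_country_partition(cfg.synth())
    frames = []
    for crop_id, d in data.items():
        stack = hs.normalize_stack(d["impact_set"])
        frames.append(country_profile(stack, mask, d["production"]))
    p = _write_csv(pd.concat(frames, ignore_index=True), outdir / "country_impacts.csv")
    manifest.add("country", p)


def _stage_overlap(cfg: PipelineConfig, data: dict, outdir: Path, manifest: RunManifest) -> None:
    scfg = cfg.synth()
    first_crop = next(iter(data))
    physical = data[first_crop]["physical"]
    ranges, _ = gen_species_ranges(scfg, physical, cfg.min_area)
    results = [sp.overlap_fraction(r, physical, cfg.min_area) for r in ranges]
    ranked = sp.rank_by_overlap(results)
    p1 = _write_csv(ranked, outdir / "overlap.csv")
    rich = sp.richness(ranges)
    p2 = outdir / "richness.grid"
    write_raster(rich, p2)
    # harvest within the first species' range (red-squirrel-style case map)
    hir = sp.harvest_in_range(data[first_crop]["harvested"], ranges[0])
    p3 = outdir / f"harvest_in_range_{ranges[0].species_id}.grid"
    write_raster(hir, p3)
    manifest.add("overlap", p1, p2, p3)


def _stage_consumption(cfg: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    rows = cons.consumption_table()
    p = _write_csv(pd.DataFrame(rows), outdir / "consumption.csv")
    manifest.add("consumption", p)


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> RunManifest:
    """Execute the requested stages in dependency order; write a manifest."""
    cfg.validate()
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise ConfigError(f"unknown stages {bad}; known: {list(ALL_STAGES)}")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.metadata import version
        pkg_version = version("impact-atlas")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    manifest = RunManifest(config_hash=cfg.digest(), package_version=pkg_version)

    need_impacts = any(s in stages for s in ("hotspots", "country", "overlap"))
    data = _build_impact_sets(cfg) if need_impacts else {}

    stage_fns = {
        "hotspots": lambda: _stage_hotspots(cfg, data, outdir, manifest),
        "trade": lambda: _stage_trade(cfg, outdir, manifest),
        "country": lambda: _stage_country(cfg, data, outdir, manifest),
        "overlap": lambda: _stage_overlap(cfg, data, outdir, manifest),
        "consumption": lambda: _stage_consumption(cfg, outdir, manifest),
    }
    for stage in ALL_STAGES:  # fixed dependency order
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        stage_fns[stage]()
        dt = time.perf_counter() - t0
        manifest.durations_s[stage] = round(dt, 3)
        log.info("stage %s: done in %.2fs", stage, dt)
    manifest.add("manifest", outdir / "manifest.json")
    manifest.write(outdir / "manifest.json")
    return manifest
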