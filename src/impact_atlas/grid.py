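"""Raster data model, text-grid I/O, alignment checks and block resampling.

Every gridded quantity in the pipeline — production surfaces, per-tonne
intensity surfaces, impact layers, country masks, species-range masks,
richness counts — is carried as a :class:`Layer`: a dense 2-D float array
plus an explicit boolean validity mask. Grids are row-major and north-up:
row 0 is the top row, indices are 0-based, and cell (r, c) covers the
half-open box
``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]``
where ``s`` is the cell size.

Real-world rasters (GeoTIFF etc.) must be converted to the package's
plain-text grid format as a preprocessing step; no reprojection engine is
provided, and synthetic grids are treated as abstract equal-area grids.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "Semantics",
    "IndicatorKind",
    "Layer",
    "AlignmentError",
    "GridFormatError",
    "read_raster",
    "write_raster",
    "aggregate_to",
    "assert_aligned",
]

#: nodata sentinel used by the text grid format when writing
DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two layers that must share a grid do not."""


class GridFormatError(ValueError):
    """A grid file could not be parsed."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    Two specs are *aligned* iff all six fields compare equal; every
    cellwise operation in the package requires aligned inputs.
    """

    nrows: int
    ncols: int
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "synthetic-equal-area"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other


class Semantics(str, enum.Enum):
    """What the values in a layer mean; drives validation rules."""

    HARVESTED_AREA_HA = "harvested_area_ha"
    PHYSICAL_AREA_HA = "physical_area_ha"
    PRODUCTION_T = "production_t"
    DRY_PRODUCTION_T = "dry_production_t"
    INTENSITY_PER_T = "intensity_per_t"
    IMPACT = "impact"
    NORMALIZED_IMPACT = "normalized_impact"
    RICHNESS_COUNT = "richness_count"
    CATEGORY_CODE = "category_code"
    MASK = "mask"


#: semantics whose valid values must be non-negative
_NONNEGATIVE = {
    Semantics.HARVESTED_AREA_HA,
    Semantics.PHYSICAL_AREA_HA,
    Semantics.PRODUCTION_T,
    Semantics.DRY_PRODUCTION_T,
    Semantics.RICHNESS_COUNT,
}


class IndicatorKind(enum.IntEnum):
    """The five environmental-impact indicators, in canonical order.

    GHG — greenhouse-gas emissions (t CO2e / t crop);
    LND — occupational land-use biodiversity impact (PDF·yr / t);
    Nit — nitrogen-fertiliser impact on marine species (PDF·yr / t);
    Pho — phosphorus-fertiliser impact on freshwater fish (PDF·yr / t);
    WAT — water debt (years; a sustainability ratio, not multiplied by
    production).

    The integer order is total and fixed; it is the tie-break everywhere
    a single indicator must be picked from equals.
    """

    GHG = 0
    LND = 1
    Nit = 2
    Pho = 3
    WAT = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class Layer:
    """A 2-D grid of values with an explicit missing-data mask.

    ``values`` where ``valid`` is False are ignored by every operation;
    they are stored as-is but carry no meaning.
    """

    spec: GridSpec
    values: np.ndarray
    valid: np.ndarray
    semantics: Semantics = Semantics.IMPACT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.spec.shape}"
            )
        if self.valid.shape != self.spec.shape:
            raise ValueError(
                f"valid shape {self.valid.shape} != grid {self.spec.shape}"
            )
        if isinstance(self.semantics, str):
            self.semantics = Semantics(self.semantics)
        self._check_semantics()

    def _check_semantics(self) -> None:
        vals = self.values[self.valid]
        if vals.size == 0:
            return
        if self.semantics in _NONNEGATIVE and np.any(vals < 0):
            raise ValueError(f"{self.semantics.value} layer has negative valid values")
        if self.semantics is Semantics.NORMALIZED_IMPACT and (
            np.any(vals < 0) or np.any(vals > 1)
        ):
            raise ValueError("normalized_impact layer has valid values outside [0, 1]")

    # -- constructors ------------------------------------------------------

    @classmethod
    def full(
        cls,
        spec: GridSpec,
        value: float = 0.0,
        semantics: Semantics = Semantics.IMPACT,
    ) -> "Layer":
        """All-valid constant layer."""
        return cls(
            spec,
            np.full(spec.shape, value, dtype=np.float64),
            np.ones(spec.shape, dtype=bool),
            semantics,
        )

    @classmethod
    def from_values(
        cls,
        values: np.ndarray | Sequence[Sequence[float]],
        valid: np.ndarray | None = None,
        semantics: Semantics = Semantics.IMPACT,
        spec: GridSpec | None = None,
    ) -> "Layer":
        """Build a layer from an array; NaN cells become invalid."""
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("layer values must be 2-D")
        if spec is None:
            spec = GridSpec(nrows=arr.shape[0], ncols=arr.shape[1])
        if valid is None:
            valid = ~np.isnan(arr)
        arr = np.where(np.asarray(valid, bool), arr, 0.0)
        return cls(spec, arr, np.asarray(valid, bool), semantics)

    # -- views -------------------------------------------------------------

    def valid_values(self) -> np.ndarray:
        """Flat array of the values on valid cells."""
        return self.values[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def masked(self) -> np.ndarray:
        """values with invalid cells as NaN (a copy)."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def with_(self, **kwargs) -> "Layer":
        """Shallow functional update (values/valid/semantics/spec)."""
        fields = dict(
            spec=self.spec, values=self.values, valid=self.valid, semantics=self.semantics
        )
        fields.update(kwargs)
        return Layer(**fields)

    def equals(self, other: "Layer", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Equality on (spec, valid, values restricted to valid cells)."""
        if self.spec != other.spec or self.semantics != other.semantics:
            return False
        if not np.array_equal(self.valid, other.valid):
            return False
        a, b = self.values[self.valid], other.values[other.valid]
        if rtol == 0.0 and atol == 0.0:
            return bool(np.array_equal(a, b))
        return bool(np.allclose(a, b, rtol=rtol, atol=atol))


# ---------------------------------------------------------------------------
# text-grid I/O
#
# Format (plain text, whitespace separated):
#   line 1: nrows ncols cell_size origin_x origin_y nodata
#   line 2: semantics token
#   then nrows lines of ncols numbers; nodata marks invalid cells.
# ---------------------------------------------------------------------------


def write_raster(layer: Layer, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a layer to the package's plain-text grid format.

    Invalid cells are stored as ``nodata``. If a valid cell happens to hold
    the nodata value exactly, a different sentinel must be chosen by the
    caller (an error is raised rather than silently corrupting the mask).
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if np.any(layer.values[layer.valid] == nodata):
        raise ValueError(
            f"a valid cell holds the nodata sentinel {nodata}; choose another sentinel"
        )
    body = np.where(layer.valid, layer.values, nodata)
    s = layer.spec
    try:
        with open(path, "w") as fh:
            fh.write(
                f"{int(s.nrows)} {int(s.ncols)} {float(s.cell_size)!r} "
                f"{float(s.origin_x)!r} {float(s.origin_y)!r} {float(nodata)!r}\n"
            )
            fh.write(f"{layer.semantics.value}\n")
            for row in body:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    except OSError as exc:  # pragma: no cover - OS specific
        raise IOError(f"cannot write raster to {path}: {exc}") from exc


def read_raster(path: str | Path) -> Layer:
    """Read a layer from the plain-text grid format written by write_raster."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    try:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 6:
                raise GridFormatError(
                    f"{path}: header must be 'nrows ncols cell_size origin_x origin_y nodata'"
                )
            nrows, ncols = int(header[0]), int(header[1])
            cell_size, origin_x, origin_y, nodata = map(float, header[2:])
            sem_token = fh.readline().strip()
            try:
                semantics = Semantics(sem_token)
            except ValueError as exc:
                raise GridFormatError(f"{path}: unknown semantics '{sem_token}'") from exc
            data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    except OSError as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    if data.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: body shape {data.shape} does not match header {(nrows, ncols)}"
        )
    spec = GridSpec(nrows, ncols, cell_size, origin_x, origin_y)
    valid = data != nodata
    values = np.where(valid, data, 0.0)
    return Layer(spec, values, valid, semantics)


# ---------------------------------------------------------------------------
# alignment and resampling
# ---------------------------------------------------------------------------

_SPEC_FIELDS = ("nrows", "ncols", "cell_size", "origin_x", "origin_y", "crs_id")


def assert_aligned(layers: Iterable[Layer]) -> None:
    """Raise AlignmentError naming the first differing GridSpec field."""
    layers = list(layers)
    if not layers:
        raise ValueError("assert_aligned requires at least one layer")
    ref = layers[0].spec
    for i, layer in enumerate(layers[1:], start=1):
        if layer.spec != ref:
            for f in _SPEC_FIELDS:
                if getattr(layer.spec, f) != getattr(ref, f):
                    raise AlignmentError(
                        f"layer {i} misaligned with layer 0: {f} "
                        f"{getattr(layer.spec, f)!r} != {getattr(ref, f)!r}"
                    )
            raise AlignmentError(f"layer {i} misaligned with layer 0")


def aggregate_to(
    layer: Layer,
    factor: int,
    mode: str = "sum",
    *,
    pad: bool = False,
) -> Layer:
    """Block-aggregate a layer by an integer factor.

    Each coarse cell combines its ``factor**2`` fine cells using only the
    valid ones; a coarse cell with no valid children is invalid. ``sum``
    conserves the total of valid values and is the right statistic for
    extensive quantities (areas, tonnes, impact totals); ``mean`` is for
    intensive ones (per-tonne intensities, richness when coarsening).

    ``factor`` must divide both grid dimensions unless ``pad=True``, in
    which case the grid is padded on the bottom/right with invalid cells.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    nr, nc = layer.spec.shape
    if (nr % factor or nc % factor) and not pad:
        raise ValueError(
            f"factor {factor} does not divide grid {nr}x{nc}; pass pad=True to pad"
        )
    values, valid = layer.values, layer.valid
    if nr % factor or nc % factor:
        pr = (-nr) % factor
        pc = (-nc) % factor
        values = np.pad(values, ((0, pr), (0, pc)))
        valid = np.pad(valid, ((0, pr), (0, pc)))
        nr, nc = values.shape

    R, C = nr // factor, nc // factor
    v = np.where(valid, values, 0.0).reshape(R, factor, C, factor)
    m = valid.reshape(R, factor, C, factor)
    sums = v.sum(axis=(1, 3))
    counts = m.sum(axis=(1, 3))
    out_valid = counts > 0
    if mode == "sum":
        out = sums
    else:
        out = np.divide(sums, counts, out=np.zeros_like(sums), where=out_valid)
    out[~out_valid] = 0.0
    s = layer.spec
    new_spec = replace(
        s, nrows=R, ncols=C, cell_size=s.cell_size * factor
    )
    return Layer(new_spec, out, out_valid, layer.semantics)
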