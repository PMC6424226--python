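"""LV perfusion polar maps: data model, file I/O, CFR, relative images, quadrants.

The left-ventricular myocardium is sampled on a fixed polar ("bullseye")
grid of 1,344 pixels — 21 rings from apex to base, 64 angular sectors per
ring, with angle 0 at the anterior–septal junction proceeding
counterclockwise viewed from the apex.  Each pixel carries absolute rest
and stress perfusion in cc/min/g plus a validity flag (inside the LV and
quantifiable).  All downstream severity scoring operates on this grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyMapError, GeometryError, ParseError, ValidationError

#: Total number of LV pixels on the polar grid.
LV_PIXEL_COUNT = 1344

#: Ordered quadrant labels: contiguous angular sectors starting at angle 0.
QUADRANT_NAMES = ("anterior", "septal", "inferior", "lateral")

#: Default quadrant -> coronary artery attribution (configurable).
DEFAULT_ARTERY_MAP = {
    "anterior": "LAD",
    "septal": "LAD",
    "inferior": "RCA",
    "lateral": "LCx",
}

CSV_COLUMNS = ("ring", "sector", "rest", "stress", "valid")


@dataclass(frozen=True)
class PolarGeometry:
    """Ring/sector layout of the polar grid.

    ``n_rings * n_sectors`` must equal the fixed LV pixel count; pixels are
    indexed ring-major (ring 0 = apex, sector 0 at the anterior–septal
    junction).
    """

    n_rings: int = 21
    n_sectors: int = 64

    def __post_init__(self) -> None:
        if self.n_rings < 1 or self.n_sectors < 1:
            raise GeometryError("ring and sector counts must be positive")
        if self.n_rings * self.n_sectors != LV_PIXEL_COUNT:
            raise GeometryError(
                f"geometry {self.n_rings}x{self.n_sectors} has "
                f"{self.n_rings * self.n_sectors} pixels; expected {LV_PIXEL_COUNT}"
            )

    @property
    def n_pixels(self) -> int:
        return self.n_rings * self.n_sectors

    def rings_sectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Ring and sector index of every pixel in ring-major order."""
        idx = np.arange(self.n_pixels)
        return idx // self.n_sectors, idx % self.n_sectors


DEFAULT_GEOMETRY = PolarGeometry()


@dataclass
class PerfusionPolarMap:
    """Rest and stress absolute perfusion (cc/min/g) on the LV polar grid."""

    rest: np.ndarray
    stress: np.ndarray
    valid_mask: np.ndarray
    geometry: PolarGeometry = field(default_factory=PolarGeometry)

    def __post_init__(self) -> None:
        self.rest = np.asarray(self.rest, dtype=float).ravel()
        self.stress = np.asarray(self.stress, dtype=float).ravel()
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).ravel()
        n = self.geometry.n_pixels
        for name, arr in (("rest", self.rest), ("stress", self.stress),
                          ("valid_mask", self.valid_mask)):
            if arr.size != n:
                raise GeometryError(f"{name} has {arr.size} pixels; expected {n}")
        for name, arr in (("rest", self.rest), ("stress", self.stress)):
            vals = arr[self.valid_mask]
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"{name} has non-finite values on valid pixels")
            if np.any(vals < 0):
                raise ValidationError(f"{name} has negative perfusion on valid pixels")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def grid(self, component: str) -> np.ndarray:
        """Return one component reshaped to (n_rings, n_sectors)."""
        arr = getattr(self, component)
        return arr.reshape(self.geometry.n_rings, self.geometry.n_sectors)


@dataclass
class CFRMap:
    """Per-pixel coronary flow reserve (stress/rest, dimensionless)."""

    values: np.ndarray
    valid_mask: np.ndarray
    geometry: PolarGeometry = field(default_factory=PolarGeometry)
    cap: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).ravel()
        vals = self.values[self.valid_mask]
        if np.any(vals < 0) or np.any(vals > self.cap):
            raise ValidationError("CFR values outside [0, cap] on valid pixels")


@dataclass(frozen=True)
class QuadrantPartition:
    """Pixel -> quadrant assignment plus quadrant -> artery attribution."""

    labels: np.ndarray  # per-pixel quadrant index into QUADRANT_NAMES
    geometry: PolarGeometry
    artery_map: dict = field(default_factory=lambda: dict(DEFAULT_ARTERY_MAP))

    def pixels_in(self, quadrant: str) -> np.ndarray:
        return np.flatnonzero(self.labels == QUADRANT_NAMES.index(quadrant))

    def artery_of(self, quadrant: str) -> str:
        return self.artery_map[quadrant]


def compute_cfr(pmap: PerfusionPolarMap, rest_floor: float = 0.1,
                cfr_cap: float = 10.0) -> CFRMap:
    """Per-pixel CFR = stress / max(rest, rest_floor), clipped to [0, cfr_cap].

    The rest floor (default 0.1 cc/min/g, below physiologic resting flow)
    prevents division blow-up on near-zero rest pixels; the cap bounds the
    dynamic range.  Invalid pixels propagate unchanged in the mask.
    """
    if rest_floor <= 0:
        raise ValidationError("rest_floor must be positive")
    cfr = pmap.stress / np.maximum(pmap.rest, rest_floor)
    cfr = np.clip(cfr, 0.0, cfr_cap)
    return CFRMap(values=cfr, valid_mask=pmap.valid_mask.copy(),
                  geometry=pmap.geometry, cap=cfr_cap)


def relative_map(values: np.ndarray, valid_mask: np.ndarray,
                 top_fraction: float = 0.02) -> np.ndarray:
    """Express a perfusion component as percent of its robust maximum.

    The maximum is the mean of the hottest ``top_fraction`` of valid pixels
    (default hottest 2%), so a single noisy pixel cannot dominate the
    normalization.  Values above the robust maximum exceed 100%.  Invalid
    pixels are returned as NaN.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    values = np.asarray(values, dtype=float).ravel()
    valid_mask = np.asarray(valid_mask, dtype=bool).ravel()
    vals = values[valid_mask]
    if vals.size == 0:
        raise EmptyMapError("relative_map needs at least one valid pixel")
    n_top = max(1, math.ceil(top_fraction * vals.size))
    robust_max = float(np.sort(vals)[-n_top:].mean())
    if robust_max <= 0:
        raise ValidationError("robust maximum is not positive; map has no signal")
    out = np.full(values.shape, np.nan)
    out[valid_mask] = 100.0 * values[valid_mask] / robust_max
    return out


def quadrant_partition(geometry: PolarGeometry = DEFAULT_GEOMETRY,
                       artery_map: dict | None = None) -> QuadrantPartition:
    """Split the grid into four equal contiguous angular quadrants.

    Quadrant k covers sectors [k*S/4, (k+1)*S/4) in the fixed order
    anterior, septal, inferior, lateral; sizes differ by at most one pixel
    when the sector count is not divisible by four.  Deterministic.
    """
    _, sectors = geometry.rings_sectors()
    # np.array_split keeps sizes within +/-1 for non-divisible sector counts
    bounds = np.cumsum([len(c) for c in np.array_split(np.arange(geometry.n_sectors), 4)])
    labels = np.searchsorted(bounds, sectors, side="right")
    return QuadrantPartition(labels=labels, geometry=geometry,
                             artery_map=dict(artery_map or DEFAULT_ARTERY_MAP))


# ---------------------------------------------------------------------------
# File formats.  CSV dialect: header `ring,sector,rest,stress,valid`, one row
# per pixel, 1,344 data rows, UTF-8, '.' decimal.  JSON: object with
# `geometry`, `rest`, `stress`, `valid` arrays in ring-major order.
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if str(path).endswith(".json") else "csv"


def read_polar_map(path, fmt: str | None = None) -> PerfusionPolarMap:
    """Read a perfusion polar map from the documented CSV or JSON dialect."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # malformed CSV
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        if len(df) != LV_PIXEL_COUNT:
            raise GeometryError(
                f"{path}: {len(df)} pixel rows; expected {LV_PIXEL_COUNT}")
        n_rings = int(df["ring"].max()) + 1
        n_sectors = int(df["sector"].max()) + 1
        geometry = PolarGeometry(n_rings=n_rings, n_sectors=n_sectors)
        order = np.lexsort((df["sector"].to_numpy(), df["ring"].to_numpy()))
        df = df.iloc[order]
        expect_r, expect_s = geometry.rings_sectors()
        if not (np.array_equal(df["ring"].to_numpy(), expect_r)
                and np.array_equal(df["sector"].to_numpy(), expect_s)):
            raise ParseError(f"{path}: ring/sector indices do not tile the grid")
        return PerfusionPolarMap(
            rest=df["rest"].to_numpy(float),
            stress=df["stress"].to_numpy(float),
            valid_mask=df["valid"].to_numpy().astype(bool),
            geometry=geometry,
        )
    if fmt == "json":
        try:
            with open(path, encoding="utf-8") as fh:
                obj = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        try:
            geometry = PolarGeometry(n_rings=int(obj["geometry"]["n_rings"]),
                                     n_sectors=int(obj["geometry"]["n_sectors"]))
            rest, stress, valid = obj["rest"], obj["stress"], obj["valid"]
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: missing field {exc}") from exc
        if len(rest) != LV_PIXEL_COUNT:
            raise GeometryError(
                f"{path}: {len(rest)} pixels; expected {LV_PIXEL_COUNT}")
        return PerfusionPolarMap(rest=np.asarray(rest), stress=np.asarray(stress),
                                 valid_mask=np.asarray(valid), geometry=geometry)
    raise ParseError(f"unknown polar-map format {fmt!r}")


def write_polar_map(pmap: PerfusionPolarMap, path, fmt: str | None = None,
                    extra_columns: dict | None = None) -> None:
    """Write a map in the CSV (default) or JSON dialect; round-trips exactly.

    ``extra_columns`` appends per-pixel columns (e.g. a CFC ``category``)
    to the CSV dialect.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        rings, sectors = pmap.geometry.rings_sectors()
        df = pd.DataFrame({
            "ring": rings,
            "sector": sectors,
            "rest": pmap.rest,
            "stress": pmap.stress,
            "valid": pmap.valid_mask.astype(int),
        })
        for name, col in (extra_columns or {}).items():
            df[name] = np.asarray(col).ravel()
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        obj = {
            "geometry": {"n_rings": pmap.geometry.n_rings,
                         "n_sectors": pmap.geometry.n_sectors},
            "rest": pmap.rest.tolist(),
            "stress": pmap.stress.tolist(),
            "valid": pmap.valid_mask.astype(int).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)
    else:
        raise ParseError(f"unknown polar-map format {fmt!r}")
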