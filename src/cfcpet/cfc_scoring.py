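"""Coronary flow capacity (CFC) scoring of LV perfusion maps.

Each pixel is placed into one of five ordered severity categories by
*combining* its coronary flow reserve (CFR) and absolute stress perfusion:
the pixel is ranked independently on a CFR band scale and on a stress-flow
band scale, and the assigned category is the MILDER of the two ranks.  The
most severe category therefore requires BOTH CFR <= 1.27 AND stress
perfusion <= 0.83 cc/min/g, and a pixel that is normal on either metric is
normal overall — high stress flow "rescues" a low CFR caused by high
resting perfusion.

Scan-level size–severity metrics derived from the category map (percent of
LV per category, presence/extent flags, minimum quadrant averages,
relative-defect sizes) are the covariates used by the outcome models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import GeometryError, ValidationError
from .polar_map import (
    CFRMap,
    PerfusionPolarMap,
    QuadrantPartition,
    QUADRANT_NAMES,
    quadrant_partition,
    relative_map,
)

#: Category names ordered from most severe (index 0) to normal (index 4),
#: with the conventional map colors.
CATEGORY_NAMES = ("severe", "moderate", "mild", "minimal", "normal")
CATEGORY_COLORS = ("blue", "green", "yellow", "orange", "red")

#: Normative severe-band ceilings: CFR <= 1.27 AND stress <= 0.83 cc/min/g.
SEVERE_CFR_CEILING = 1.27
SEVERE_STRESS_CEILING = 0.83

#: Percent-of-LV cutoffs for the scan-level extent flags (strict inequalities).
MODERATE_EXTENT_CUTOFF = 15.0
MILD_EXTENT_CUTOFF = 15.0

#: Relative-defect cutoff: pixels below this percent of the robust maximum.
RELATIVE_DEFECT_CUTOFF = 60.0


@dataclass(frozen=True)
class CFCThresholds:
    """Band ceilings per metric for the five CFC categories.

    ``cfr_ceilings[i]`` / ``stress_ceilings[i]`` are the inclusive upper
    bounds of band ``i`` on each metric (band 4 is unbounded).  Only the
    severe boundary (1.27, 0.83) is normative; the intermediate ceilings
    are configuration with documented defaults.
    """

    cfr_ceilings: tuple = (1.27, 1.74, 2.38, 2.90, math.inf)
    stress_ceilings: tuple = (0.83, 1.12, 1.76, 2.17, math.inf)

    def __post_init__(self) -> None:
        for name, bounds in (("cfr_ceilings", self.cfr_ceilings),
                             ("stress_ceilings", self.stress_ceilings)):
            if len(bounds) != len(CATEGORY_NAMES):
                raise ValidationError(f"{name} must have exactly "
                                      f"{len(CATEGORY_NAMES)} entries")
            if not all(a < b for a, b in zip(bounds, bounds[1:])):
                raise ValidationError(f"{name} must be strictly increasing")
            if not math.isinf(bounds[-1]):
                raise ValidationError(f"{name} must be unbounded in the last band")

    @classmethod
    def from_dict(cls, obj: dict) -> "CFCThresholds":
        def _band(vals):
            vals = [math.inf if v in (None, "inf", ".inf") else float(v) for v in vals]
            return tuple(vals)
        return cls(cfr_ceilings=_band(obj["cfr_ceilings"]),
                   stress_ceilings=_band(obj["stress_ceilings"]))

    def to_dict(self) -> dict:
        conv = lambda v: None if math.isinf(v) else v
        return {"cfr_ceilings": [conv(v) for v in self.cfr_ceilings],
                "stress_ceilings": [conv(v) for v in self.stress_ceilings]}


DEFAULT_THRESHOLDS = CFCThresholds()


@dataclass
class CFCResult:
    """Per-pixel CFC categories plus the scan-level size–severity metrics.

    ``categories`` holds the per-pixel category index (−1 on invalid
    pixels); ``percent_lv[i]`` is the percent of valid LV pixels in
    category ``i`` and sums to 100.  ``mqa`` maps metric name to
    ``(minimum quadrant average, quadrant)``; the relative-defect fields
    give the percent of LV below the 60%-of-maximum cutoff on the relative
    rest and stress images.  MQA and defect fields are ``None`` until a
    full scan scoring fills them in.
    """

    categories: np.ndarray
    percent_lv: np.ndarray
    thresholds: CFCThresholds = field(default_factory=CFCThresholds)
    flags: dict | None = None
    mqa: dict | None = None
    relative_rest_defect_percent: float | None = None
    relative_stress_defect_percent: float | None = None

    @property
    def severe_percent(self) -> float:
        return float(self.percent_lv[0])

    def to_dict(self) -> dict:
        return {
            "percent_lv": {name: float(p) for name, p
                           in zip(CATEGORY_NAMES, self.percent_lv)},
            "severe_percent": self.severe_percent,
            "flags": self.flags,
            "mqa": self.mqa,
            "relative_rest_defect_percent": self.relative_rest_defect_percent,
            "relative_stress_defect_percent": self.relative_stress_defect_percent,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _band_rank(values: np.ndarray, ceilings: tuple) -> np.ndarray:
    """Index of the first band whose inclusive ceiling contains each value."""
    finite = np.asarray(ceilings[:-1], dtype=float)
    # side='left': a value exactly at a ceiling belongs to that band ("<=")
    return np.searchsorted(finite, np.asarray(values, dtype=float), side="left")


def classify_pixel(cfr: float, stress: float,
                   thresholds: CFCThresholds = DEFAULT_THRESHOLDS) -> int:
    """CFC category of one pixel: the milder of its CFR and stress band ranks.

    Returns the category index (0 = severe ... 4 = normal).  Severe
    requires both metrics within their severe band; a pixel normal on
    either metric is normal overall.
    """
    if cfr < 0 or stress < 0:
        raise ValidationError("cfr and stress must be non-negative")
    rank_cfr = int(_band_rank(np.array([cfr]), thresholds.cfr_ceilings)[0])
    rank_stress = int(_band_rank(np.array([stress]), thresholds.stress_ceilings)[0])
    return max(rank_cfr, rank_stress)


def classify_map(cfr_map: CFRMap, pmap: PerfusionPolarMap,
                 thresholds: CFCThresholds = DEFAULT_THRESHOLDS) -> CFCResult:
    """Apply the per-pixel CFC rule over a map and tally percent of LV.

    ``percent_lv`` is computed over valid pixels only and sums to 100 for
    any map with at least one valid pixel.
    """
    if cfr_map.geometry != pmap.geometry:
        raise GeometryError("CFR map and perfusion map geometries differ")
    if not np.array_equal(cfr_map.valid_mask, pmap.valid_mask):
        raise GeometryError("CFR map and perfusion map masks differ")
    valid = pmap.valid_mask
    cats = np.full(valid.shape, -1, dtype=int)
    rank_cfr = _band_rank(cfr_map.values[valid], thresholds.cfr_ceilings)
    rank_stress = _band_rank(pmap.stress[valid], thresholds.stress_ceilings)
    cats[valid] = np.maximum(rank_cfr, rank_stress)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValidationError("classify_map needs at least one valid pixel")
    counts = np.bincount(cats[valid], minlength=len(CATEGORY_NAMES))
    percent_lv = 100.0 * counts / n_valid
    return CFCResult(categories=cats, percent_lv=percent_lv, thresholds=thresholds)


def scan_flags(result: CFCResult) -> dict:
    """Scan-level presence/extent flags with the strict printed cutoffs.

    severe_present: any severe pixel (> 0% of LV); moderate_gt15 /
    mild_gt15: category extent strictly above 15% of LV.
    """
    return {
        "severe_present": result.severe_percent > 0.0,
        "moderate_gt15": float(result.percent_lv[1]) > MODERATE_EXTENT_CUTOFF,
        "mild_gt15": float(result.percent_lv[2]) > MILD_EXTENT_CUTOFF,
    }


def min_quadrant_average(values: np.ndarray, valid_mask: np.ndarray,
                         partition: QuadrantPartition) -> tuple[float, str]:
    """Minimum over quadrants of the mean metric value on valid pixels.

    Ties break to the first quadrant in the fixed anterior, septal,
    inferior, lateral order.  An empty quadrant is an error naming it.
    """
    values = np.asarray(values, dtype=float).ravel()
    valid_mask = np.asarray(valid_mask, dtype=bool).ravel()
    best: tuple[float, str] | None = None
    for qi, name in enumerate(QUADRANT_NAMES):
        sel = (partition.labels == qi) & valid_mask
        if not sel.any():
            raise ValidationError(f"quadrant {name!r} has no valid pixels")
        avg = float(values[sel].mean())
        if best is None or avg < best[0]:
            best = (avg, name)
    return best


def relative_defect_percent(relative: np.ndarray, valid_mask: np.ndarray,
                            cutoff: float = RELATIVE_DEFECT_CUTOFF) -> float:
    """Percent of valid LV pixels strictly below ``cutoff``% of maximum."""
    if not 0 < cutoff < 100:
        raise ValidationError("cutoff must be in (0, 100)")
    relative = np.asarray(relative, dtype=float).ravel()
    valid_mask = np.asarray(valid_mask, dtype=bool).ravel()
    vals = relative[valid_mask]
    if vals.size == 0:
        raise ValidationError("relative_defect_percent needs valid pixels")
    return 100.0 * float(np.count_nonzero(vals < cutoff)) / vals.size


def severity_size_ks(group_a, group_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of severity-size histograms.

    Returns (D, p) where D = sup |ECDF_a − ECDF_b| over the pooled
    severe-percent values of the two scan groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("severity_size_ks needs two non-empty groups")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def score_scan(pmap: PerfusionPolarMap,
               thresholds: CFCThresholds = DEFAULT_THRESHOLDS,
               rest_floor: float = 0.1, cfr_cap: float = 10.0,
               top_fraction: float = 0.02,
               partition: QuadrantPartition | None = None) -> CFCResult:
    """Full scan scoring: CFC map, flags, MQA metrics and relative defects.

    Convenience wrapper chaining CFR computation, classification, quadrant
    summaries and relative-defect sizing into one populated CFCResult.
    """
    from .polar_map import compute_cfr  # local import avoids cycle at module load

    if partition is None:
        partition = quadrant_partition(pmap.geometry)
    cfr_map = compute_cfr(pmap, rest_floor=rest_floor, cfr_cap=cfr_cap)
    result = classify_map(cfr_map, pmap, thresholds)
    result.flags = scan_flags(result)
    mqa_cfr = min_quadrant_average(cfr_map.values, pmap.valid_mask, partition)
    mqa_stress = min_quadrant_average(pmap.stress, pmap.valid_mask, partition)
    result.mqa = {
        "cfr": {"value": mqa_cfr[0], "quadrant": mqa_cfr[1],
                "artery": partition.artery_of(mqa_cfr[1])},
        "stress": {"value": mqa_stress[0], "quadrant": mqa_stress[1],
                   "artery": partition.artery_of(mqa_stress[1])},
    }
    rel_rest = relative_map(pmap.rest, pmap.valid_mask, top_fraction)
    rel_stress = relative_map(pmap.stress, pmap.valid_mask, top_fraction)
    result.relative_rest_defect_percent = relative_defect_percent(
        rel_rest, pmap.valid_mask)
    result.relative_stress_defect_percent = relative_defect_percent(
        rel_stress, pmap.valid_mask)
    return result
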