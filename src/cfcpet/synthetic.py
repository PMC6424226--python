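"""Synthetic perfusion phantoms and synthetic clinical cohorts.

Every downstream stage is exercised on data with known ground truth:

* **Phantoms** — target-pattern lesions on the LV polar grid: a severe core
  of prescribed size surrounded by concentric moderate and mild border
  bands, on a uniform normally-perfused background, with multiplicative
  Gaussian noise at the scanner's test–retest precision (±10% coefficient
  of variance by default).

* **Cohorts** — scans with realistic clinical covariates, a phantom-derived
  severity score per scan, propensity-driven revascularization within 90
  days, and proportional-hazards outcomes (death, MI, stroke, late
  revascularization) from a piecewise-exponential model in which the
  revascularization effect switches on at the revascularization day and
  acts only through an interaction with severe flow capacity.

The generating parameters travel alongside the data as a
:class:`SyntheticTruth` so that recovery tests can compare estimates
against the exact simulated effect sizes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfc_scoring import CFCThresholds, DEFAULT_THRESHOLDS, _band_rank
from .errors import ValidationError
from .polar_map import (
    DEFAULT_GEOMETRY,
    PerfusionPolarMap,
    PolarGeometry,
    quadrant_partition,
)

DAYS_PER_YEAR = 365.25

#: Covariate marginals of the untreated clinical population the cohort
#: generator emulates (prevalences; age is Normal(mean, sd) in years).
COVARIATE_MARGINALS = {
    "male": 0.74,
    "hypertension": 0.67,
    "diabetes": 0.22,
    "dyslipidemia": 0.89,
    "smoking": 0.40,
    "prior_pci": 0.28,
    "prior_cabg": 0.12,
    "mi_recent": 0.01,
    "mi_distant": 0.15,
    "statin": 0.71,
    "antiplatelet": 0.69,
    "beta_blocker": 0.43,
    "acei_arb": 0.51,
    "diuretic": 0.24,
}
AGE_MEAN, AGE_SD = 62.0, 11.9

#: Exclusion reasons in the order they are applied to a scan pool.
EXCLUSION_REASONS = (
    "stress_inhibitor",      # medications/caffeine inhibiting vasodilator stress
    "nonstandard_protocol",  # research protocols outside the standard one
    "technical_failure",
    "short_followup",        # < 90 d event-free follow-up
)


@dataclass(frozen=True)
class LesionSpec:
    """Target-pattern lesion: severe core plus concentric border bands.

    ``core_fraction`` and ``border_fractions`` are percents of the LV;
    ``border_positions`` place each border band's perfusion on the linear
    path from core levels to background levels (0 = core, 1 = background).
    """

    center: tuple = (10, 16)
    core_fraction: float = 10.0
    border_fractions: tuple = (10.0, 10.0)   # (moderate, mild) % of LV
    core_levels: tuple = (0.7, 0.5)          # (rest, stress) cc/min/g
    background_levels: tuple = (0.9, 2.5)    # (rest, stress) cc/min/g
    border_positions: tuple = (0.25, 0.5)

    def __post_init__(self) -> None:
        fracs = (self.core_fraction, *self.border_fractions)
        if any(f < 0 for f in fracs):
            raise ValidationError("lesion fractions must be non-negative")
        if sum(fracs) > 100:
            raise ValidationError("lesion fractions exceed the LV size")
        if any(v < 0 for v in (*self.core_levels, *self.background_levels)):
            raise ValidationError("perfusion levels must be non-negative")
        if len(self.border_fractions) != len(self.border_positions):
            raise ValidationError("need one border position per border band")


def _lesion_growth_order(center: tuple, geometry: PolarGeometry) -> np.ndarray:
    """Pixel indices sorted by distance from the lesion center.

    Distance combines ring offset with circular sector offset, the latter
    scaled so half the circumference spans the full ring range (keeps grown
    lesions roughly isotropic on the 21x64 grid).  Ties break by (ring,
    sector) so growth is deterministic.
    """
    rings, sectors = geometry.rings_sectors()
    r0, s0 = center
    dr = rings - r0
    ds = np.abs(sectors - s0)
    ds = np.minimum(ds, geometry.n_sectors - ds)
    scale = geometry.n_rings / (geometry.n_sectors / 2)
    dist = np.hypot(dr, ds * scale)
    return np.lexsort((sectors, rings, dist))


def phantom_levels(spec: LesionSpec,
                   geometry: PolarGeometry = DEFAULT_GEOMETRY
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (rest, stress) level arrays for a lesion spec.

    The lesion is grown concentrically from the center until the core and
    each border band reach their target pixel fractions (rounded to whole
    pixels); border levels interpolate between core and background at the
    spec's positions.
    """
    n = geometry.n_pixels
    rest = np.full(n, spec.background_levels[0])
    stress = np.full(n, spec.background_levels[1])
    order = _lesion_growth_order(spec.center, geometry)
    fractions = (spec.core_fraction, *spec.border_fractions)
    positions = (0.0, *spec.border_positions)
    start = 0
    for frac, t in zip(fractions, positions):
        count = int(round(frac / 100.0 * n))
        band = order[start:start + count]
        rest[band] = spec.core_levels[0] + t * (spec.background_levels[0]
                                                - spec.core_levels[0])
        stress[band] = spec.core_levels[1] + t * (spec.background_levels[1]
                                                  - spec.core_levels[1])
        start += count
    return rest, stress


def generate_phantom(spec: LesionSpec, noise_cov: float = 0.10,
                     seed: int | None = None,
                     geometry: PolarGeometry = DEFAULT_GEOMETRY,
                     rng: np.random.Generator | None = None) -> PerfusionPolarMap:
    """Generate one perfusion phantom with multiplicative Gaussian noise.

    Noise with coefficient of variance ``noise_cov`` is applied
    independently to rest and stress per pixel, emulating test–retest
    variability; results are deterministic under a fixed seed.
    """
    if noise_cov < 0:
        raise ValidationError("noise_cov must be non-negative")
    rest, stress = phantom_levels(spec, geometry)
    if noise_cov > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        rest = np.maximum(rest * rng.normal(1.0, noise_cov, rest.size), 0.0)
        stress = np.maximum(stress * rng.normal(1.0, noise_cov, stress.size), 0.0)
    return PerfusionPolarMap(rest=rest, stress=stress,
                             valid_mask=np.ones(geometry.n_pixels, bool),
                             geometry=geometry)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generating parameters for the synthetic cohort (the ground truth).

    Hazards are per person-year; all effect sizes are hazard ratios.  The
    revascularization effect applies to the death/MI/stroke hazards from
    the revascularization day onward, and differs between scans with and
    without severe flow capacity (the interaction that the outcome models
    must recover).  Late revascularizations (beyond the 90-day window)
    form a separate event process counted only in the MACE composite.
    """

    seed: int = 0
    # imaging stage
    lesion_prevalence: float = 0.19
    core_fraction_shape: float = 1.2     # gamma shape for lesion core, % LV
    core_fraction_scale: float = 8.0     # gamma scale, % LV
    core_fraction_min: float = 1.0
    core_fraction_max: float = 45.0
    border_ratio_moderate: float = 1.0   # border size relative to core
    border_ratio_mild: float = 1.0
    core_levels: tuple = (0.7, 0.5)
    background_levels: tuple = (0.9, 2.5)
    border_positions: tuple = (0.25, 0.5)
    noise_cov: float = 0.10
    # between-scan spread of resting perfusion (lognormal sigma): real
    # populations show marked resting-flow heterogeneity, which decouples
    # CFR from stress-flow summaries across scans
    rest_scale_cov: float = 0.15
    # baseline cause-specific hazards, events per person-year
    hazard_death: float = 0.0117
    hazard_mi: float = 0.0050
    hazard_stroke: float = 0.0045
    hazard_late_revasc: float = 0.0150
    # severity effects (hazard ratios for severe CFC present vs absent)
    hr_dms_severe: float = 1.3
    hr_mace_severe: float = 1.6
    # treatment effect of revascularization within 90 d on death/MI/stroke
    hr_revasc_severe: float = 0.46
    hr_revasc_nonsevere: float = 1.0
    # covariate log-hazard effects, shared by all causes
    beta_age_per10: float = math.log(1.5)
    beta_male: float = math.log(1.2)
    beta_diabetes: float = math.log(1.5)
    # propensity of revascularization within 90 d (logistic coefficients)
    prop_intercept: float = -4.8
    prop_severe_flag: float = 2.4
    prop_severe_percent: float = 0.04    # per % of LV severe
    prop_age_per10: float = 0.2
    prop_male: float = 0.3
    # follow-up
    followup_mean_years: float = 3.0
    followup_max_years: float = 9.0
    min_followup_years: float = 90.0 / DAYS_PER_YEAR
    revasc_window_days: float = 90.0

    def __post_init__(self) -> None:
        for name in ("hazard_death", "hazard_mi", "hazard_stroke",
                     "hazard_late_revasc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("hr_dms_severe", "hr_mace_severe", "hr_revasc_severe",
                     "hr_revasc_nonsevere"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.late_revasc_severe_hr() <= 0:
            raise ValidationError(
                "hr_mace_severe is too small relative to hr_dms_severe for "
                "the configured baseline hazards")

    def dms_hazard(self) -> float:
        return self.hazard_death + self.hazard_mi + self.hazard_stroke

    def late_revasc_severe_hr(self) -> float:
        """Severity hazard ratio on the late-revascularization process.

        Chosen so that the composite MACE hazard (death+MI+stroke+late
        revascularization, all exponential) has exactly ``hr_mace_severe``
        for severe vs non-severe scans while death/MI/stroke each carry
        ``hr_dms_severe``.
        """
        lam_d, lam_r = self.dms_hazard(), self.hazard_late_revasc
        return (self.hr_mace_severe * (lam_d + lam_r)
                - self.hr_dms_severe * lam_d) / lam_r

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["derived"] = {"late_revasc_severe_hr": self.late_revasc_severe_hr()}
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=list)

    @classmethod
    def from_dict(cls, obj: dict) -> "SyntheticTruth":
        obj = {k: v for k, v in obj.items() if k != "derived"}
        for key in ("core_levels", "background_levels", "border_positions"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class ScanRecord:
    """One scan's covariates, severity metrics, treatment and outcomes."""

    scan_id: int
    patient_id: int
    covariates: dict
    severe_percent: float
    severe_present: bool
    revascularized_90d: bool
    revascularization_day: float | None
    followup_years: float
    events: dict  # outcome -> {"time": years, "event": bool}

    @classmethod
    def from_series(cls, row: pd.Series) -> "ScanRecord":
        cov_keys = ["age", *COVARIATE_MARGINALS.keys()]
        day = row.get("revascularization_day", np.nan)
        return cls(
            scan_id=int(row["scan_id"]),
            patient_id=int(row["patient_id"]),
            covariates={k: row[k] for k in cov_keys if k in row},
            severe_percent=float(row["severe_percent"]),
            severe_present=bool(row["severe_present"]),
            revascularized_90d=bool(row["revasc90"]),
            revascularization_day=None if pd.isna(day) else float(day),
            followup_years=float(row["followup_years"]),
            events={o: {"time": float(row[f"{o}_time"]),
                        "event": bool(row[f"{o}_event"])}
                    for o in ("death", "dms", "mace")},
        )


def _score_level_batch(rest: np.ndarray, stress: np.ndarray,
                       thresholds: CFCThresholds,
                       geometry: PolarGeometry,
                       rest_floor: float = 0.1, cfr_cap: float = 10.0,
                       top_fraction: float = 0.02) -> dict:
    """Vectorized scan scoring of a (n_scans, n_pixels) batch of maps.

    Mirrors :func:`cfc_scoring.score_scan` on fully-valid maps; used by the
    cohort generator to score thousands of phantoms at once.
    """
    cfr = np.clip(stress / np.maximum(rest, rest_floor), 0.0, cfr_cap)
    cats = np.maximum(_band_rank(cfr, thresholds.cfr_ceilings),
                      _band_rank(stress, thresholds.stress_ceilings))
    n = rest.shape[1]
    pct = {i: 100.0 * (cats == i).sum(axis=1) / n for i in range(3)}
    part = quadrant_partition(geometry)
    qmeans_cfr = np.stack([cfr[:, part.labels == q].mean(axis=1)
                           for q in range(4)], axis=1)
    qmeans_stress = np.stack([stress[:, part.labels == q].mean(axis=1)
                              for q in range(4)], axis=1)
    n_top = max(1, math.ceil(top_fraction * n))
    robust_max = np.sort(stress, axis=1)[:, -n_top:].mean(axis=1)
    rel_stress_defect = 100.0 * (
        stress < 0.60 * robust_max[:, None]).sum(axis=1) / n
    return {
        "severe_percent": pct[0],
        "moderate_percent": pct[1],
        "mild_percent": pct[2],
        "mqa_cfr": qmeans_cfr.min(axis=1),
        "mqa_stress": qmeans_stress.min(axis=1),
        "relative_stress_defect_percent": rel_stress_defect,
    }


def _piecewise_exponential_times(rng: np.random.Generator, rate0: np.ndarray,
                                 multiplier: np.ndarray,
                                 switch_time: np.ndarray) -> np.ndarray:
    """Event times under a hazard that jumps from rate0 to rate0*multiplier
    at switch_time (inverse-CDF sampling of the piecewise-exponential law)."""
    e = rng.exponential(1.0, rate0.shape)
    pre = rate0 * switch_time
    return np.where(e < pre, e / rate0,
                    switch_time + (e - pre) / (rate0 * multiplier))


def generate_cohort(n_scans: int, truth: SyntheticTruth | None = None,
                    seed: int | None = None, use_phantoms: bool = True,
                    thresholds: CFCThresholds = DEFAULT_THRESHOLDS,
                    geometry: PolarGeometry = DEFAULT_GEOMETRY,
                    batch_size: int = 1024
                    ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort of scored PET scans with survival outcomes.

    Covariates follow the configured marginals; each scan's severity
    metrics come from generating and scoring a noisy phantom (or, with
    ``use_phantoms=False``, directly from the lesion truth — faster, for
    calibration studies that do not exercise the imaging stage).
    Revascularization within 90 days is assigned by a logistic propensity
    on covariates and measured severity; event times follow cause-specific
    piecewise-exponential hazards in which the revascularization effect
    switches on at the revascularization day.  Fixed seed implies a
    bit-identical cohort.
    """
    if n_scans < 1:
        raise ValidationError("n_scans must be at least 1")
    if truth is None:
        truth = SyntheticTruth(seed=0 if seed is None else int(seed))
    if seed is not None:
        truth = dataclasses.replace(truth, seed=int(seed))
    rng = np.random.default_rng(truth.seed)

    df = pd.DataFrame({"scan_id": np.arange(n_scans),
                       "patient_id": np.arange(n_scans)})
    df["age"] = np.clip(rng.normal(AGE_MEAN, AGE_SD, n_scans), 25, 95)
    for name, p in COVARIATE_MARGINALS.items():
        df[name] = (rng.random(n_scans) < p).astype(int)

    # --- imaging stage: lesion truth and measured severity -----------------
    has_lesion = rng.random(n_scans) < truth.lesion_prevalence
    core = np.zeros(n_scans)
    core[has_lesion] = np.clip(
        rng.gamma(truth.core_fraction_shape, truth.core_fraction_scale,
                  has_lesion.sum()),
        truth.core_fraction_min, truth.core_fraction_max)
    total_ratio = 1 + truth.border_ratio_moderate + truth.border_ratio_mild
    core = np.minimum(core, 90.0 / total_ratio)  # keep total lesion <= 90% LV
    centers_r = rng.integers(2, geometry.n_rings - 2, n_scans)
    centers_s = rng.integers(0, geometry.n_sectors, n_scans)
    df["lesion_core_fraction"] = core
    df["lesion_center_ring"] = centers_r
    df["lesion_center_sector"] = centers_s

    # per-scan resting-flow level (mean-1 lognormal); stress bands drive the
    # CFC categories, so classification is insensitive to this scaling
    sigma = truth.rest_scale_cov
    rest_scale = rng.lognormal(-0.5 * sigma ** 2, sigma, n_scans) \
        if sigma > 0 else np.ones(n_scans)

    if use_phantoms:
        metrics = {k: np.empty(n_scans) for k in (
            "severe_percent", "moderate_percent", "mild_percent",
            "mqa_cfr", "mqa_stress", "relative_stress_defect_percent")}
        npix = geometry.n_pixels
        for lo in range(0, n_scans, batch_size):
            hi = min(lo + batch_size, n_scans)
            rest = np.empty((hi - lo, npix))
            stress = np.empty((hi - lo, npix))
            for j, i in enumerate(range(lo, hi)):
                if has_lesion[i]:
                    spec = LesionSpec(
                        center=(int(centers_r[i]), int(centers_s[i])),
                        core_fraction=float(core[i]),
                        border_fractions=(
                            float(core[i] * truth.border_ratio_moderate),
                            float(core[i] * truth.border_ratio_mild)),
                        core_levels=truth.core_levels,
                        background_levels=truth.background_levels,
                        border_positions=truth.border_positions)
                    rest[j], stress[j] = phantom_levels(spec, geometry)
                else:
                    rest[j] = truth.background_levels[0]
                    stress[j] = truth.background_levels[1]
            rest *= rest_scale[lo:hi, None]
            if truth.noise_cov > 0:
                rest = np.maximum(
                    rest * rng.normal(1.0, truth.noise_cov, rest.shape), 0.0)
                stress = np.maximum(
                    stress * rng.normal(1.0, truth.noise_cov, stress.shape), 0.0)
            batch = _score_level_batch(rest, stress, thresholds, geometry)
            for k, v in batch.items():
                metrics[k][lo:hi] = v
        for k, v in metrics.items():
            df[k] = v
    else:
        df["severe_percent"] = core
        df["moderate_percent"] = core * truth.border_ratio_moderate
        df["mild_percent"] = core * truth.border_ratio_mild
        df["mqa_cfr"] = np.nan
        df["mqa_stress"] = np.nan
        df["relative_stress_defect_percent"] = np.nan
    df["severe_present"] = (df["severe_percent"] > 0).astype(int)
    severe = df["severe_present"].to_numpy(float)

    # --- treatment assignment ---------------------------------------------
    logit = (truth.prop_intercept
             + truth.prop_severe_flag * severe
             + truth.prop_severe_percent * df["severe_percent"].to_numpy()
             + truth.prop_age_per10 * (df["age"].to_numpy() - AGE_MEAN) / 10.0
             + truth.prop_male * df["male"].to_numpy())
    propensity = 1.0 / (1.0 + np.exp(-logit))
    treated = rng.random(n_scans) < propensity
    rev_day = np.where(treated,
                       rng.uniform(0.0, truth.revasc_window_days, n_scans),
                       np.nan)
    t_rev = np.where(treated, rev_day / DAYS_PER_YEAR, np.inf)
    df["true_propensity"] = propensity

    # --- outcomes ----------------------------------------------------------
    eta = (truth.beta_age_per10 * (df["age"].to_numpy() - AGE_MEAN) / 10.0
           + truth.beta_male * df["male"].to_numpy()
           + truth.beta_diabetes * df["diabetes"].to_numpy())
    base_mult = np.exp(eta)
    sev_dms = truth.hr_dms_severe ** severe
    treat_mult = np.where(severe > 0, truth.hr_revasc_severe,
                          truth.hr_revasc_nonsevere)
    switch = np.where(np.isfinite(t_rev), t_rev, 1e9)
    cause_times = {}
    for cause, lam in (("death", truth.hazard_death),
                       ("mi", truth.hazard_mi),
                       ("stroke", truth.hazard_stroke)):
        rate0 = lam * base_mult * sev_dms
        cause_times[cause] = _piecewise_exponential_times(
            rng, rate0, treat_mult, switch)
    # late revascularization: hazard 0 inside the 90-day window, constant after
    window_y = truth.revasc_window_days / DAYS_PER_YEAR
    rate_lr = (truth.hazard_late_revasc * base_mult
               * truth.late_revasc_severe_hr() ** severe)
    cause_times["late_revasc"] = window_y + rng.exponential(1.0 / rate_lr)

    censor = np.minimum(rng.exponential(truth.followup_mean_years, n_scans),
                        truth.followup_max_years)
    censor = np.maximum(censor, truth.min_followup_years)

    # a death/MI/stroke before the drawn revascularization day precludes it
    t_dms = np.minimum.reduce([cause_times[c] for c in ("death", "mi", "stroke")])
    precluded = treated & (t_dms < t_rev)
    treated = treated & ~precluded
    rev_day = np.where(treated, rev_day, np.nan)

    df["revasc90"] = treated.astype(int)
    df["revascularization_day"] = rev_day
    df["followup_years"] = censor
    t_mace = np.minimum(t_dms, cause_times["late_revasc"])
    for outcome, t_event in (("death", cause_times["death"]),
                             ("dms", t_dms), ("mace", t_mace)):
        df[f"{outcome}_event"] = (t_event <= censor).astype(int)
        df[f"{outcome}_time"] = np.minimum(t_event, censor)
    return df, truth


def apply_exclusions(pool: pd.DataFrame,
                     reasons: tuple = EXCLUSION_REASONS
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Filter a scan pool by its exclusion-reason flags, with accounting.

    Flags are applied in the given order; a scan carrying several flags is
    counted under the first.  The report lists, per reason, the number
    removed and its percent of the initial pool (one decimal), followed by
    a ``remaining`` entry.
    """
    for reason in reasons:
        if reason not in pool.columns:
            raise ValidationError(f"unknown exclusion flag {reason!r}")
    n0 = len(pool)
    keep = pool.copy()
    report = []
    for reason in reasons:
        flagged = keep[reason].astype(bool)
        removed = int(flagged.sum())
        report.append({
            "reason": reason,
            "removed": removed,
            "percent_of_pool": round(100.0 * removed / n0, 1) if n0 else 0.0,
        })
        keep = keep[~flagged]
    report.append({"reason": "remaining", "removed": int(len(keep)),
                   "percent_of_pool": round(100.0 * len(keep) / n0, 1) if n0 else 0.0})
    return keep, report
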