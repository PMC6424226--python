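"""Reproducible pipeline: simulate -> score -> analyze -> report.

A run is driven by a :class:`PipelineConfig` (YAML-loadable) and writes a
run directory containing the cohort table, the generating truth, fit
tables, survival summaries and per-scan reports, plus a manifest listing
every input and output with its SHA-256 so a run is auditable and
re-running with the same config is bit-identical for the deterministic
stages.  Scan reports summarize size–severity metrics only; they never
phrase management recommendations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfc_scoring, outcomes, synthetic
from .cfc_scoring import CFCResult, CFCThresholds, CATEGORY_NAMES
from .errors import ConfigError, ValidationError
from .synthetic import LesionSpec, ScanRecord, SyntheticTruth

log = logging.getLogger("cfcpet")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    seed: int = 1
    n_scans: int = 2000
    outcome: str = "dms"
    covariates: tuple = outcomes.DEFAULT_COVARIATES
    ties: str = "efron"
    window_days: float = 90.0
    use_phantoms: bool = True
    thresholds_file: str | None = None
    truth_file: str | None = None
    n_reports: int = 3

    def __post_init__(self) -> None:
        if self.outcome not in ("death", "dms", "mace"):
            raise ConfigError(f"unknown outcome {self.outcome!r}")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError(f"unknown ties method {self.ties!r}")
        for name in ("thresholds_file", "truth_file"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "covariates" in obj:
            obj["covariates"] = tuple(obj["covariates"])
        return cls(**obj)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["covariates"] = list(self.covariates)
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def load_thresholds(self) -> CFCThresholds:
        if self.thresholds_file is None:
            return cfc_scoring.DEFAULT_THRESHOLDS
        with open(self.thresholds_file, encoding="utf-8") as fh:
            return CFCThresholds.from_dict(yaml.safe_load(fh))

    def load_truth(self) -> SyntheticTruth:
        if self.truth_file is None:
            return SyntheticTruth(seed=self.seed)
        with open(self.truth_file, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        return SyntheticTruth.from_dict({**obj, "seed": self.seed})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def scan_report(record: ScanRecord, result: CFCResult) -> dict:
    """Per-scan report: size–severity metrics and the implicated territory.

    Reports the percent of LV per CFC category, the minimum quadrant
    averages of CFR and stress flow, relative defect sizes and extent
    flags, naming the implicated quadrant/artery when severe CFC is
    present.  No treatment recommendation is emitted.
    """
    if result.mqa is None or result.flags is None:
        raise ValidationError("scan_report requires a fully scored scan")
    severe = result.flags["severe_present"]
    implicated = result.mqa["stress"] if severe else None
    return {
        "scan_id": record.scan_id,
        "patient_id": record.patient_id,
        "covariates": {k: (float(v) if isinstance(v, (int, float, np.floating))
                           else v) for k, v in record.covariates.items()},
        "percent_lv": {name: float(p) for name, p
                       in zip(CATEGORY_NAMES, result.percent_lv)},
        "severe_percent": result.severe_percent,
        "flags": result.flags,
        "mqa": result.mqa,
        "relative_rest_defect_percent": result.relative_rest_defect_percent,
        "relative_stress_defect_percent": result.relative_stress_defect_percent,
        "implicated_quadrant": implicated["quadrant"] if implicated else None,
        "implicated_artery": implicated["artery"] if implicated else None,
        "revascularized_90d": record.revascularized_90d,
        "followup_years": record.followup_years,
    }


def render_scan_report(report: dict) -> str:
    lines = [
        f"Scan {report['scan_id']} (patient {report['patient_id']})",
        "CFC percent of LV: " + ", ".join(
            f"{k} {v:.1f}%" for k, v in report["percent_lv"].items()),
        f"Severe CFC: {report['severe_percent']:.1f}% of LV",
        (f"Minimum quadrant average CFR: {report['mqa']['cfr']['value']:.2f} "
         f"({report['mqa']['cfr']['quadrant']})"),
        (f"Minimum quadrant average stress flow: "
         f"{report['mqa']['stress']['value']:.2f} cc/min/g "
         f"({report['mqa']['stress']['quadrant']})"),
        (f"Relative defects (<60% of maximum): rest "
         f"{report['relative_rest_defect_percent']:.1f}%, stress "
         f"{report['relative_stress_defect_percent']:.1f}% of LV"),
    ]
    if report["implicated_artery"]:
        lines.append(f"Implicated territory: {report['implicated_quadrant']} "
                     f"quadrant ({report['implicated_artery']})")
    else:
        lines.append("Implicated territory: none (no severe CFC)")
    return "\n".join(lines)


def analyze_cohort(cohort: pd.DataFrame, outcome: str = "dms",
                   covariates=outcomes.DEFAULT_COVARIATES,
                   ties: str = "efron", window_days: float = 90.0) -> dict:
    """Run the full outcome analysis on a scored cohort.

    Returns the main Cox fit, the severity-by-exposure interaction fit, a
    propensity-adjusted interaction fit, the severe-vs-not Kaplan–Meier /
    log-rank comparison, the hazard-ratio-over-time curve, and the severity
    KS comparison between treated and untreated scans.
    """
    covariates = [c for c in covariates if c in cohort.columns]
    cp = outcomes.build_counting_process(cohort, outcome=outcome,
                                         window_days=window_days,
                                         covariates=covariates)
    main_fit = outcomes.cox_fit(cp, covariates + ["exposed"], ties=ties)
    inter_fit = outcomes.interaction_model(cp, covariates, ties=ties)

    prop_covs = [c for c in covariates if c not in ("severe_present",)]
    prop = outcomes.fit_propensity(cohort, prop_covs)
    cp_prop = cp.merge(
        pd.DataFrame({"scan_id": cohort["scan_id"],
                      "propensity_score": prop.scores}),
        on="scan_id", how="left")
    prop_fit = outcomes.interaction_model(
        cp_prop, covariates + ["propensity_score"], ties=ties)

    severe = cohort["severe_present"] == 1
    lr_stat, lr_p = outcomes.log_rank(
        cohort.loc[severe, f"{outcome}_time"],
        cohort.loc[severe, f"{outcome}_event"],
        cohort.loc[~severe, f"{outcome}_time"],
        cohort.loc[~severe, f"{outcome}_event"])
    km_severe = outcomes.km_estimate(cohort.loc[severe, f"{outcome}_time"],
                                     cohort.loc[severe, f"{outcome}_event"])
    km_other = outcomes.km_estimate(cohort.loc[~severe, f"{outcome}_time"],
                                    cohort.loc[~severe, f"{outcome}_event"])
    hr_curve = outcomes.hazard_ratio_curve(inter_fit, cp)

    treated = cohort["revasc90"] == 1
    ks_stat, ks_p = cfc_scoring.severity_size_ks(
        cohort.loc[treated, "severe_percent"],
        cohort.loc[~treated, "severe_percent"])
    return {
        "counting_process": cp,
        "main_fit": main_fit,
        "interaction_fit": inter_fit,
        "propensity_model": prop,
        "propensity_fit": prop_fit,
        "log_rank": {"statistic": lr_stat, "p": lr_p},
        "km": {"severe": km_severe, "not_severe": km_other},
        "hr_curve": hr_curve,
        "severity_ks": {"statistic": ks_stat, "p": ks_p},
    }


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute simulate -> score -> analyze -> report into a run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.load_thresholds()
    truth = config.load_truth()
    stage = "simulate"
    try:
        cohort, truth = synthetic.generate_cohort(
            config.n_scans, truth=truth, seed=config.seed,
            use_phantoms=config.use_phantoms, thresholds=thresholds)
        cohort.to_csv(out / "cohort.csv", index=False)
        truth.to_json(out / "truth.json")
        log.info("simulate: %d scans, %d revascularized within 90 d",
                 len(cohort), int(cohort["revasc90"].sum()))

        stage = "score"
        comparison = outcomes.group_compare(
            cohort, "revasc90",
            variables=["age", "male", "diabetes", "hypertension",
                       "severe_percent", "mqa_cfr", "mqa_stress"])
        comparison.to_csv(out / "group_comparison.csv", index=False)
        log.info("score: %.1f%% of scans with severe CFC",
                 100.0 * cohort["severe_present"].mean())

        stage = "analyze"
        res = analyze_cohort(cohort, outcome=config.outcome,
                             covariates=list(config.covariates),
                             ties=config.ties, window_days=config.window_days)
        res["main_fit"].summary().to_csv(out / f"cox_{config.outcome}.csv")
        res["interaction_fit"].summary().to_csv(
            out / f"cox_{config.outcome}_interaction.csv")
        res["propensity_fit"].summary().to_csv(
            out / f"cox_{config.outcome}_propensity.csv")
        res["hr_curve"].to_csv(out / "hazard_ratio_over_time.csv", index=False)
        with open(out / "survival_summary.json", "w", encoding="utf-8") as fh:
            json.dump({
                "log_rank": res["log_rank"],
                "severity_ks": res["severity_ks"],
                "n_events": res["main_fit"].n_events,
            }, fh, indent=2)
        log.info("analyze: %d events for outcome %s",
                 res["main_fit"].n_events, config.outcome)

        stage = "report"
        reports = []
        rng = np.random.default_rng(config.seed + 1)
        lesioned = cohort[cohort["lesion_core_fraction"] > 0].head(config.n_reports)
        for _, row in lesioned.iterrows():
            spec = LesionSpec(
                center=(int(row["lesion_center_ring"]),
                        int(row["lesion_center_sector"])),
                core_fraction=float(row["lesion_core_fraction"]),
                border_fractions=(
                    float(row["lesion_core_fraction"] * truth.border_ratio_moderate),
                    float(row["lesion_core_fraction"] * truth.border_ratio_mild)),
                core_levels=truth.core_levels,
                background_levels=truth.background_levels,
                border_positions=truth.border_positions)
            pmap = synthetic.generate_phantom(spec, noise_cov=truth.noise_cov,
                                              rng=rng)
            result = cfc_scoring.score_scan(pmap, thresholds)
            reports.append(scan_report(ScanRecord.from_series(row), result))
        with open(out / "scan_reports.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2)
        with open(out / "scan_reports.txt", "w", encoding="utf-8") as fh:
            fh.write("\n\n".join(render_scan_report(r) for r in reports))
        log.info("report: %d scan reports", len(reports))
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out
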