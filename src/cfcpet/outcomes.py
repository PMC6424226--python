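"""Survival and group-comparison statistics for the scored cohort.

The central analysis is a Cox proportional-hazards model on
counting-process data in which revascularization within 90 days after the
scan is a *time-varying* exposure: a treated scan contributes an unexposed
interval (0, d] and an exposed interval (d, T] split at its
revascularization day d, while revascularization beyond the 90-day window
never sets the exposure (it is not considered scan-guided).  Around that
sit Kaplan–Meier/log-rank comparisons, a logistic propensity score for
receiving early revascularization, an exposure-by-severity interaction
model, hazard-ratio-over-time curves at median covariates, and the
χ²/Welch-t table comparisons between treated and untreated groups.

Time is measured in years (90 days = 90/365.25 y).  Ties are handled by
the Efron approximation by default, with Breslow optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .errors import AnalysisError, ValidationError

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOW_DAYS = 90.0

#: Default covariate roster for the outcome models (cohort column names).
DEFAULT_COVARIATES = (
    "male", "age", "hypertension", "diabetes", "dyslipidemia", "smoking",
    "mi_recent", "mi_distant", "prior_pci", "prior_cabg",
    "mqa_stress", "mqa_cfr", "severe_present",
)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate: right-continuous decreasing steps."""

    times: np.ndarray        # step locations (including t=0)
    survival: np.ndarray     # S(t) at each step location
    n: int
    n_events: int

    def at(self, t) -> np.ndarray:
        """S(t), right-continuous (value of the most recent step)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator; S(0) = 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValidationError("km_estimate needs at least one subject")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(times=sf.index.to_numpy(float),
                   survival=sf.iloc[:, 0].to_numpy(float),
                   n=times.size, n_events=int(events.sum()))


def log_rank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a).astype(bool)
    events_b = np.asarray(events_b).astype(bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("log_rank needs two non-empty groups")
    if events_a.sum() + events_b.sum() == 0:
        raise AnalysisError("log-rank statistic undefined with no events")
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Counting-process construction
# ---------------------------------------------------------------------------

def build_counting_process(cohort: pd.DataFrame, outcome: str = "dms",
                           window_days: float = DEFAULT_WINDOW_DAYS,
                           covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Expand a cohort into (start, stop] rows with time-varying exposure.

    A scan revascularized at day d <= ``window_days`` contributes rows
    (0, d/365.25] with ``exposed`` 0 and (d/365.25, T] with ``exposed`` 1;
    later revascularizations never set the exposure.  The event indicator
    sits on the final row of each scan.  Total at-risk time per scan is
    conserved by the split.
    """
    needed = {f"{outcome}_time", f"{outcome}_event", "revasc90",
              "revascularization_day", "followup_years"}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns {sorted(missing)}")
    rev_day = cohort["revascularization_day"].to_numpy(float)
    fup = cohort["followup_years"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.any(np.nan_to_num(rev_day, nan=-1.0) / DAYS_PER_YEAR > fup):
            raise ValidationError("revascularization day exceeds follow-up")

    stop = cohort[f"{outcome}_time"].to_numpy(float)
    event = cohort[f"{outcome}_event"].to_numpy(int)
    treated = (cohort["revasc90"].to_numpy(int) == 1) & \
        (np.nan_to_num(rev_day, nan=np.inf) <= window_days)
    t_rev = rev_day / DAYS_PER_YEAR
    split = treated & (t_rev > 0) & (t_rev < stop)

    cov = [c for c in covariates if c in cohort.columns]
    base = cohort[["scan_id", "patient_id", *cov]] if "patient_id" in cohort \
        else cohort[["scan_id", *cov]]

    rows = []
    # unexposed segment (everyone; for split scans it ends at the rev day)
    first = base.copy()
    first["start"] = 0.0
    first["stop"] = np.where(split, t_rev, stop)
    first["exposed"] = np.where(treated & ~split, 1, 0)  # rev at t=0 edge case
    first.loc[treated & ~split & (np.nan_to_num(t_rev, nan=np.inf) >= stop),
              "exposed"] = 0  # rev exactly at the event instant: never exposed
    first["event"] = np.where(split, 0, event)
    rows.append(first)
    if split.any():
        second = base[split].copy()
        second["start"] = t_rev[split]
        second["stop"] = stop[split]
        second["exposed"] = 1
        second["event"] = event[split]
        rows.append(second)
    out = pd.concat(rows, ignore_index=True)
    out = out[out["stop"] > out["start"]].reset_index(drop=True)
    return out.sort_values(["scan_id", "start"], kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Cox model fit: coefficients, hazard ratios, Wald CIs, diagnostics."""

    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    ties: str
    n_rows: int
    n_events: int
    warnings: list = field(default_factory=list)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * sps.norm.sf(np.abs(z)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "hr_lower": np.exp(self.params - z * self.se),
            "hr_upper": np.exp(self.params + z * self.se),
        }, index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "coef": self.params,
            "se": self.se,
            "hazard_ratio": self.hazard_ratios,
            "hr_lower_95": ci["hr_lower"],
            "hr_upper_95": ci["hr_upper"],
            "p": self.p_values,
        })

    def combo_hr(self, weights: dict, alpha: float = 0.05
                 ) -> tuple[float, float, float]:
        """Hazard ratio (with Wald CI) of a linear combination of coefficients.

        E.g. ``{"exposed": 1, "exposed:severe_present": 1}`` gives the
        exposure HR within the severe stratum.
        """
        w = pd.Series(0.0, index=self.params.index)
        for k, v in weights.items():
            w[k] = v
        est = float(w @ self.params)
        var = float(w @ self.cov @ w)
        z = sps.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return float(np.exp(est)), float(np.exp(est - half)), float(np.exp(est + half))


def _screen_design(X: pd.DataFrame, corr_threshold: float = 0.9) -> list[str]:
    """Colinearity screen; raises on rank deficiency, returns warnings."""
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise AnalysisError(f"aliased (constant) covariates: {constant}")
    warnings = []
    corr = X.corr().to_numpy()
    cols = list(X.columns)
    aliased = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr[i, j]
            if abs(r) > 0.9999:
                aliased.append((cols[i], cols[j]))
            elif abs(r) > corr_threshold:
                warnings.append(
                    f"high colinearity |r|={abs(r):.3f}: {cols[i]} ~ {cols[j]}")
    if aliased or np.linalg.matrix_rank(X.to_numpy()) < len(cols):
        raise AnalysisError(f"rank-deficient design; aliased pairs: {aliased}")
    return warnings


def cox_fit(cp: pd.DataFrame, covariates, ties: str = "efron",
            start_col: str = "start", stop_col: str = "stop",
            event_col: str = "event") -> SurvivalFit:
    """Cox partial-likelihood fit on counting-process (start, stop] data.

    Uses left-truncated risk sets so each row is at risk only on its own
    interval; Wald confidence intervals on the log-hazard scale.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError("ties must be 'efron' or 'breslow'")
    covariates = list(covariates)
    missing = [c for c in covariates if c not in cp.columns]
    if missing:
        raise ValidationError(f"counting-process data lacks columns {missing}")
    if int(cp[event_col].sum()) < 1:
        raise AnalysisError("Cox fit needs at least one event")
    X = cp[covariates].astype(float)
    warnings = _screen_design(X)
    model = PHReg(cp[stop_col].to_numpy(float), X.to_numpy(),
                  status=cp[event_col].to_numpy(int),
                  entry=cp[start_col].to_numpy(float), ties=ties)
    try:
        res = model.fit(disp=False)
    except Exception as exc:
        raise AnalysisError(f"Cox fit did not converge: {exc}") from exc
    params = pd.Series(res.params, index=covariates)
    if not np.all(np.isfinite(params)):
        raise AnalysisError("Cox fit produced non-finite coefficients")
    cov = pd.DataFrame(res.cov_params(), index=covariates, columns=covariates)
    return SurvivalFit(
        params=params,
        se=pd.Series(np.sqrt(np.diag(cov)), index=covariates),
        cov=cov,
        log_likelihood=float(model.loglike(res.params)),
        ties=ties,
        n_rows=len(cp),
        n_events=int(cp[event_col].sum()),
        warnings=warnings,
    )


def interaction_model(cp: pd.DataFrame, base_covariates,
                      exposure_col: str = "exposed",
                      modifier_col: str = "severe_present",
                      ties: str = "efron") -> SurvivalFit:
    """Cox model with exposure, modifier main effects and their product.

    The product column is named ``"<exposure>:<modifier>"``; the severe-
    stratum exposure HR is ``combo_hr({exposure: 1, product: 1})``.
    """
    cp = cp.copy()
    product = f"{exposure_col}:{modifier_col}"
    cp[product] = cp[exposure_col] * cp[modifier_col]
    covs = [c for c in base_covariates if c not in (exposure_col, product)]
    if modifier_col not in covs:
        covs.append(modifier_col)
    return cox_fit(cp, covs + [exposure_col, product], ties=ties)


# ---------------------------------------------------------------------------
# Propensity score
# ---------------------------------------------------------------------------

@dataclass
class PropensityModel:
    """Logistic model of early revascularization; scores lie in (0, 1)."""

    params: pd.Series
    se: pd.Series
    scores: np.ndarray
    n_treated: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.se})


def fit_propensity(cohort: pd.DataFrame, covariates,
                   treatment_col: str = "revasc90") -> PropensityModel:
    """Maximum-likelihood logistic regression of treatment on covariates."""
    import statsmodels.api as sm

    covariates = list(covariates)
    y = cohort[treatment_col].astype(int).to_numpy()
    if y.min() == y.max():
        raise AnalysisError("propensity model needs treated and untreated scans")
    X = sm.add_constant(cohort[covariates].astype(float), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:
        raise AnalysisError(f"propensity fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or \
            not np.all(np.isfinite(res.params)):
        raise AnalysisError("propensity fit did not converge "
                            "(possible complete separation)")
    scores = np.asarray(res.predict(X))
    eps = np.finfo(float).tiny
    scores = np.clip(scores, eps, 1 - 1e-15)
    return PropensityModel(params=res.params, se=res.bse, scores=scores,
                           n_treated=int(y.sum()))


# ---------------------------------------------------------------------------
# Hazard-ratio-over-time curve
# ---------------------------------------------------------------------------

def expand_time_interaction(cp: pd.DataFrame, split_times,
                            exposure_col: str = "exposed",
                            name: str = "exposed:logt") -> pd.DataFrame:
    """Split intervals at ``split_times`` and add an exposure x log(time) column.

    The product column takes the value exposure*log(stop) on each
    sub-interval, a step approximation to a continuously time-varying
    effect that becomes exact in the limit of a fine grid.
    """
    pieces = [cp]
    for t in sorted(split_times):
        next_pieces = []
        for piece in pieces:
            inside = (piece["start"] < t) & (t < piece["stop"])
            left = piece[inside].copy()
            right = piece[inside].copy()
            left["stop"] = t
            left["event"] = 0
            right["start"] = t
            next_pieces.extend([piece[~inside], left, right])
        pieces = [pd.concat(next_pieces, ignore_index=True)]
    out = pieces[0].sort_values(["scan_id", "start"], ignore_index=True)
    out[name] = out[exposure_col] * np.log(out["stop"])
    return out


def hazard_ratio_curve(fit: SurvivalFit, cp: pd.DataFrame,
                       exposure_col: str = "exposed",
                       time_grid=None) -> pd.DataFrame:
    """HR(t) of exposure vs none with other covariates at their medians.

    Product terms named ``"<exposure>:<col>"`` contribute with the median
    of ``col`` over the counting-process rows; a ``"<exposure>:logt"``
    term contributes with log(t).  Under a plain proportional-hazards
    model the curve is flat at exp(beta_exposure).
    """
    if exposure_col not in fit.params.index:
        raise ValidationError(f"fit has no {exposure_col!r} coefficient")
    if time_grid is None:
        time_grid = np.linspace(cp["stop"].min(), cp["stop"].max(), 50)
    time_grid = np.asarray(time_grid, float)
    log_hr = np.full(time_grid.shape, float(fit.params[exposure_col]))
    prefix = exposure_col + ":"
    for name in fit.params.index:
        if not name.startswith(prefix):
            continue
        partner = name[len(prefix):]
        if partner == "logt":
            log_hr = log_hr + float(fit.params[name]) * np.log(time_grid)
        else:
            med = float(cp[partner].median())
            log_hr = log_hr + float(fit.params[name]) * med
    return pd.DataFrame({"time": time_grid, "hazard_ratio": np.exp(log_hr)})


# ---------------------------------------------------------------------------
# Table-1-style group comparisons
# ---------------------------------------------------------------------------

def group_compare(table: pd.DataFrame, group_col: str,
                  variables=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable two-group tests: χ² for binary, Welch t for continuous.

    Binary variables are compared by the χ² test on the 2x2 count table
    (no continuity correction) with group percentages reported; continuous
    variables by the unequal-variance (Welch) t test with group mean ± SD.
    """
    groups = table[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValidationError(f"{group_col!r} must define exactly two groups")
    g0, g1 = sorted(groups)
    a = table[table[group_col] == g0]
    b = table[table[group_col] == g1]
    if variables is None:
        variables = [c for c in table.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for var in variables:
        xa = a[var].dropna().to_numpy(float)
        xb = b[var].dropna().to_numpy(float)
        binary = set(np.unique(table[var].dropna())) <= {0, 1, True, False}
        if binary:
            counts = np.array([[ (xa == 1).sum(), (xa == 0).sum()],
                               [ (xb == 1).sum(), (xb == 0).sum()]])
            if counts[:, 0].sum() in (0, counts.sum()):  # degenerate margin
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
            rows.append({
                "variable": var, "kind": "binary", "test": "chi2",
                "group_a_n": int((xa == 1).sum()),
                "group_a_stat": 100.0 * (xa == 1).mean() if xa.size else np.nan,
                "group_b_n": int((xb == 1).sum()),
                "group_b_stat": 100.0 * (xb == 1).mean() if xb.size else np.nan,
                "statistic": float(stat), "p": float(p),
            })
        else:
            if np.array_equal(xa, xb):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append({
                "variable": var, "kind": "continuous", "test": "welch_t",
                "group_a_n": xa.size, "group_a_stat": float(np.mean(xa)),
                "group_b_n": xb.size, "group_b_stat": float(np.mean(xb)),
                "statistic": float(stat), "p": float(p),
            })
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out
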