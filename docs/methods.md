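# Methods

`cfcpet` implements a quantitative myocardial-perfusion analysis chain for
rest–stress cardiac PET: per-pixel coronary flow capacity (CFC) scoring of
left-ventricular (LV) perfusion maps, scan-level size–severity metrics, and
survival models linking severe CFC and early revascularization to adverse
outcomes. Because no patient data ship with the package, every stage is
exercised on synthetic phantoms and synthetic cohorts with known generating
parameters; this note records the models, defaults and design choices.

## The LV polar grid

Perfusion is sampled on a fixed polar ("bullseye") grid of **1,344 pixels**,
organised as 21 rings (apex to base) × 64 angular sectors, with sector 0 at
the anterior–septal junction, counterclockwise viewed from the apex. Each
pixel carries absolute rest and stress perfusion in cc/min/g plus a validity
flag. The ring/sector factorisation is a package choice: the total pixel
count is the normative constant, and 21 × 64 keeps the sector count
divisible by four for quadrant analysis while giving enough radial
resolution for concentric lesions. Quadrants are the four equal contiguous
angular blocks (anterior, septal, inferior, lateral), mapped by default to
LAD (anterior + septal), LCx (lateral) and RCA (inferior); the mapping is
configurable because no pixel-level territory table is normative.

File formats are deliberately plain: a CSV dialect
(`ring,sector,rest,stress,valid`, 1,344 data rows) and an equivalent JSON
object. CSV round-trips are bit-exact (`%.17g` on write, round-trip float
parsing on read).

## Per-pixel physiology

* **CFR** (coronary flow reserve) = stress / max(rest, `rest_floor`),
  clipped to `[0, cfr_cap]`. Defaults: `rest_floor` = 0.1 cc/min/g — below
  physiologic resting flow (even transmural scar rests near 0.25 cc/min/g)
  so it only guards against division blow-up — and `cfr_cap` = 10.
* **Relative images** express a component as percent of a *robust maximum*:
  the mean of the hottest 2% of valid pixels (`top_fraction` = 0.02), so a
  single hot pixel cannot dominate normalisation. Relative values may
  exceed 100%.

## CFC classification

Each pixel is ranked independently on a five-band CFR scale and a five-band
stress-perfusion scale; its CFC category is the **milder (higher) of the
two ranks**. The rule is forced by the definition of the severe category —
severe requires *both* CFR ≤ 1.27 *and* stress perfusion ≤ 0.83 cc/min/g —
and by the clinical observation that high stress flow with low CFR (high
resting perfusion) is low-risk: a pixel normal on either metric is normal
overall. All band ceilings are inclusive (≤), applied uniformly.

Only the severe boundary (1.27, 0.83) is normative. The intermediate band
ceilings are configuration with documented defaults:

| band | category | CFR ≤ | stress ≤ (cc/min/g) |
|------|----------|-------|---------------------|
| 0 | severe (blue) | 1.27 | 0.83 |
| 1 | moderate (green) | 1.74 | 1.12 |
| 2 | mild (yellow) | 2.38 | 1.76 |
| 3 | minimal (orange) | 2.90 | 2.17 |
| 4 | normal (red) | ∞ | ∞ |

Scan-level metrics: percent of LV per category (computed over valid pixels,
summing to 100); extent flags with the strict printed cutoffs
(severe > 0%, moderate > 15%, mild > 15% of LV); minimum quadrant averages
(MQA) of CFR and stress flow, computed independently per metric with ties
broken to the first quadrant in anterior/septal/inferior/lateral order; and
relative-defect sizes (percent of LV strictly below 60% of the robust
maximum on relative rest and stress images).

## Phantoms

A phantom is a target-pattern lesion on a uniform background: a severe core
grown concentrically from a centre pixel until it covers the requested
fraction of the LV (rounded to whole pixels), surrounded by moderate and
mild border bands grown the same way. Growth order sorts pixels by a
ring/sector distance in which half the circumference spans the full ring
range, keeping lesions roughly isotropic; ties break deterministically.
Border perfusion interpolates linearly from core to background levels at
positions 0.25 and 0.5 of the path — chosen so that, under the default
thresholds, the two border bands classify as moderate and mild
respectively. Default levels: core (rest 0.7, stress 0.5), background
(rest 0.9, stress 2.5) cc/min/g.

Measurement noise is multiplicative Gaussian with coefficient of variance
0.10 applied independently per pixel to rest and stress, matching the
scanner methodology's test–retest precision of ±10%. Noise-free phantoms
round-trip through scoring to 1-pixel resolution (100/1344 ≈ 0.074% of LV);
at 10% noise the per-pixel CoV across replicates reproduces 0.10.

## Synthetic cohort

The cohort generator emulates a tertiary-care stable-CAD population:

* **Covariates** — independent draws from configurable marginals matching
  the untreated clinical population (74% male, age 62 ± 11.9 y, 67%
  hypertension, 22% diabetes, 89% dyslipidemia, 28% prior PCI, …).
  Independence of covariates is a simplification of real comorbidity
  clustering.
* **Imaging** — 19% of scans carry a lesion; core size is gamma-distributed
  (shape 1.2, scale 8% of LV, truncated to [1, 45]) with moderate and mild
  borders equal to the core size. Each scan's severity metrics come from
  generating and scoring its noisy phantom (vectorised in batches; verified
  against per-scan scoring). Resting perfusion carries an additional
  per-scan lognormal scale (σ = 0.15), emulating the marked between-patient
  resting-flow heterogeneity of real populations; stress bands drive the
  CFC categories, so classification is insensitive to it, but it decouples
  CFR-based from stress-flow-based summaries across scans as in real data.
* **Treatment** — revascularization within 90 days is Bernoulli with a
  logistic propensity on measured severity (flag + extent), age and sex,
  with an intercept placing the treated fraction near 3–4% and roughly
  15% within the severe stratum. The revascularization day is uniform on
  [0, 90] days.
* **Outcomes** — cause-specific exponential hazards for death
  (0.0117/person-year), MI (0.0050), stroke (0.0045) and late
  revascularization (0.0150), each multiplied by shared covariate effects
  (age HR 1.5/decade, male 1.2, diabetes 1.5) and by severity: death, MI
  and stroke each carry the DMS severity hazard ratio (default **1.3**),
  while the late-revascularization process carries the multiplier that
  makes the MACE composite's severity hazard ratio exactly **1.6**. From
  the revascularization day onward the death/MI/stroke hazards are
  multiplied by the treatment effect: HR **0.46** in the severe stratum,
  1.0 otherwise (the interaction the outcome models must recover).
  Sampling is by piecewise-exponential inversion, so the generator matches
  the counting-process Cox analysis exactly.
* **Follow-up** — exponential censoring with mean 3.0 y truncated at 9 y
  and floored at 90 days (mirroring the exclusion of shorter event-free
  follow-up); the resulting mean ± SD ≈ 2.9 ± 2.5 y.

Hazards condition on the *measured* severe-CFC flag (the scored phantom),
not the latent lesion indicator, so the covariate entering the Cox model is
the true risk factor and recovery is free of measurement-error attenuation;
with the default levels the two differ with negligible probability anyway
(background pixels sit more than 6σ from the severe stress band at 10%
noise). Two further consistency rules: a death/MI/stroke drawn before the
revascularization day cancels the (unobserved) revascularization, and the
late-revascularization process has zero hazard inside the 90-day window —
revascularizations there are the exposure, not events. The latter makes the
composite MACE severity effect very slightly time-inhomogeneous
(≈1% of the log-HR, negligible against the n = 20,000 confidence interval).

Exclusion accounting applies ordered boolean flags (stress-inhibiting
medication/caffeine, nonstandard protocol, technical failure, <90 d
event-free follow-up), counts each scan under its first flag, and reports
per-reason counts with one-decimal percentages of the initial pool.

## Outcome models

* **Counting process** — each scan revascularized at day d ≤ 90 contributes
  rows (0, d] unexposed and (d, T] exposed (d in years, 90 d = 90/365.25 y);
  later revascularizations never set the exposure. Splits conserve at-risk
  time; the event indicator sits on the final row.
* **Cox regression** — partial likelihood on (start, stop] risk sets with
  left truncation (statsmodels `PHReg` with entry times). Efron tie
  handling by default, Breslow optional; on tie-free data the two agree to
  numerical precision. Wald CIs on the log scale. Before fitting, a
  colinearity screen reports pairs with |r| > 0.9 and raises on constant
  columns, near-perfect pairs (|r| > 0.9999) or rank deficiency, naming the
  aliased covariates rather than silently dropping them.
* **Interaction model** — main effects plus the exposure × severe product;
  the severe-stratum treatment HR is exp(β_exposed + β_product), with a
  delta-method Wald CI from the coefficient covariance.
* **Propensity score** — maximum-likelihood logistic regression of early
  revascularization on baseline covariates; scores are clipped into the
  open unit interval and usable as a Cox covariate.
* **HR-over-time curve** — HR(t) of exposure vs none with the other
  covariates at their medians: flat at exp(β_exposed) under plain
  proportional hazards; product terms named `exposed:<col>` contribute at
  the median of `<col>`, and an `exposed:logt` term (built by splitting
  intervals on a time grid and attaching exposure × log t) contributes
  log(t). The step approximation uses the covariate value at each
  sub-interval's end, so coarse grids bias the slope magnitude toward
  larger values while preserving its sign; recovery tests therefore check
  direction, not magnitude.
* **Group comparisons** — χ² on 2×2 counts (no continuity correction) for
  binary variables, Welch's unequal-variance t for continuous ones,
  two-tailed at α = 0.05; severity-size distributions between groups are
  compared by the two-sample Kolmogorov–Smirnov statistic.

Analysis is per-scan; each simulated patient contributes one scan. A
cluster-robust variance for repeated scans per patient is out of scope.

## Numerical and testing notes

* Fixed seeds make phantoms, cohorts and every pipeline output
  bit-identical; the pipeline manifest records the config digest and
  SHA-256 of every artifact.
* Recovery checks run at n = 20,000 scans: the Cox interaction fits
  recover the generating MACE (1.6) and DMS (1.3) severity HRs and the
  severe-stratum revascularization HR (0.46) within their 95% CIs.
* The null calibration runs 2,000 replicates of n = 200 with all severity,
  covariate and treatment effects set to 1: the severe-vs-not log-rank
  rejection rate at α = 0.05 stays within the binomial band. With only
  ~12 events per replicate the asymptotic log-rank is mildly conservative
  (long-run rate ≈ 0.042 in a 6,000-replicate side study), which the band
  tolerates. These replicates use the generator's analytic severity mode
  (no phantom imaging), since they calibrate the survival stage; the
  imaging stage is validated separately by the phantom round-trip and CoV
  checks.
* Problem sizes in the analysis drivers (2,000-scan cohort) are chosen to
  make the demonstration quick; all statistical claims in the tests use
  the sizes stated above.

## Limitations

Synthetic cohorts cannot validate clinical effect sizes — they verify that
the estimators recover what the generator put in, under a generator whose
assumptions (independent covariates, exponential baselines, one scan per
patient, independent cause-specific hazards, uniform revascularization
timing) are simplifications. Passing tests therefore demonstrate
correctness of the measurement and inference machinery, not clinical
validity of the thresholds. Tracer-kinetic flow quantification, attenuation
correction, coronary-calcium scoring and any rendering of clinical images
are out of scope; thresholds for the intermediate CFC bands are defaults to
be replaced by site-validated values.
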