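# cfcpet

Quantitative myocardial-perfusion severity scoring and outcome analysis for
rest–stress cardiac PET, exercised entirely on synthetic phantoms and
synthetic cohorts.

## What it does

In stable coronary artery disease, revascularization shows no mortality or
infarction benefit in unselected patients; the question is whether an
objective, regional severity threshold identifies the scans that do
benefit. `cfcpet` implements the analysis chain behind that question, for
researchers who want a tested, reusable reference implementation:

1. **Polar maps** (`cfcpet.polar_map`) — a fixed 1,344-pixel LV bullseye
   grid (21 rings × 64 sectors) holding absolute rest and stress perfusion
   in cc/min/g, with a documented CSV/JSON format, per-pixel coronary flow
   reserve CFR = stress/rest, relative images normalised to a robust
   maximum, and quadrant/artery decomposition.
2. **Coronary flow capacity scoring** (`cfcpet.cfc_scoring`) — each pixel
   is ranked on a five-band CFR scale and a five-band stress-perfusion
   scale and assigned the **milder** of the two ranks, so the severe
   category requires *both* CFR ≤ 1.27 *and* stress perfusion ≤ 0.83
   cc/min/g, and high stress flow rescues a low CFR caused by high resting
   perfusion. Scan-level outputs: percent of LV per category, extent flags,
   minimum quadrant averages (MQA) of CFR and stress flow, relative-defect
   sizes, and Kolmogorov–Smirnov comparison of severity-size distributions.
3. **Synthetic data** (`cfcpet.synthetic`) — target-pattern lesion phantoms
   (severe core + moderate/mild border rings) with ±10% multiplicative
   test–retest noise, and full cohorts: realistic covariate marginals,
   phantom-derived severity per scan, propensity-driven revascularization
   within 90 days, and piecewise-exponential death/MI/stroke/late-
   revascularization outcomes with a severity × revascularization
   interaction, all carrying their generating truth for recovery tests.
4. **Outcome models** (`cfcpet.outcomes`) — Kaplan–Meier and log-rank;
   counting-process construction in which revascularization at day d ≤ 90
   becomes a time-varying exposure switching on at d; Cox regression on
   (start, stop] risk sets (Efron or Breslow ties) with Wald CIs and a
   colinearity screen; logistic propensity scores; the interaction model
   with exp(β_exposed + β_interaction) as the severe-stratum treatment HR;
   hazard-ratio-over-time curves at median covariates; χ²/Welch-t group
   tables.
5. **Pipeline** (`cfcpet.pipeline`, `cfcpet.cli`) — simulate → score →
   analyze → report with YAML config, seeded bit-identical reruns, a
   SHA-256 manifest, and per-scan size–severity reports (no management
   advice is ever emitted).

The model recovered by the analysis stage is the proportional-hazards
specification

λ(t | x) = λ₀(t) · exp(βᵀx + β_sev·severe + β_rev·rev(t) + β_int·severe·rev(t)),

with rev(t) the 90-day revascularization exposure switching from 0 to 1 at
the revascularization day.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_phantom_fidelity.py
python analysis/03_fit_outcomes.py
python analysis/04_scan_reports.py
```

`01` prints the cohort accounting (5,000 scans, seed 1):

```
simulated 5000 scans (seed 1)
  severe CFC present: 18.4%
  revascularized within 90 d: 208 (4.2%)
  death events: 229
  dms events: 414
  mace events: 653
  mean follow-up: 2.85 y (SD 2.50)
```

18.4% of scans carry severe CFC; 4.2% were revascularized within the
90-day window (preferentially the severe scans, via the propensity model);
DMS = death/MI/stroke, MACE additionally counts late revascularizations.

`02` verifies the imaging stage:

```
severe boundary: CFR <= 1.27, stress <= 0.83 cc/min/g
  core   5.0% of LV -> severe scored 4.985% (1 pixel = 0.074%)
  core  12.0% of LV -> severe scored 11.979% (1 pixel = 0.074%)
  core  30.0% of LV -> severe scored 29.985% (1 pixel = 0.074%)
per-pixel CoV across 300 replicates at 10% noise: 0.1000
```

Noise-free phantoms are scored back to their constructed severe fraction at
1-pixel resolution, and the noise model reproduces the 10% test–retest
coefficient of variance.

`03` fits the Cox models and compares against the generating truth:

```
dms: severe-CFC HR 1.26 (95% CI 0.82-1.95; generating value 1.3)
  revascularization HR within the severe stratum: 0.21 (95% CI 0.08-0.57; generating value 0.46)
  log-rank severe vs not: chi2 = 0.5 (p = 0.48)
  severity-size KS, revascularized vs not: D = 0.63
mace: severe-CFC HR 1.56 (95% CI 1.13-2.14; generating value 1.6)
```

Each estimate brackets its generating hazard ratio; at this demonstration
size the severe-stratum treatment CI is wide — the dedicated recovery tests
run at n = 20,000, where all three effects are recovered within their 95%
CIs.

The same stages are available as a CLI (`cfcpet simulate|score|analyze|
report|run`), e.g. `cfcpet run --seed 1 --out runs/demo`.

## Layout

```
src/cfcpet/        library (polar maps, CFC scoring, synthetic data,
                   outcome models, pipeline, CLI)
analysis/          numbered study drivers writing to results/
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    models, defaults, design choices, limitations
```
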