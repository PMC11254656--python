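# ipdrecon

Reconstructed individual-patient-data (IPD) survival meta-analysis for
published oncology trials, built around the use case of first-line
immunotherapy in extensive-stage small cell lung cancer (ES-SCLC): phase-3
trials publish Kaplan–Meier (KM) figures for overall survival (OS) and
progression-free survival (PFS) but rarely deposit patient-level data.
`ipdrecon` inverts digitized KM curves plus their numbers-at-risk tables back
into per-patient `(time, event)` records, pools the reconstructed arms into
treatment-class groups (e.g. PD-L1 inhibitor + chemotherapy vs PD-1
inhibitor + chemotherapy), and compares each group against a designated
control group.

It is aimed at meta-analysts and trial statisticians who want the whole
chain — digitized coordinates → IPD → pooled comparison — as tested,
scriptable code rather than a sequence of manual tool invocations.

## What it computes

* **Curve inversion** (the core step): a Guyot-style interval-by-interval
  algorithm. Between consecutive at-risk times an integer censoring count is
  hypothesized and spread uniformly; event multiplicities at each digitized
  step are chosen so the running product-limit estimate tracks the published
  step values; the censoring count is selected so the implied number at risk
  matches the printed one. Published event totals (from the trial
  characteristics table) calibrate the tail beyond the last at-risk time.
* **Survival estimation**, written from first principles and cross-checked
  against lifelines and R `survival` in the test suite:
  * product-limit estimator `S(t) = ∏ (1 − dᵢ/nᵢ)` with Greenwood variance
    `S(t)² Σ dᵢ/(nᵢ(nᵢ−dᵢ))`;
  * median survival with Brookmeyer–Crowley 95% CI (log(−log) transform);
  * two-group log-rank test (hypergeometric variance);
  * single-covariate Cox proportional-hazards fit with Efron tie handling
    (HR with Wald 95% CI and p-value);
  * restricted mean survival time `RMST(τ) = ∫₀^τ S(t) dt` with the
    Greenwood-based area variance, and a normal-approximation test of the
    RMST difference between groups — informative when curves cross and the
    proportional-hazards assumption fails.
* **Safety comparison**: pooled adverse-event incidences per treatment class
  and Pearson chi-square (df = 1, no continuity correction) on the 2×2 table.
* **Synthetic trial generator**: parametric arms (exponential, Weibull,
  piecewise-exponential for delayed-separation/crossing curves) with uniform
  accrual, administrative cutoff and exponential dropout, rendered back into
  digitizer-style curve coordinates (Gaussian noise on the survival axis) and
  calendar-grid risk tables — so the whole pipeline can be validated against
  known ground truth.

The package ships a transcription of the study-characteristics table of the
nine ES-SCLC trials (11 immunotherapy cohorts, 2,677 patients) and the
five-group assignment with the PD-L1 class as control; loading them
reproduces the published pooled counts exactly.

## Worked example

Simulate a three-arm trial set (two control-class arms with a 12-month
median, one experimental arm with a delayed-onset advantage), render the
published-figure artifacts, then reconstruct and compare.

`sim.yaml`:

```yaml
seed: 11
accrual_months: 10
admin_censor_month: 28
dropout_rate: 0.005
endpoint: OS
render: {risk_interval_months: 3, coordinate_noise_sd: 0.005}
arms:
  - {arm_id: ctrl1, n: 150, hazard: {model: exponential, rate: 0.0578}}
  - {arm_id: ctrl2, n: 150, hazard: {model: weibull, shape: 1.1, scale: 16}}
  - {arm_id: exp1, n: 200, hazard: {model: piecewise, change_times: [4], rates: [0.06, 0.035]}}
```

`run.yaml`:

```yaml
seed: 11
rmst_taus: [12, 24]
endpoints: [OS]
control_group: control
studies:
  - {arm_id: ctrl1, enrollment: 150, curves: {OS: data/ctrl1_curve.csv}, risk_tables: {OS: data/ctrl1_risk.csv}}
  - {arm_id: ctrl2, enrollment: 150, curves: {OS: data/ctrl2_curve.csv}, risk_tables: {OS: data/ctrl2_risk.csv}}
  - {arm_id: exp1, enrollment: 200, curves: {OS: data/exp1_curve.csv}, risk_tables: {OS: data/exp1_risk.csv}}
groups:
  - {name: control, role: control, members: [ctrl1, ctrl2]}
  - {name: novel, role: experimental, members: [exp1]}
```

```bash
ipdrecon simulate --config sim.yaml --out data
ipdrecon run --config run.yaml --out out --plots
cat out/summary.md
```

This prints:

```
# Pooled reconstructed-IPD analysis

Control group: **control**
Comparisons: 1 (p-values unadjusted)
alpha = 0.05

## OS

| group | n | median (95% CI) | control median | HR (95% CI) | p |
|---|---|---|---|---|---|
| novel | 200 | 18.0 (14.8-24.3) | 12.0 (10.0-14.6) | 0.65 (0.51-0.82) | 0.000 |

- OS RMST(tau=12) novel vs control: diff 0.37 m (95% CI -0.38 to 1.12), p = 0.335
- OS RMST(tau=24) novel vs control: diff 2.19 m (95% CI 0.57 to 3.82), p = 0.008
```

Reading the output: the experimental group's reconstructed median OS is 18.0
months against 12.0 for the pooled control, with a Cox HR of 0.65 — the
simulated advantage (true HR ≈ 0.7) is recovered from nothing but the
rendered curves and risk tables. The 12-month RMST difference is small
(curves have barely separated by then) while the 24-month difference of 2.2
months is significant, the typical signature of a late-separating benefit.
`out/` also contains per-arm reconstructed IPD CSVs, a JSON report, a
reconstruction-fit audit and a manifest with input hashes and the seed.

The same `run` command accepts real digitized coordinates (e.g. from
WebPlotDigitizer) in place of simulated ones: `time_months,survival` curve
CSVs and `time_months,n_at_risk` risk CSVs per arm.

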