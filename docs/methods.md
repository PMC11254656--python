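# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `ipdrecon`.

## Problem setting

Published phase-3 oncology trials report time-to-event endpoints as
Kaplan–Meier figures with numbers-at-risk tables and event totals, not as
patient-level data. A meta-analysis that wants patient-level flexibility —
pooled KM curves, hazard ratios on pooled cohorts, restricted-mean
comparisons at common truncation times — must first invert those figures
into individual records. The package implements that inversion and the
downstream pooled comparison, with a simulator that generates trials with
known ground truth so every stage can be validated quantitatively.

## Curve inversion

Inputs per arm: a digitized step curve (time in months, survival
probability), an at-risk table whose first entry is the enrollment, and
optionally a published event total.

Preprocessing sorts coordinates by time, collapses duplicate times to the
minimum survival, clamps survival onto [0, 1], enforces monotone
non-increase by running minimum, and prepends the (0, 1) origin. The number
of clamped/reordered points is kept as an audit trail; heavy correction is a
sign of poor digitization.

The inversion walks the inter-risk intervals `[T_i, T_{i+1})` in order,
carrying the current at-risk count `n` and the running reconstructed KM value
`S`. For a hypothesized integer censoring count `c`, censor times are spread
uniformly over the interval interior; at each digitized step `(t_k, s_k)`
the event multiplicity is `d_k = round(n_k (1 − s_k / S))`, i.e. chosen
against the *running reconstructed* value rather than the raw published
ratio, so integer rounding is self-correcting and cannot drift within an
interval. The censoring count is selected by a monotone integer search from
zero upward minimizing the distance between the implied and the published
at-risk count at `T_{i+1}`; ties are broken first toward the candidate whose
final survival lands closest to the last published step in the interval,
then toward fewer censorings. Beyond the last risk time, censoring is
assumed only at the final curve time unless an event total is available, in
which case the tail censoring count is searched so the reconstructed event
count honors the published total.

A final calibration pass reconciles any residual difference between the
reconstructed and published event totals by flipping individual event
indicators. A flip leaves every at-risk count unchanged and perturbs the KM
curve by a relative `1/n(t)`, so flips are made at the earliest eligible
times, where the risk set is largest and the distortion smallest. Totals
that are arithmetically infeasible are approached as closely as possible
with a logged warning.

The reconstruction is fully deterministic: identical inputs produce
byte-identical outputs. Each arm gets a fit audit (maximum absolute
deviation and RMSE between the re-estimated KM and the digitized steps,
at-risk residuals at every published time, reconstructed event total).

Measured behavior (reproduced by the test suite and acceptance script): a
noiseless rendering with at-risk entries at every event time inverts exactly
(deviation 0 to machine precision); with survival-axis noise of sd 0.005 and
risk entries every 3 months, published at-risk counts are honored within ±1
and the re-estimated curve stays within ~0.01 of the digitized one except at
extreme-tail steps where a single subject is worth more than that.

## Estimators

All estimators treat ties between censorings and events at the same time by
the standard convention that events come first (a record censored at `t` is
at risk for events at `t`). Curve inversion produces many such ties, so the
convention is load-bearing and is asserted in tests.

* **Product-limit / Greenwood.** `S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i)`,
  `Var S(t) = S(t)² Σ d_i/(n_i(n_i − d_i))`. Where `S = 0` the variance is
  reported as 0.
* **Median with CI.** The median is the first event time with `S ≤ 0.5`.
  The 95% CI is the Brookmeyer–Crowley construction on the log(−log S)
  scale: each bound is the first event time at which the corresponding
  pointwise band crosses 0.5. Components the curve or band never reaches are
  returned as undefined, never as errors — "not reached" is a result.
* **Log-rank.** Unweighted two-group statistic with hypergeometric variance,
  df = 1.
* **Cox.** Single binary covariate (group indicator; control = 0), partial
  likelihood with Efron's tie correction, Newton–Raphson from β = 0,
  tolerance 1e-8, at most 50 iterations, steps clamped to ±5 to survive flat
  likelihoods. Efron is used because inversion-induced ties are heavy and it
  is the accepted default for that regime. Monotone likelihood (complete
  separation in time) and non-convergence are flagged on the result, never
  silently returned. The Wald 95% CI is `exp(β ± 1.96·se)`.
* **RMST.** Area under the KM step function on `[0, τ]`, with variance
  `Σ_{t_i ≤ τ} A_i² d_i/(n_i(n_i − d_i))` where `A_i` is the area between
  `t_i` and `τ`. A `τ` beyond the last observed time raises — the package
  never extrapolates silently. The difference test between two groups is a
  two-sided normal approximation on `diff/√(var_a + var_b)`.
* **Chi-square.** Pearson on the pooled 2×2 table, df = 1, no continuity
  correction (pooled denominators in the intended use are in the hundreds).
  The computation is delegated to `scipy.stats.chi2_contingency`; tests
  verify it against the closed form `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`.

Cross-validation: the product-limit curve matches lifelines to ~1e-15, the
Greenwood standard error and the Efron Cox fit match R `survival`
(`coxph` with `eps = 1e-12`) to ~1e-16 and ~1e-12 respectively. lifelines'
own Cox optimizer stops at a looser precision (~3e-6 on these fixtures),
which is why R is the oracle for the tight Cox comparison.

## Pooling and comparisons

Arms of one treatment class are pooled by concatenating their reconstructed
records into a unified cohort; each record keeps a tag naming its source
arm. Comparisons are pairwise against the single designated control group:
Cox HR (HR < 1 means lower hazard in the non-control group), per-side
medians, and RMST differences at each configured truncation time (defaults
12 and 24 months). P-values are reported unadjusted; the report header
states the number of comparisons so the reader can judge multiplicity. A
study-stratified Cox variant exists behind the `stratify_by_study` config
flag, off by default, as a deliberate deviation from naive pooling for
sensitivity analyses.

## Synthetic-data model

The generator emulates what a published figure gives a digitizer:

* latent event times from exponential (constant hazard), Weibull, or
  piecewise-exponential hazards — the last produces the delayed-separation
  and crossing shapes typical of immunotherapy trials, the very motivation
  for reporting RMST alongside hazard ratios;
* uniform accrual over `accrual_months` with one administrative cutoff at
  `admin_censor_month` (calendar scale), plus exponential loss to follow-up
  at `dropout_rate` per month — together these reproduce the right-tail
  censoring pattern and heterogeneous follow-up of real trials;
* rendering: the exact KM step values, optionally thinned, perturbed with
  Gaussian noise (default sd 0.005 on the survival scale — roughly the
  pixel-level error of a careful digitization of a full-height figure),
  clipped, and re-monotonized; at-risk tables on a 3-month calendar grid,
  matching the typical figure layout.

Noise is applied to the survival axis only; time-axis error is second-order
for a step curve, and exact times keep the renderer invertible so round-trip
tests are sharp. One integer seed drives everything; per-arm streams are
`default_rng([seed, arm_index])`.

What the simulator does not model: covariates (the analysis uses none),
informative censoring, digitizer time-axis error, and reader-specific
systematic bias. Passing the validation suite therefore demonstrates that
the pipeline is correct *given* faithful digitized coordinates; it says
nothing about the quality of any particular manual digitization.

Validation problem sizes were chosen to keep the full suite fast while
leaving wide Monte-Carlo margins: single-arm checks use n = 200, recovery
checks 20 replicates of 300 patients/arm (measured median HR error ~0.004
against a 0.03 bound; median-survival error ~0.04–0.13 months against 0.3),
null-calibration checks 1000 replicates (rejection rates 0.046–0.059 against
a 0.03–0.07 band), and closed-form checks 20,000 patients.

## Known limitations

* Reproducing the published clinical numbers of the motivating ES-SCLC
  analysis (medians 14.3 vs 14.5 months, HRs 0.94/0.96, etc.) requires the
  digitized coordinates of nine external publications' figures, which are
  copyrighted artifacts not shipped here; the pipeline accepts such
  digitizations as ordinary input. The shipped study table does reproduce
  all published *count* totals exactly.
* The safety module compares pooled incidences only; per-study safety
  denominators are often unpublished, so the shipped AE inputs are synthetic
  and heterogeneity across studies is not modeled.
* Inversion quality degrades where figures carry little information: very
  sparse risk tables, heavy tail censoring, or steps worth several percent
  of survival each. The fit audit quantifies this per arm; downstream
  results should be read together with it.
* The Cox model is a single group indicator — no covariate adjustment,
  stratification beyond the optional study strata, or frailty.
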