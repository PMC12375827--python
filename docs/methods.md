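# Methods

## Decision problem and model structure

The package evaluates first-line pembrolizumab + gemcitabine/cisplatin
against gemcitabine/cisplatin alone in advanced biliary tract cancer from
the healthcare-system perspective of China, Japan, the United States and
Switzerland. The economic model is a partitioned survival analysis
(PartSA) with three states — progression-free (PFS), progressed disease
(PD), dead — on a 21-day cycle over a 10-year horizon. With a 21-day
cycle, ceil(10 × 365.25 / 21) = 174 cycles cover the full horizon without
truncating the last partial year; by then state occupancy of both arms is
almost entirely "dead", so the horizon is effectively lifetime.

Occupancy is read off the two arm-level survival functions: π_PFS =
min(S_PFS, S_OS) (the min-clamp guards against crossing extrapolations),
π_death = 1 − S_OS, π_PD the remainder. The three shares sum to one by
construction at every cycle; this is asserted to 1e-12 in tests.

**Evaluation convention.** State membership is evaluated at each cycle
start (t_i = i × 21/365.25 years, so cycle 0 contributes the intact cohort).
No half-cycle correction is applied by default; setting
`ModelSettings(half_cycle_correction=True)` moves every evaluation to the
cycle midpoint, which quantifies the discretization sensitivity without
changing any other code path. Cycle-start evaluation was chosen because it
is the default of the mainstream decision-modelling tools this analysis
mirrors.

## Survival evidence pipeline

### Synthetic trial generation

No per-patient data or deposited accessions exist for the underlying
trial, and published fitted-parameter supplements are not available, so
the package ships a generator that emulates the trial's published shape:
two arms of n = 533 (experimental) and n = 536 (control); experimental-arm
median OS 12.7 months and median PFS 6.5 months.

Per subject, PFS is drawn from an exponential (default) or Weibull
distribution whose median equals the target; OS = PFS + an independent
exponential post-progression survival whose rate is calibrated by
root-finding on the analytic convolution so that the *OS distribution's*
median equals the target. This enforces PFS ≤ OS per subject by
construction. Exponential defaults were chosen because a median is the
only published calibration target per endpoint, and an exponential is
fully determined by its median (rate = ln 2 / median); Weibull generation
exists for model-selection tests.

Censoring: each subject receives one censoring time shared by both
endpoints — administrative at 30 months (a plausible trial follow-up
window), or earlier with probability 0.05 (dropout, uniform before the
horizon). These two defaults produce risk tables with realistic attrition
for reconstruction testing; they are not published values.

The control-arm medians (OS 10.9, PFS 5.6 months) are **package defaults,
not published values** — the source trial publishes no control-arm
medians. They were fixed once so the experimental arm dominates on
survival, and are ordinary parameters of `ArmSpec`. Quantitative
end-to-end outputs therefore approximate the published base case only in
order of magnitude; the qualitative conclusion (ICER far above every WTP
threshold) is insensitive to any plausible choice.

All sampling is inverse-CDF on a fixed uniform stream
(`numpy.random.default_rng(seed)`), which gives bit-reproducibility and a
useful monotonicity property: at fixed seed, raising a median can only
lengthen each subject's time.

### Digitized export and pseudo-IPD reconstruction

`export_digitized` evaluates the Kaplan–Meier curve (lifelines) on a time
grid and counts numbers at risk at fixed intervals — exactly the
information a published figure carries. The pipeline uses a half-month
grid and a 3-month risk table; reconstruction accuracy tests use the
coarser 30-point grid / 6-month table to show the method tolerates
figure-quality input.

`reconstruct_ipd` inverts that information with the Guyot-style
interval-by-interval scheme: within each risk-table interval, censorings
are assumed uniform, their count iterated until the implied number at risk
at the next table time matches the published one, and event counts at each
digitized step solved from the product-limit drop ratios. After the last
table time no censoring is assumed before the final plotted point. An
optional total-event constraint is enforced exactly by flipping the
latest-time censored records to events (or vice versa) — equivalent in
effect on the KM curve at table times to the published final-interval
adjustment, and simpler to verify. Digitized input is cleaned before use:
survival clipped to [0, 1] and flattened by a running minimum, with
increases above 0.005 (beyond hand-digitization jitter) rejected as real
inconsistencies. Without a risk table the function falls back to a
no-censoring assumption with a loud warning and requires the arm size.

Round-trip accuracy (generate → export → reconstruct → KM) is ≤ 0.02
maximum absolute deviation at risk-table times for n = 200 arms across 20
seeds; observed deviations are ≈ 0.003.

### Parametric fitting and selection

Five families are fitted per endpoint and arm — exponential, Weibull,
gamma, log-logistic, lognormal — by maximising the right-censored
log-likelihood Σ_events log f + Σ_censored log S. Optimization runs on a
transformed scale (log for positive parameters; identity for the
lognormal μ) so positivity needs no constraints, from deterministic
method-of-moments starts (the exponential start is its closed-form MLE),
via Nelder–Mead polished by BFGS; fits are exactly reproducible. The
covariance of the estimator is the inverse of a central-difference Hessian
of the negative log-likelihood on the transformed scale and is retained
for PSA; a non-positive-definite Hessian yields no covariance (the PSA
then holds that curve fixed).

Model selection minimises AIC (= 2k − 2ℓ) by default, with BIC
(= k ln n − 2ℓ) available via `--criterion`; AIC is the default because
the source analysis reports using both without stating a conflict rule.
Ties go to fewer parameters, then to a fixed family order. The gamma
median has no closed form and is found by bracketed root-finding
(tolerance 1e-10); other medians use closed forms.

lifelines' univariate parametric fitters serve as an independent MLE
cross-check in the test suite; they are never the implementation.

## Cost and QALY accrual

All monetary values are USD. The source price lists' exchange rates are
recorded as comments in the config files and never applied.

* **First-line drugs** (to PFS occupants): pembrolizumab 200 mg flat on
  day 1 (max 35 cycles); gemcitabine 1,000 mg/m² and cisplatin 25 mg/m² on
  days 1 and 8 (cisplatin max 8 cycles; gemcitabine uncapped, since only
  cisplatin and pembrolizumab carry published caps). mg/m² doses scale by
  the country's mean body surface area; doses round **up** to whole vials
  per administration (no vial sharing — the conservative standard
  assumption). Vial sizes are explicit per drug and country (Japan prices
  cisplatin per 50 mg pack, Switzerland fluorouracil per 500 mg pack).
* **Administration** (per cycle, to PFS occupants): the "administration"
  cost row doubles as the disease-management cost named in the source's
  cost list, which has no other matching input row.
* **Examination** (per cycle, to all alive).
* **Second line** (per cycle, per unit PD occupancy): a fixed-proportion
  mix — FOLFOX for 47%/49% (experimental/control), post-progression
  immunotherapy for 0.9%/1.1%, best supportive care for the remainder. A
  PartSA cannot track time-in-state without tunnel machinery, so
  second-line costs accrue for the whole PD occupancy; this is likely
  conservative (it overstates second-line duration). FOLFOX uses standard
  mFOLFOX6 dosing (oxaliplatin 85, leucovorin 400, fluorouracil
  2,800 mg/m² per 14-day course) prorated ×1.5 to the 21-day cycle — the
  source names the regimen but no doses; both are config-overridable in
  code. Post-progression immunotherapy is costed as one 200 mg
  pembrolizumab administration per cycle (agent unnamed in the source).
* **Adverse events**: the four grade ≥3 events with incidence ≥ 9%
  (neutropenia, leukopenia, thrombocytopenia, anemia), costed once —
  probability × unit cost summed over events — in the first cycle only.
  AE disutilities default to zero: the source mentions them but tabulates
  no values.
* **End of life**: a one-time cost applied to each cycle's incremental
  deaths, discounted at that cycle.
* **QALYs**: (21/365.25) years × (u_PFS π_PFS + u_PD π_PD) per cycle.

Discounting multiplies every cycle-i flow by (1 + r)^(−i × 21/365.25),
with r the country's annual rate (0.05 China, 0.03 elsewhere).

ICER = ΔCost/ΔQALY when the ratio is meaningful; otherwise an explicit
status is reported — *dominant* (cheaper, more effective), *dominated*
(dearer, less effective), *undefined* (|ΔQALY| < 1e-12 with a real cost
difference). Results serialize these as tokens, never numbers.

## Uncertainty analysis

* **One-way DSA**: every cost, probability and utility varied to ±20% of
  base (bounded parameters capped at 1), all else held at base; bars
  sorted by |ICER_high − ICER_low|. Cross-field config invariants are
  deliberately not re-validated for excursions (e.g. u_PD may transiently
  exceed u_PFS). A failed extreme run is recorded as NaN, not fatal.
* **PSA**: 5,000 draws by default. Costs ~ gamma, probabilities and
  utilities ~ beta, moment-matched so every parameter's mean equals its
  base value; spreads derive from the DSA ranges treated as 95% intervals,
  sd = (high − low)/(2 × 1.96). Survival parameters are resampled per draw
  from each fit's asymptotic multivariate normal on the transformed scale
  (on by default; `--freeze-curves`/`vary_survival=False` disables it,
  since the source does not state whether its PSA varied the curves).
  Infeasible assignments fail fast before any model run. Fixed seed gives
  a bit-identical draw sequence.
* **CEAC**: fraction of draws with positive net monetary benefit,
  λ·ΔE − ΔC > 0 (strict), on a 0–1.2 million USD/QALY grid of 201 points —
  wide enough to show every country's acceptability turning point.
* **ICE quadrants**: counts by sign of (ΔE, ΔC); boundary zeros count to
  the positive side (documented, tested).
* **Price scenarios**: pembrolizumab's vial price scaled by (1 − r) for
  r in {10, …, 90, 95}% — the scaling automatically reaches the
  post-progression immunotherapy, priced off the same vial. The smallest
  reduction achieving ICER ≤ WTP is found by bisection to 0.1% after
  endpoint bracketing, valid because the ICER is affine and strictly
  decreasing in the price.

## Problem sizes and numerical choices

The shipped defaults run the full published scale: n = 533/536 subjects,
174 cycles, 5,000 PSA draws. The complete pipeline takes a few seconds;
a full PSA about 15 s. Reconstruction accuracy tests use n = 200 arms over
20 seeds, and model-selection consistency tests n = 1,000 over 20 seeds —
sizes at which the checked tolerances (0.02 KM deviation, 5% parameter
recovery, ≥ 90% correct selection) are comfortably discriminating.

Tolerances: occupancy conservation 1e-12; median root-finding 1e-10;
exponential MLE agreement with the closed form 1e-8; digitization
monotonicity tolerance 0.005; ICER sign tolerance 1e-12.

## What the synthetic data does and does not show

The generator reproduces arm sizes, published experimental-arm medians,
the PFS ≤ OS constraint, administrative censoring and a digitized-figure
export path. It does **not** emulate subgroup structure, biliary-tract
cancer subtypes, covariate-dependent or non-proportional hazards, country-
specific survival differences, or the exact shapes of the published KM
curves. Passing tests therefore demonstrate that the pipeline is correct
and calibrated on data with the published summary geometry — not that it
reproduces the published base-case numbers, which depend on fitted
parameters available only in an unavailable supplement. The worked-example
China ICER (~$357k/QALY with the default seed) accordingly matches the
published $542k/QALY in conclusion and order of magnitude, not in value.

## Known limitations

* Control-arm survival calibration is assumed, not sourced (see above).
* Second-line cost accrual over the entire PD occupancy overstates
  treatment duration; a tunnel-state extension would bound it.
* Time-constant parametric hazards are fitted to the whole follow-up;
  no spline/cure/waning structures are considered.
* AE disutilities and second-line administration costs are excluded
  (hooks exist; defaults zero), mirroring the tabulated inputs.
* The reconstruction assumes censoring uniform within risk intervals;
  heavily clustered censoring would degrade accuracy.
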