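# Methods

This note records the statistical procedures the package implements, the
defaults it ships, the design decisions that were genuinely open, and what
the synthetic-data experiments do and do not establish.

## Cohort model and derived variables

A patient record carries the six tree variables, a serial-creatinine history,
enrolment/exit dates (day precision; follow-up in years is days/365.25) and a
single terminal outcome: RRT inception, death, loss to follow-up, or
administrative censoring.  Inclusion requires at least 6 months of follow-up
and at least four creatinine measurements with strictly increasing dates;
rows violating these rules are rejected with per-row diagnostics, never
silently dropped.

Proteinuria is coded present if **any** available component exceeds its
threshold (dipstick > 20 mg/dL, 24-h protein > 0.3 g, microalbuminuria
> 20 mg/L); comparisons are strict, missing components are non-informative,
and the status is undeterminable only when all three are missing.  The
coding is monotone: raising a component can never remove proteinuria.

Per-visit eGFR is recomputed from creatinine with the CKD-EPI 2009 creatinine
equation (no race term: the cohorts the package emulates come from a single
Italian region), with the patient's age advanced by the elapsed time.  Which
equation the original registry stored at entry is not documented, so loaders
accept pre-computed eGFR columns as an alternative.  The annual eGFR slope is
the OLS coefficient of eGFR on time in years; it is invariant to calendar
shifts of the visit dates.

CKD stages use the KDIGO bands with stages 1–2 merged — ≥60, 45–59 (3a),
30–44 (3b), 15–29 (4), <15 (5) — five ordered categories (4 model df).
eGFR-progression categories (not standardised anywhere) default to five
bands: ≤−5, (−5,−3], (−3,−1], (−1,+1], >+1 mL/min per year, again 4 df;
both sets are configurable.

## The classification tree

The tree is applied as a frozen algorithm; no induction, pruning or split
search.  Every internal comparison sends "≤" left.  The eGFR (33.652) and
phosphate (4.3) thresholds are the published ones; the age threshold is not
published as a number, so it defaults to 67 y — consistent with the node age
distributions (the "younger diabetic" node averages 61 ± 6, the "older male"
node 78 ± 6) — and is overridable.  Analyses that depend on behaviour near
the split must set it explicitly.

Proteinuric patients with eGFR at or below the split and a missing phosphate
cannot be placed (about a fifth of registry phosphate values are missing);
they are excluded from survival analyses but always counted and listed in
assignment reports.

## Survival estimation

All estimators use delayed entry at 0.5 years by risk-set truncation: event
times stay on the enrolment clock, risk sets simply start at 6 months.  For
validation analyses both cohorts are administratively censored at a 4-year
horizon so follow-up lengths are comparable.

**Kaplan-Meier** curves (lifelines) censor the competing outcome at its
time; the competing-risks module is the corrective companion.  Confidence
bands use the Greenwood variance on the log(−log S) scale.

**Cox regression** is implemented in-package (Newton-Raphson, at most 100
iterations, convergence when the relative log-likelihood change is below
1e-9, step-halving on overshoot).  Ties use the Breslow approximation by
default — the convention of the commercial package in which such registry
analyses are typically run — with Efron available by flag.  Monotone
likelihoods (complete separation) raise instead of "converging".  The fit
returns both the inverse-information covariance and a cluster sandwich
covariance (score residuals summed within nephrology units); with no
cluster column every subject is its own cluster, giving the ordinary robust
covariance.  Under Efron ties the sandwich uses Breslow-form residuals
evaluated at the Efron optimum.  The baseline survival is the exponentiated
Breslow cumulative hazard at the reference covariate pattern.  AIC is
−2ℓ + 2·df; BIC uses the **number of events** as the sample size (the
survival-analysis convention; worth stating because goodness-of-fit tables
rarely say).

**Aalen-Johansen** cumulative incidence is computed directly from its
increments S(u⁻)·d_k(u)/n(u), so the conservation identity
Σ_k CIF_k(t) + S(t) = 1 holds to machine precision at every event time, and
reduces exactly to 1 − KM when only one cause is present.

**Fine–Gray** regression is implemented in-package (no installed Python
library provides it).  Subjects failing from a competing cause remain in
later risk sets with IPCW weights G(u⁻)/G(s⁻) from the Kaplan-Meier
estimate of the censoring distribution; administrative censoring (plus loss
to follow-up whenever loss is not itself modelled as a cause) feeds the
weight model; the cause set is a parameter.  Weights below 1e-6 are clipped
to zero to avoid late-time blow-up.  With zero competing events the fit
collapses exactly to the cause-specific Cox model (asserted to 1e-8 in the
suite).  Robust covariance is the same cluster sandwich as the Cox side —
chosen for consistency, since the original report does not say — and omits
the correction terms for estimating the weights; those terms reduce
variance, so the reported intervals are mildly conservative (observed
coverage ≈ 0.93–0.96 at nominal 0.95 in the recovery experiments).

## Validation pipeline

*Discrimination*: per-node KM curves plus, for every node pair, the maximal
absolute survival difference over the horizon and a log-rank statistic.
The underlying assessment in this literature is visual; these numeric
summaries are this package's addition and are labelled as such in reports.

*Calibration by baseline-survival transfer*: expected curve for node j in
the validation cohort = S₀(t)^exp(β_j) from the derivation node model;
observed = the node's validation KM curve.  Curves are compared on a 0.5-year
grid from 0.5 to 4.0; a sup-gap above 0.05 flags miscalibration.  The 0.05
threshold is a package choice (graphical assessment has no number); the
self-consistency experiments below show the null noise floor sits well under
it at the sample sizes used.

*Interaction models*: 6 node indicators + cohort indicator + 6 interactions,
reference node chosen automatically as the node with the most outcome events
(overridable), cluster-robust by center, fitted on both the cause-specific
(Cox) and subdistribution (Fine–Gray) scales.

*Risk ranking*: HR < 0.5 very low, [0.5, 0.8) low, [0.8, 2] high, > 2 very
high.  The published band description omits (1.5, 2]; it is mapped to
"high" here because only the single node with HR 2.93 carries the "very
high" annotation.  The ranking is monotone in HR.

*Model comparison*: univariate Cox fits on nodes (6 df), CKD stage (4 df)
and slope category (4 df) with AIC/BIC; ordered categories with zero events
are collapsed into a neighbour with a warning rather than fitted to a
divergent coefficient.

*Matching*: exact on (node, follow-up month), month = days/30.4375 rounded
half-up; greedy pairing in sorted-patient-id order makes results
deterministic and order-invariant; an optional caliper allows nearest-month
pairing.  Matched subsets have identical node distributions by construction.

*Incidence-rate ratios*: IRR = rate_validation/rate_derivation with the
log-normal interval exp(log IRR ± 1.96·√(1/e₁ + 1/e₂)); person-time is
counted from the 6-month entry.

## Synthetic cohorts

The generator emulates the registry's published structure:

* **Node mix** — default membership probabilities are the derivation-cohort
  shares (230, 378, 152, 264, 90, 410, 741 of 2265).
* **Covariates** — age, baseline eGFR and phosphate are normals at the
  published per-node means/SDs, truncated to the node's defining predicate
  region (with a one-rounding-unit guard so stored, rounded values stay on
  the correct side of each split); diabetes and sex are Bernoulli at the
  published prevalences where the tree leaves them free, and degenerate
  where it does not (no diabetics in node 4, only diabetics in node 5, no
  males in node 6, only males in node 7).  Every generated patient therefore
  round-trips through the classifier to its generated label.
* **Event times** — competing exponential cause times (RRT, death, loss)
  started at the 6-month entry; the memoryless shift enforces the inclusion
  criterion exactly.  Per-node hazards are calibrated in closed form,
  λ = −ln(1−p)/5.5, so that the 6-year KM failure probabilities with the
  competing outcome censored reproduce the published per-node risks (e.g.
  71.9% RRT for the proteinuric/low-eGFR/high-phosphate node).  The printed
  6-year KM risks are used as calibration targets rather than the crude
  event counts because the two are mutually inconsistent under any constant
  competing hazards — crude counts depend on the unpublished censoring
  pattern — and the KM risks are the quantities the validation actually
  compares.  Where only a range is published, the within-range ordering
  follows the crude counts.  Loss to follow-up defaults to ~10% by 6 years;
  the real pattern is unpublished and this value is a stand-in.
* **Censoring** — administrative censoring uniform between 0.5 and 10 years.
* **Clustering** — patients spread over 13 centers; optional log-normal
  center frailty multiplies all cause hazards.
* **Creatinine series** — 4+ visits spread over follow-up; eGFR follows
  baseline + slope·t (slope normal at the published per-node eGFR-change
  mean/SD) plus N(0, 2) observation noise, floored at 2, then inverted
  through CKD-EPI to creatinine.

`TrueParams` exposes the implied hazards, log hazard ratios and 6-year
risks, so recovery experiments compare estimates with known truth.
`recovery_experiment` adds a two-group harness: for the Cox estimand, latent
exponential cause times with a known cause-specific HR; for the Fine–Gray
estimand, data drawn from the Fine–Gray model itself (baseline CIF
1 − (1 − p(1 − e^{−λt}))^{exp(βx)} with plateau p = 0.45, time scale
λ = 0.35/y, competing rate 0.12/y), so β is the true log-SHR by
construction.

**What the generator does not model**: within-patient trajectory
nonlinearity, treatment effects, covariate-dependent censoring, calendar
trends within an enrolment wave, or real registry missingness beyond an
optional phosphate-missing rate (applied only where the tree never needs
phosphate, to keep cohorts fully assignable).  Passing tests therefore show
the estimators and the pipeline are correct under the stated generating
process, not that the clinical model is valid on new registry data.

## Experiment sizes and numerical choices

* Calibration experiments allocate patients **equally across nodes**: the
  sup-gap bound is per node, and at the registry mix the smallest node
  (4.4%) would be dominated by its own KM noise rather than by the transfer
  being tested.  Self-consistency uses n = 5000 (observed max sup-gap ≈
  0.01–0.02); the engineered ×0.5 hazard-shift experiment uses n = 20000 so
  the null noise floor sits clearly below the 0.05 flag threshold while the
  shifted node's gap (~0.1) sits clearly above.
* Fine–Gray recovery uses 100 replicates of n = 2000.
* Convergence: Newton with step-halving, tol 1e-9 (relative), max 100
  iterations; coefficients beyond ±15 on the log scale are treated as
  separation.
* Tie-breaks: matching pairs by sorted patient id; reference-category
  selection by maximal event count with pandas' stable idxmax on the node
  order.
* Degenerate inputs: empty cohorts, single-node discrimination, zero-margin
  tables, all-tied rank tests and zero-event categories raise or warn
  explicitly rather than returning numbers.

## Known limitations

* The Fine–Gray robust variance omits the weight-estimation correction
  (conservative in the experiments run here).
* Efron-tie sandwich uses Breslow-form residuals at the Efron optimum.
* Fine–Gray with delayed entry truncates risk sets at entry; since every
  cohort here shares the single 6-month entry time this is exact for the
  package's own pipelines, but staggered per-subject entry with competing
  risks would need additional weight adjustment.
* The matched-pair selection within an oversubscribed cell is deterministic
  (sorted ids), one of many valid 1:1 matchings.
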