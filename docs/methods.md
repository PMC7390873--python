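# Methods

## Model structure

`hfcea` implements a decision-analytic state-transition (Markov) cohort model
comparing sacubitril-valsartan (Sac-Val) with enalapril for heart failure with
reduced ejection fraction (HFrEF), from the perspective of a Chinese patient,
in 2019 US dollars.

The state space has six states: NYHA functional classes I–IV and two
absorbing death states (cardiovascular and non-cardiovascular). The death
split is an internal accounting refinement — every reported mortality figure
aggregates the two. Cycles are monthly; the base case runs 120 cycles
(10 years) for a cohort entering at age 64 with the NYHA distribution
4.5% I / 71.6% II / 23.1% III / 0.8% IV. Within a cycle a patient can be
hospitalized, suffer a 30-day readmission, change NYHA class, die of
cardiovascular (CV) causes, or die of other causes. Hospitalization and
readmission carry one-time costs and utility decrements but do not change the
health state; NYHA class is the only living-state dimension.

## Hazards and transition probabilities

* **CV death** follows an exponential survival model fitted to the comparator
  arm of the pivotal trial, S(t) = exp(λt) with λ = −0.00577 per month,
  giving a constant monthly probability 1 − e^λ ≈ 0.005753 for the NYHA I/II
  baseline. NYHA III and IV multiply this probability by relative risks
  1.372 and 1.640.
* **Hospitalization** follows a Weibull model S(t) = exp(λ·t^γ) with
  γ = 1.02685; the conditional monthly probability in cycle t is
  1 − exp(λ(t^γ − (t−1)^γ)), slowly increasing because γ > 1. NYHA III/IV
  hazard ratios are 1.71 and 3.4.
* **Treatment effect**: the Sac-Val arm applies hazard ratios 0.79
  (hospitalization) and 0.80 (CV death) to the baseline probabilities on the
  rate scale, p′ = 1 − (1 − p)^HR, chained multiplicatively with the class
  hazard ratios. Relative-risk rows multiply the probability directly. A
  `settings.hr_scale` switch enables probability-scale multiplication for
  sensitivity of conclusions to this choice.
* **Background non-CV mortality** is an age-indexed annual life table,
  treated as a left step function of age and converted to a monthly
  probability as 1 − (1 − p_year)^(1/12). Age advances deterministically:
  age(t) = 64 + (t − 1)/12.
* **NYHA class change** occurs with monthly probability 0.0088 (enalapril) or
  0.0068 (Sac-Val); the destination follows a fixed conditional matrix
  (e.g. a class-IV change always moves to class III).

### Calibration of the hospitalization scale

The published Weibull coefficients (λ = −0.00097, γ = 1.02685) imply a mean
monthly hospitalization probability of about 0.0011 over the 10-year window,
while the sensitivity range printed for the same row (0.00868–0.0145) is on a
monthly-probability scale an order of magnitude higher; the two cannot both
describe the base-case hazard. The package makes the *mean monthly
hospitalization probability over the fixed 120-cycle reference window* the
working parameter (`p_hosp_monthly`) and re-solves λ against it
(`weibull_mode: calibrated`); γ is always kept as printed. The default anchor
is 0.001102447925 — exactly the window mean implied by the published
coefficients — because a calibration of the anchor against the published
base-case totals (costs, QALYs, ICER) selects the coefficient-implied scale,
not the printed band: with the band's values, hospitalization spending alone
exceeds the published incremental cost, and the published tornado, in which
baseline hospitalization is not among the top drivers, is only consistent
with the small coefficient-implied probability. The printed band is retained
verbatim as the parameter's one-way and probabilistic sensitivity range (it
is the only uncertainty statement available for this input), which is why
this one parameter is exempt from the `low ≤ value ≤ up` validation warning.
`weibull_mode: raw` bypasses the anchor and uses λ as printed (audit mode;
the two modes coincide at the default anchor up to solver tolerance).

### Competing events within a cycle

Events resolve by conditional sequencing — CV death first, then non-CV death
among survivors, then NYHA change among cycle survivors — with probabilities
combined multiplicatively, which guarantees row-stochastic transition
matrices without renormalization. Hospitalization and readmission are
evaluated among cycle survivors and enter the event decomposition rather than
the matrix.

### Readmission conditioning

The monthly readmission probability 0.0147 is, by default, applied
*unconditionally* to every cycle survivor (`readmission_mode:
unconditional`), matching the source of the figure: an annual readmission
rate of 16.23% from a national insurance cohort, 1 − (1 − 0.0147)^12 ≈ 0.163.
The alternative `per_hospitalization` mode attaches the probability to each
hospitalization in the same cycle (a literal 30-day-readmission reading).
The unconditional reading was selected by the same base-case calibration: it
reproduces the published cost totals, whereas the conditional reading leaves
roughly $400 per patient of published comparator cost unexplained. The
readmission is attached to the cycle in which it occurs so the cohort
recursion and the patient-level simulation agree exactly in expectation.

## Accrual, discounting, half-cycle correction

* State-occupancy accruals (utility/12 per month alive, monthly drug cost and
  one outpatient visit of $41.56 per living patient) use the trapezoid
  half-cycle correction: the average of start- and end-of-cycle occupancy.
* One-time event accruals (hospitalization $1,920.49, readmission $1,340.05 —
  of which the patient pays the inpatient copay share 0.3 — and a 0.1 QALY
  decrement per event, `disutility_mode: per_event`) are applied per expected
  event without half-cycle correction.
* Everything accrued in cycle t is discounted at the cycle midpoint,
  (1.035)^(−(t − 0.5)/12), the convention the half-cycle correction implies.
* Dead states accrue nothing; there is no terminal-care cost.
* Drug copays: the "Medicare copay ratio" on drugs is the *reimbursed* share
  (Sac-Val: $85.61 × (1 − 0.8) = $17.12 patient-borne per month — forced by
  the published arithmetic), while the inpatient copay 0.3 is the
  *patient-paid* share of event costs (the only reading on which total costs
  are of the published magnitude); `settings.inpatient_copay_is_patient_share`
  flips the latter.

## Economics

ICERs are incremental cost over incremental QALY (intervention minus
comparator), with standard dominance flags when the increments disagree in
sign. Net monetary benefit is NMB(w) = w·ΔQALY − Δcost at willingness-to-pay
thresholds of $10,276 (GDP per capita) and $30,828 (3× GDP). Break-even
intervention prices solve NMB = 0 by bracketed root finding on the
patient-borne monthly cost over full paired model runs (tolerance $0.01); the
two-way price grid exploits the fact that QALYs are price-independent, so
each axis value needs one cohort run.

## Sensitivity analyses

One-way analysis re-runs both arms at each parameter's published bounds
(95% CIs, or ±5/10/20% bands as printed) and sorts by ICER span. The
probabilistic analysis fits, by moment matching with sd = (up − low)/(2·1.96):
beta distributions to probabilities and utilities, gamma to costs, and
log-normal to hazard/risk ratios (point estimate as the median,
σ = (ln up − ln low)/(2·1.96)). Event disutilities are sampled as a
beta-distributed magnitude rescaled to the printed band [0.08, 0.13] and
negated, since the beta family needs a bounded support. All parameters vary
independently and simultaneously; there is no correlation structure. Each
draw uses its own random substream spawned from the master seed, so results
are reproducible and order-independent; a probability sampled outside (0, 1)
is rejected and redrawn with a capped retry count. Degenerate ranges
(low = up) become point masses.

The published PSA summary reports mean QALYs of 4.21 for Sac-Val versus 4.51
for enalapril — the opposite ordering to every deterministic result in the
same source, almost certainly a transposition. The package therefore asserts
only the PSA cost means and the probability of cost-effectiveness, not the
PSA QALY means.

## Patient-level microsimulation (synthetic data and oracle)

The microsim draws individual patients through the identical monthly pathway
with the identical event sequencing and the identical half-cycle accrual
conventions, so its population means are unbiased Monte Carlo estimates of
the cohort totals — the package's central cross-validation requires agreement
within three standard errors at 200,000 patients. It also emits first
hospitalization and CV-death times with censoring indicators; censored
discrete-time maximum likelihood (geometric for the exponential model, exact
monthly interval probabilities for the Weibull) recovers the generating
coefficients, closing the generate → fit → regenerate loop.

What the synthetic data do not emulate: treatment discontinuation, adverse
events, covariate heterogeneity beyond NYHA class and age, seasonal or
calendar effects, and any correlation between a patient's successive events
beyond what the state structure carries. Passing tests therefore demonstrate
internal consistency of the implementation and recoverability of its
parameters, not external validity of the clinical inputs.

## Numerical choices and problem sizes

* Calibration root-finding: Brent's method on λ ∈ [−1, −10⁻³⁰⁰), xtol 1e-15;
  an anchor of exactly 0 returns λ = 0 (no hazard), used by degenerate test
  configurations.
* Break-even search: Brent's method, xtol $0.001, reported tolerance $0.01;
  with no sign change in [0, 150] the nearer boundary is reported and
  flagged.
* Weibull recovery: Nelder-Mead over (log(−λ), log γ) started at the
  exponential MLE, observations collapsed to per-month counts.
* Default sizes: 120 cycles; 10,000 PSA draws (≈40 s single-threaded);
  200,000 microsim patients per arm (≈4 s) giving QALY standard errors near
  0.003; recovery tests use 50,000 patients.
* Matrix row sums are validated to 1e-9 at construction; occupancy mass is
  conserved to the same tolerance.

## Known limitations

* The base case reproduces published totals to within ~5% (costs) and ~3%
  (ICER), not exactly: the original TreeAge implementation's Weibull
  parameterization, half-cycle details and readmission handling are not
  fully recoverable from its description, and the conventions above are the
  package's documented resolution.
* No treatment discontinuation, adverse events, or multi-strategy frontier;
  no currency conversion or inflation adjustment; parameters are sampled
  independently in the PSA.
* The life table ends at 85 (then jumps to certain death at 100), so
  simulations beyond ~30 years are dominated by the terminal step.
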