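# Base-case configuration: sacubitril-valsartan vs enalapril for HFrEF,
# Chinese patient perspective, 2019 USD.  Monthly cycles over a 10-year
# horizon, cohort entering at age 64 with the trial's NYHA distribution.
horizon_cycles: 120
start_age: 64.0
discount_rate_annual: 0.035
initial_nyha_distribution: [0.045, 0.716, 0.231, 0.008]
wtp_thresholds: [10276.0, 30828.0]   # GDP per capita and 3x GDP per capita
psa_draws: 10000
seed: 2019

settings:
  weibull_mode: calibrated
  hr_scale: rate
  readmission_mode: unconditional
  disutility_mode: per_event
  inpatient_copay_is_patient_share: true

parameters:
  # Baseline monthly event probabilities (comparator arm, NYHA I/II baseline).
  # p_hosp_monthly is the calibration anchor: the mean monthly hospitalization
  # probability over the 120-cycle reference window that the Weibull scale
  # coefficient is solved against.  The default equals the mean implied by the
  # published coefficients (lam=-0.00097, gamma=1.02685), which reproduces the
  # published base case; the low/up band is the published sensitivity range,
  # printed on a different scale than the coefficients (see docs/methods.md).
  p_hosp_monthly:        {value: 0.001102447925, low: 0.00868, up: 0.0145, dist: beta, kind: probability}
  p_cv_death_monthly:    {value: 0.0057534, low: 0.00412, up: 0.00844, dist: beta, kind: probability}
  p_readmission:         {value: 0.0147, low: 0.0132, up: 0.0161, dist: beta, kind: probability}
  p_nyha_change_enalapril: {value: 0.0088, low: 0.0079, up: 0.0097, dist: beta, kind: probability}
  p_nyha_change_sacval:    {value: 0.0068, low: 0.00612, up: 0.00748, dist: beta, kind: probability}

  # Treatment-effect hazard ratios and NYHA-class risk multipliers.
  hr_hosp_sacval:      {value: 0.79, low: 0.71, up: 0.89, dist: lognormal, kind: hazard_ratio}
  hr_cv_death_sacval:  {value: 0.80, low: 0.71, up: 0.89, dist: lognormal, kind: hazard_ratio}
  hr_hosp_nyha3:       {value: 1.71, low: 1.33, up: 2.18, dist: lognormal, kind: hazard_ratio}
  hr_hosp_nyha4:       {value: 3.4,  low: 1.69, up: 6.84, dist: lognormal, kind: hazard_ratio}
  rr_cv_death_nyha3:   {value: 1.372, low: 1.303, up: 1.445, dist: lognormal, kind: relative_risk}
  rr_cv_death_nyha4:   {value: 1.640, low: 1.503, up: 1.790, dist: lognormal, kind: relative_risk}

  # Health-state utilities and one-time event disutilities.
  utility_nyha12: {value: 0.780, low: 0.741, up: 0.819, dist: beta, kind: utility}
  utility_nyha3:  {value: 0.715, low: 0.679, up: 0.751, dist: beta, kind: utility}
  utility_nyha4:  {value: 0.660, low: 0.627, up: 0.693, dist: beta, kind: utility}
  disutility_hosp:    {value: -0.1, low: -0.13, up: -0.08, dist: beta, kind: disutility}
  disutility_readmit: {value: -0.1, low: -0.13, up: -0.08, dist: beta, kind: disutility}

  # Monthly patient-borne drug costs and healthcare costs (2019 USD).
  cost_sacval_monthly:    {value: 17.12, low: 13.70, up: 30.46, dist: gamma, kind: cost}
  cost_enalapril_monthly: {value: 10.65, low: 0.90, up: 12.78, dist: gamma, kind: cost}
  cost_outpatient_monthly: {value: 41.56, low: 33.26, up: 49.87, dist: gamma, kind: cost}
  copay_inpatient:        {value: 0.3, low: 0.1, up: 1.0, dist: fixed, kind: rate}
  cost_hospitalization:   {value: 1920.49, low: 1536.39, up: 2304.59, dist: gamma, kind: cost}
  cost_readmission:       {value: 1340.05, low: 1072.04, up: 1608.06, dist: gamma, kind: cost}

hazard_models:
  # Published parametric fits to the comparator arm's trial survival curves,
  # S(t) = exp(lam * t**gamma), t in months.
  hospitalization_enalapril: {family: weibull, lam: -0.00097, gamma_shape: 1.02685}
  cv_death_enalapril: {family: exponential, lam: -0.00577}

mortality_table:
  # Age-specific annual background (non-CV) mortality; left step function.
  - [1, 0.002949]
  - [5, 0.000284]
  - [10, 0.00015]
  - [15, 0.000169]
  - [20, 0.000177]
  - [25, 0.000154]
  - [30, 0.000298]
  - [35, 0.000458]
  - [40, 0.000472]
  - [45, 0.00071]
  - [50, 0.0011998]
  - [55, 0.0029394]
  - [60, 0.0028332]
  - [65, 0.0066972]
  - [70, 0.0097194]
  - [75, 0.0121676]
  - [80, 0.016739]
  - [85, 0.0331037]
  - [100, 1.0]

nyha_change_matrix:
  # Conditional destination distribution of a one-month NYHA class change.
  - [0.0, 0.831, 0.169, 0.0]     # from class I
  - [0.422, 0.0, 0.531, 0.047]   # from class II
  - [0.0, 0.847, 0.0, 0.153]     # from class III
  - [0.0, 0.0, 1.0, 0.0]         # from class IV

arms:
  sacval:
    drug: {unit_price: 1.42, copay_ratio: 0.8, monthly_price: 85.61, monthly_cost: 17.12}
    drug_cost_param: cost_sacval_monthly
    nyha_progress_param: p_nyha_change_sacval
    hr_hosp_param: hr_hosp_sacval
    hr_cv_death_param: hr_cv_death_sacval
  enalapril:
    drug: {unit_price: 0.18, copay_ratio: 0.0, monthly_price: 10.65, monthly_cost: 10.65}
    drug_cost_param: cost_enalapril_monthly
    nyha_progress_param: p_nyha_change_enalapril
    hr_hosp_param: null
    hr_cv_death_param: null
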