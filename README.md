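# hfcea — cost-effectiveness of sacubitril-valsartan vs enalapril in HFrEF

`hfcea` is a decision-analytic Markov cohort model for heart failure with
reduced ejection fraction (HFrEF), built for health-economics analysts who
want a fully scripted, testable alternative to spreadsheet/TreeAge models.
It compares sacubitril-valsartan (Sac-Val) with enalapril from the
perspective of a Chinese patient under the national negotiated drug prices
(2019 USD), and reports total costs, quality-adjusted life years (QALYs) and
the incremental cost-effectiveness ratio (ICER), with one-way, two-way
(price-threshold) and probabilistic sensitivity analyses.

## The model

Six health states — NYHA classes I–IV plus cardiovascular (CV) and non-CV
death — evolve in monthly cycles over a 10-year horizon, starting at age 64
with the trial NYHA mix (4.5/71.6/23.1/0.8%). Baseline monthly
hospitalization risk follows a Weibull model, S(t) = exp(λ·t^γ), and CV death
an exponential model, with NYHA-class multipliers (hospitalization HR 1.71 /
3.4 and CV-death RR 1.372 / 1.640 for III / IV). The treatment arm applies
hazard ratios on the rate scale:

    p' = 1 − (1 − p)^HR,  HR = 0.79 (hospitalization), 0.80 (CV death)

Background non-CV mortality comes from an age-indexed life table. Utilities
(0.780 / 0.715 / 0.660 by class severity, 0.1 QALY lost per hospitalization
or readmission), patient-borne drug costs ($17.12 vs $10.65 per month),
outpatient visits ($41.56/month) and the patient share (0.3) of
hospitalization/readmission costs accrue with a half-cycle correction and
3.5%/year midpoint discounting. Outcomes:

    ICER = ΔCost / ΔQALY        NMB(w) = w·ΔQALY − ΔCost

at willingness-to-pay thresholds of $10,276 (GDP per capita) and $30,828
(3× GDP). A patient-level microsimulation of the same pathway serves as an
independent validation oracle and generates synthetic censored event-time
data for hazard-parameter recovery. All inputs live in one packaged YAML
configuration; every analysis is a pure function of a config object. See
`docs/methods.md` for conventions and calibration.

## Worked example

```python
import hfcea as h

cfg = h.default_config()
sacval, enalapril = h.scenario_run(cfg)          # paired 120-cycle runs
ce = h.icer(sacval, enalapril, cfg.wtp_thresholds)
print(f"Sac-Val   {sacval.total_qaly:.2f} QALYs  ${sacval.total_cost:,.2f}")
print(f"enalapril {enalapril.total_qaly:.2f} QALYs  ${enalapril.total_cost:,.2f}")
print(f"ICER ${ce.icer:,.2f}/QALY   NMB@10,276 ${ce.nmb[10276.0]:,.2f}")
print(f"10-y deaths: {h.death_fraction(sacval, 10):.1%} vs "
      f"{h.death_fraction(enalapril, 10):.1%}")

th = h.breakeven_price(wtp=10276.0, comparator_monthly_cost=12.78, config=cfg)
print(f"break-even Sac-Val price ${th.breakeven_monthly_cost:.2f}/month")
```

prints

```
Sac-Val   4.65 QALYs  $4,905.43
enalapril 4.36 QALYs  $4,158.07
ICER $2,563.47/QALY   NMB@10,276 $2,248.51
10-y deaths: 49.9% vs 57.2%
break-even Sac-Val price $49.00/month
```

Sac-Val buys 0.29 extra QALYs for $747 more per patient — about $2,563 per
QALY gained, a quarter of the per-capita-GDP threshold, so Sac-Val is
cost-effective; it stays so until its patient-borne price exceeds about
$49/month. The same API drives the sensitivity machinery:
`h.one_way_dsa(cfg)` (tornado table), `h.two_way_grid(...)` (price grid),
`h.run_psa(cfg)` and `h.ceac(...)` (probabilistic analysis), and
`h.simulate_population(...)` (microsimulation). A thin CLI mirrors these:
`hfcea run --arm sacval`, `hfcea icer`, `hfcea threshold`, `hfcea dsa`,
`hfcea psa`, `hfcea ceac`, `hfcea microsim`, `hfcea validate <config>`.

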