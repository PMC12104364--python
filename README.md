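# pedpd-cua

Cost-utility and budget-impact modelling of **automated peritoneal dialysis
(APD)** versus **continuous ambulatory peritoneal dialysis (CAPD)** for
pediatric end-stage kidney disease (ESKD), in the Thai health-technology-
assessment setting.

Children with kidney failure who cannot receive a timely transplant are
maintained on dialysis; peritoneal dialysis is the usual pediatric choice,
either manually (CAPD) or by an overnight cycler machine (APD). APD frees
school hours and caregiver time but costs more. This package implements the
decision-analytic machinery a health economist needs to weigh that trade-off:

- a **lifetime two-arm Markov cohort model** with one-year cycles over four
  health states per arm — the assigned PD modality, hemodialysis (HD),
  kidney transplantation (KT), and death — accumulating discounted costs,
  life years (LY) and quality-adjusted life years (QALY);
- the **survival-to-probability chain** used to parameterize it: conditional
  survival S(u) = S(t)/S(t−1), cycle event probability tp(t) = 1 − S(u),
  annual rate r = −ln(1 − tp)/cycle and back-transform p = 1 − e^(−r·t),
  plus constant-hazard extrapolation of a 3-year survival curve to year 10;
- **cost-effectiveness comparison**: incremental cost Δc, effects Δe, the
  ICER Δc/Δe per QALY and per LY, dominance labels, and net monetary
  benefit NMB = λ·QALY − cost at a willingness-to-pay λ (160,000 baht/QALY
  by default, the Thai threshold);
- **uncertainty analysis**: one-way (tornado) sweeps of every parameter over
  its 95% CI, and a probabilistic sensitivity analysis (beta for
  probabilities/utilities, gamma for costs, method-of-moments from mean and
  CI) summarized as a cost-effectiveness acceptability curve;
- a **ten-year budget-impact projection** of the pediatric PD population
  (attrition to transplant, HD and death; incident inflow) priced under both
  modalities from the payer perspective, reproducing published-table
  rounding conventions exactly;
- a **synthetic-parameter generator** and an independent individual-level
  **microsimulation oracle** used to verify the cohort engine.

The packaged fixture carries every input printed in the main text of the
source analysis (modality utilities 0.94/0.89, 3% discounting, start age 1,
WTP, and the full budget-impact configuration). The per-year transition
schedule and cost tables live in that study's supplementary variables table
and are shipped as clearly tagged *synthetic placeholders* with a provenance
manifest; transcribing the supplementary table into
`src/pedpd_cua/data/supplementary_template.json` activates the checks that
reproduce the published cost-utility results.

## Worked example

```python
from pedpd_cua import load_reference_parameters, run_cohort, compare_strategies

params, manifest = load_reference_parameters()
ref = run_cohort(params, "CAPD")
alt = run_cohort(params, "APD")
result = compare_strategies(ref, alt, wtp=params.wtp)
print(f"CAPD: cost {ref.total_cost:,.0f} baht, {ref.total_ly:.2f} LY, {ref.total_qaly:.2f} QALY")
print(f"APD : cost {alt.total_cost:,.0f} baht, {alt.total_ly:.2f} LY, {alt.total_qaly:.2f} QALY")
print(f"ICER {result.icer_per_qaly:,.0f} baht/QALY; LY axis: {result.dominance_ly}")
```

prints (placeholder transition/cost values — pipeline demonstration, not the
published base case):

```
CAPD: cost 10,586,510 baht, 20.67 LY, 18.11 QALY
APD : cost 10,901,871 baht, 20.47 LY, 18.37 QALY
ICER 1,213,664 baht/QALY; LY axis: dominated
```

APD costs more, buys QALYs through its higher utility weight, and loses a
little survival — so it is "dominated" on the life-year axis while having a
finite (here, above-threshold) price per QALY.

The budget impact from the published patient counts:

```python
from pedpd_cua import load_bia_reference, run_bia
table = run_bia(load_bia_reference())
print(table.to_frame().to_string(index=False))
```

reproduces the published ten-year table cell for cell — e.g. 2023: 618
patients, 268 M baht (CAPD) vs 307 M (APD), +39 M, 63,107 baht per patient;
average row 853 patients, 370 M vs 424 M, +54 M, 63,202 baht.

The same analyses are available from a shell:

```sh
pedpd-cua compare --params params.json --out-dir out/
pedpd-cua tornado --params params.json --out out/tornado.csv
pedpd-cua psa --params params.json --n 1000 --seed 7 --out out/psa.csv
pedpd-cua ceac --params params.json --n 1000 --seed 7 --grid 0:400000:10000 --out out/ceac.csv
pedpd-cua bia --config bia.json --out out/bia.csv
pedpd-cua simulate-params --seed 1 --out out/params.json
```

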