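# Methods

## Model structure

Each treatment arm (APD or CAPD) is a discrete-time Markov cohort model with
one-year cycles and four states: the arm's assigned PD modality, hemodialysis
(HD), kidney transplantation (KT), and death (absorbing). The two arms share
the HD/KT/death machinery and differ only in which modality the PD state
denotes, its costs and its utility. Modelled moves are PD→HD, PD→KT, PD→death,
HD→PD, HD→death, KT→HD, KT→PD and KT→death; HD→KT is not modelled, patients
never switch between APD and CAPD, and after HD or KT failure they return to
their *own* arm's modality. The probability of moving from PD to KT is
constrained equal across arms (no modality-specific transplant data). The
transition schedule covers model years 1–10; later cycles reuse the year-10
row. The cohort starts fully in the PD state at age 1 and runs to age 100 or
until the alive fraction falls below 1e−6 ("lifetime" horizon).

## From survival curves to transition probabilities

Dialysis survival enters as a curve S(t), t = 0..T, with S(0) = 1,
non-increasing. Per-cycle event probabilities are the conditional-survival
complement, tp(t) = 1 − S(t)/S(t−1); the chain through the annual rate
r = −ln(1 − tp)/cycle and back via p = 1 − e^(−r·cycle) is the identity for
one-year cycles but both directions are implemented and property-tested,
since the rate is the quantity one would rescale for other cycle lengths.
tp = 1 is handled explicitly (infinite rate), and a curve that reaches zero
where a conditional ratio is needed raises a degenerate-curve error.

A curve observed to year 3 is extended to year 10 **multiplicatively**:
S(t) = S(t−1)·q with q = S(3)/S(2). A multiplicative ratio (constant hazard)
keeps survival non-negative for any horizon, where an absolute annual
decrement would eventually go negative; this is the package's reading of an
"observed decrease" extrapolation. Curves observed to only two years fall
back to the ratio of the last two points. The extrapolated tail is exactly
equivalent to a constant per-cycle probability 1 − q (tested algebraically).

## Background mortality

Age-specific all-cause mortality q(age) is merged into every alive state's
death entry as **independent competing risks**,
p = 1 − (1 − p_state)(1 − q(age)), the conservative default when the
state-specific estimate's coverage of all-cause death is unknown. A
`mortality_combination: "max"` switch instead takes max(p_state, q) for
parameterizations whose state-specific probabilities already embed all-cause
mortality. The stay probability is the residual of each row; a residual
pushed below zero by the merge raises an explicit infeasible-row error
rather than being silently renormalized.

## Accounting conventions

* **Discounting**: factor (1 + r)^−t with t = 0 for the first cycle (first
  year undiscounted), r = 3%/year for both costs and outcomes by default.
* **Half-cycle correction**: off by default (none is applied in the source
  analysis); an option accrues the trapezoid of start- and end-of-cycle
  occupancy instead.
* **Costs**: each state carries annual direct medical cost for the first
  year, direct medical cost from year 2 onward, and direct non-medical cost
  (all years), in baht/year at 2022 prices (inputs are assumed already
  inflation-adjusted). The year-1/year-2+ split is indexed by time since
  model start for the PD and HD states and by time since state entry for KT:
  the transplant-year cost differs radically from graft maintenance, so KT is
  internally split into a first-year tunnel state and a maintenance state
  (collapsed back to one KT column in exported traces). Death accrues
  nothing.
* **Utilities**: one weight per state in [0, 1] (PD arm-specific: APD 0.94,
  CAPD 0.89; HD and KT shared across arms); QALYs are occupancy-weighted
  utilities, so setting all utilities to 1 makes QALY ≡ LY exactly. No
  time-varying utilities (e.g. no second-year post-transplant improvement).

## Comparison

Incrementals are APD − CAPD from unrounded totals. ICERs are reported per
QALY and per LY; a zero effect-difference yields an explicit "undefined"
rather than an exception. Dominance (cheaper-and-better / pricier-and-worse)
is labelled separately on the QALY and LY axes — with a utility advantage for
APD and a small survival disadvantage, "dominated on the LY axis, finite
ICER per QALY" is the expected pattern. `cost_effective_at_wtp` is the net
monetary benefit ordering NMB(APD) ≥ NMB(CAPD), NMB = λ·QALY − cost, which
in the common north-east quadrant is ICER ≤ λ. Printed-table rounding (two
decimals for LY/QALY) is presentation only.

## Sensitivity analysis

**One-way (tornado)**: every parameter carrying a 95% CI is set to each
bound with all else at base values, the full two-arm model is rerun, and the
two ICERs are recorded; entries are sorted by |ICER range|, ties broken by
parameter id. Discount rates are swept over a conventional 0–6% band. A
bound that violates an invariant (e.g. a probability above 1, or a row sum
above 1) is clamped/rescaled with a logged warning.

**Probabilistic (PSA)**: all CI-carrying parameters are drawn independently
each iteration — beta for probabilities and utilities, gamma for costs,
moment-matched with SE = (CI_high − CI_low)/3.92; an infeasible beta fit
falls back to uniform over the CI with a warning; parameters without a CI
stay fixed; discount rates are not sampled. Each draw reruns both arms and
stores (Δcost, ΔQALY). The default 1000 iterations take ~20 s on one core.
The CEAC evaluates, at each willingness-to-pay on a 0–400,000 baht grid
(step 10,000, always containing 160,000), the fraction of draws in which
each arm's NMB is strictly larger, splitting exact ties equally, so the two
probabilities sum to 1 by construction.

## Budget impact

The payer-perspective projection multiplies each year's pediatric PD
population by the annual direct medical cost per patient under CAPD
(433,641 baht) and APD (496,836 baht), with 100% first-year uptake and no
discounting. Counts are either supplied directly (published-table mode) or
projected as count(y+1) = count(y)·(1 − p_KT − p_HD − p_death) + incident
cases, with attrition probabilities 0.079/0.031/0.023 and incident cases
derivable from an all-age ESKD incidence series × proportion pediatric
(0.004) × probability of PD (0.76).

`printed` mode reproduces the published table's arithmetic, reverse-
engineered cell-by-cell: per-arm budgets and the incremental budget are each
rounded half-up to whole millions of baht, the **incremental is rounded from
the exact cost difference** (not differenced after rounding — the published
table's 2026 and 2029 rows differ by 1 M from the difference of their own
rounded budget cells, which pins this order of operations), and NBI per
patient = rounded incremental × 10⁶ / count. Averages are means of the
rounded yearly values, rounded as printed. `exact` mode carries full
precision, where NBI per patient is identically the unit-cost difference
(63,195 baht).

## Fixtures, generator and verification oracle

The packaged fixture (`data/`) holds every main-text input; the transition
schedule, cost tables, HD/KT utilities, mortality table and all CIs are
synthetic placeholders pending transcription of the source study's
supplementary variables table, and a provenance manifest tags each value
(`main_text` / `supplementary_transcribed` / `synthetic_placeholder`).
Placeholders were chosen once to be clinically plausible for a pediatric
dialysis cohort (single-digit-percent annual event probabilities with
year-1 risk above later years, six-figure baht annual costs with APD's
dialysis cost above CAPD's) so that the pipeline's qualitative behaviour
matches the setting; tests that assert the published cost-utility numbers
skip with an explanatory message while any placeholder remains.

The generator (`generate_parameter_set`) emits random fully-valid parameter
sets: dialysis mortality is drawn as a monotone survival curve and pushed
through the extrapolation/conversion chain above; exits are scaled to leave
room for background mortality; profiles produce realistic cohorts, short
high-mortality sets for oracle comparisons, or edge-stretched sets
(probabilities near 0 and near 1) for fuzzing. It emulates the *structure*
of real parameterizations, not any particular population — passing tests
demonstrate correctness of the machinery, not clinical conclusions.

The microsimulation oracle replays the exact cycle matrices one individual
at a time (categorical sampling, 200,000 individuals in the acceptance
check) and returns Monte-Carlo means and standard errors; the cohort engine
must agree within 3 SE. Because the two share only the matrix constructor
and not the accumulation logic, agreement cross-checks the cohort algebra,
discounting and cost-timing implementation.

## Numerical choices and limitations

Row sums are validated to 1e−12, trace conservation to 1e−10; survival
reconstruction from per-cycle probabilities holds to 1e−10. The engine is
fully deterministic; all stochastic components (generator, PSA, oracle)
funnel through seeded numpy generators. Parameter correlation is not
modelled in the PSA (independent draws); probabilities drawn jointly from a
shared survival curve are supported only through the generator, not the
sampler. No expected-value-of-perfect-information analysis, no >2-strategy
frontier, no estimation of transition probabilities from patient-level data,
and no CPI adjustment (costs are taken as already expressed in the analysis
year's baht).
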