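# ionapath

Decision-analytic cost and throughput model for diverting partial medial
meniscectomy from the operating room (OR) to in-office needle arthroscopy
(IONA).

## The problem

Knee arthroscopy with meniscectomy is one of the highest-volume orthopedic
procedures, and in bundled-payment systems (Ontario's quality-based
procedures, QBP) each case carries a fixed government reimbursement and an
all-inclusive hospital case cost. IONA — small-bore arthroscopy performed in
a clinic room under local anesthesia — can treat MRI-irreparable medial
meniscus tears without an OR slot. This package models, for a mid-sized
community hospital, what happens to annual revenue, expenses, profit, and
surgical-waitlist throughput if patients whose MRI reads *likely
irreparable* are offered IONA instead of traditional OR arthroscopy.

It is written for health-economics and operations analysts: every model
parameter lives in one YAML configuration, every stage is a library
function, and a CLI ties them into a reproducible pipeline.

## The model

**Decision tree.** Surgically booked patients split by MRI read:
repairable (fraction `p_rep = 47.2%`) or irreparable (`p_irr = 52.8%`),
pooled from a six-study literature review (n = 508). Within each arm,
patients resolve as repair, meniscectomy (resection), or — for the 12% MRI
false positives — diagnostic arthroscopy. In the proposed state a fraction
`s` of irreparable-arm patients selects IONA (base case 50%); of those, a
fraction `r` prove repairable at arthroscopy and are *revised* to a full OR
repair (base case `r = 20.3% = 23.1% × (1 − 0.12)`). Expected case mix is
deterministic-fractional: branch count = `N ×` branch probability.

**Throughput.** Diverted patients = OR-bound count (current) − OR-bound
count (proposed), which collapses to `N · p_irr · s · (1 − r)` because a
revised IONA still occupies an OR slot.

**DuPont financials.** Revenue = QBP rate × cases per line; expenses =
case cost × cases per line; profit = revenue − expenses; margin =
profit / revenue. IONA procedures bill at the meniscectomy/DA QBP rate; an
IONA revision costs one disposable set plus one OR repair. The five
per-case unit rates are not published, so they are recovered by ordinary
least squares from the eight published mean line items (the calibration in
`ionapath.finance.calibrate_unit_rates`).

**Monte Carlo.** Annual volume ~ Normal(198, 31), truncated at 0, 10,000
draws, both states evaluated on each draw (paired design); paired and
Welch t-tests compare the states.

**Sensitivity.** Two-way grids over `(s, r)` in 10-point steps classify
each cell GREEN/YELLOW/RED against zero and the current-state baseline,
and a threshold report extracts the break-even frontier.

## Worked example

```bash
$ ionapath throughput
diverted 41.66 of 198 patients/year (21.04%); headline 42 (21.2%)

$ ionapath calibrate
                   rate  cad_per_case
billing_meniscectomy_da       1256.27
         billing_repair       1256.51
   cost_meniscectomy_da       1298.48
            cost_repair       1598.77
   cost_iona_disposable        763.79

$ ionapath run --sims 10000 --seed 42 --out results/
Care-pathway diversion model: run report
annual volume: Normal(198, 31), 10000 simulations, seed 42
base case: selection 50%, revision 20.3%

mean diverted patients/year: 41.59 (SD 6.57) -> headline 42 (21.2% of volume)
revenue_total: current $248,358.37 (SD $39,204.35) vs proposed $248,355.88 (SD $39,203.95); diff -0.0%, paired p=0, Welch p=0.996
expenses_total: current $280,808.81 (SD $44,326.78) vs proposed $266,661.21 (SD $42,093.52); diff -5.0%, paired p=0, Welch p=5.8e-117
profit: current $-32,450.44 (SD $5,122.43) vs proposed $-18,305.33 (SD $2,889.57); diff -43.6%, paired p=0, Welch p=0
annual expense savings: $14,147.60
profit beats current state from selection 10% (revision up to 30%)
positive profit from selection 60% (revision up to 0%)
```

Reading the numbers: offering IONA to half of the irreparable-MRI patients
diverts about 42 patients per year (21.2% of OR demand) into the clinic.
Revenue is essentially unchanged — every patient is still billed exactly
once — while annual expenses fall by roughly 5% (≈ $14.1k at the
calibrated rates), cutting the pathway's annual operating loss by more
than 40%. Profit only turns positive outright at 60%+ uptake with no
revisions, but *any* uptake with a revision rate under ~40% beats the
current state. Other subcommands: `pool`, `sensitivity`, `synth`
(synthetic booking/case-costing extracts with known latent rates), and a
YAML config override via `--config` (see `examples/base_case.yaml`).

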