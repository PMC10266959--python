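# Methods

This note documents the model implemented by `ionapath`: its structure,
parameter defaults, numerical conventions, the design choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Scope and structural assumptions

The model starts at patients already booked for OR meniscectomy or repair;
there is no non-surgical branch and no prevalence stage (the 20.0%
prevalence of MRI-confirmed tears among knee-pain patients is recorded as
`defaults.MRI_TEAR_PREVALENCE` but deliberately unused). Structural rules
of the tree, encoded as its topology rather than as parameters:

* only MRI-likely-irreparable patients are offered IONA;
* every IONA revision is an OR **repair** (no crossover to meniscectomy),
  and it consumes both the office procedure and the OR slot;
* eligibility for IONA mirrors eligibility for traditional arthroscopy,
  so the two states cover the same patient population;
* IONA meniscectomy, diagnostic IONA, and IONA revision all bill at the
  OR meniscectomy/DA bundled-payment rate — each patient is billed
  exactly once, which makes total revenue invariant between states
  whenever the repair and meniscectomy billing rates coincide.

## Evidence pooling

Branch probabilities come from pooled literature counts (fixed-effect
summation of events and totals; no heterogeneity weighting — only pooled
row totals are published, so per-study weighting would be unidentifiable
anyway). Within each MRI arm the repaired/resected shares are scaled by
`1 − fp_rate` (fp_rate = 12%, the MRI false-positive rate, identical in
both arms) and the displaced mass becomes the diagnostic-arthroscopy
branch.

**Printed-rounding mode** (`use_printed_rounding`, default on): stage
percentages are snapped to one decimal before and after the
false-positive adjustment, emulating a source that tabulates percentages
at one decimal. This matters: the irreparable-arm repaired share is
62/268 = 23.134%, and 23.134% × 0.88 = 20.358% — which rounds to 20.4% —
whereas the one-decimal chain 23.1% × 0.88 = 20.33% rounds to the
published 20.3%. Downstream headline counts (42 diverted, 105 maximum)
likewise reconcile only with the one-decimal values, so reproduction runs
use this mode; full-precision mode remains available for fresh analyses.

## Case-mix allocation

Allocation is deterministic-fractional: each branch receives its exact
expected mass, so randomness enters only through the annual-volume draw.
(A multinomial per-patient sampling mode exists behind a flag for stress
testing.) Arm splits are renormalised to sum exactly to one — one-decimal
inputs can miss by up to 0.005, and renormalisation makes patient
conservation exact for any valid input. When the revision rate `r`
departs from its base value, the non-revision IONA mass splits between
meniscectomy and diagnostic IONA in the irreparable arm's
resect : diagnostic ratio (0.677 : 0.120), which reproduces the base case
exactly at `r = 0.203` and stays valid on all of `r ∈ [0, 1]`. Fractional
patients are allowed internally; only headline counts are rounded
(half away from zero).

## Unit-rate calibration

The hospital's per-case rates are unpublished; only eight mean annual
line items are. Writing each line as (base-case expected count) × (rate
combination) gives an overdetermined linear system in the five rates —
meniscectomy/DA billing, repair billing, meniscectomy/DA cost, repair
cost, IONA disposable cost — solved by ordinary least squares
(magnitude-weighting available, off by default). The published lines are
internally inconsistent at the few-percent level: the IONA revision lines
imply a lower per-case amount than any single rate vector can produce
(residuals +4.7–4.8% on those two lines; all others under 1.4%).
Calibration therefore reports per-line relative residuals and refuses fits
where any residual reaches 10%, which in practice signals a wrong case
mix rather than table noise. Consequences of the residual: the model's
base-case savings come out at $14,171/year against the published
$14,502.55 (−2.3%) and the expense reduction at 5.04% against 5.15%.

## Monte Carlo simulation

Annual volume is drawn from Normal(198, 31) — the observed mean and SD of
2016–2020 bookings — truncated below at zero (numerically negligible at
this mean/SD: Φ(−6.4)) and rounded to whole patients; 10,000 draws by
default, seeded via `numpy.random.default_rng`. Both states are evaluated
on the *same* draw (paired design). Because allocation is deterministic,
every financial metric is proportional to the draw; the between-state
expense difference therefore inherits the volume distribution's
coefficient of variation exactly, and profit margins are volume-free
constants per state.

Statistical comparison reports the paired t-test as primary (the
simulation is naturally paired) and the unpaired Welch test alongside.
The paired test on exactly-proportional differences is significant for
*any* nonzero per-patient difference, including the economically
negligible revenue one (≈ −$2.5/year on ~$248k); the Welch test
(p ≈ 0.996) is the informative statement that revenue does not differ
between states. Constant paired differences (margins) are flagged as
degenerate rather than assigned a p-value. Percentage differences are
computed on means.

The headline throughput pair divides the rounded mean diverted count by
the mean volume (42/198 = 21.2%) and the diverted-count SD by the same
mean volume — a convention, since the per-draw ratio is constant; both
the unrounded mean (41.66 ⇒ 21.04%) and the SD are also reported.

## Sensitivity analysis

Grids sweep `s` and `r` over 0–100% in 10-point steps (the step
reproduces every published threshold; finer steps only tighten them —
asserted in tests). Cells are deterministic evaluations at N = 198.
Classification uses strict inequalities — GREEN above zero (profit) or
above the base-case throughput; YELLOW between; RED below the
current-state baseline (profit) or below zero (throughput) — with exact
ties to the baseline classified YELLOW and flagged. Values within 1e-9 of
zero are snapped to zero before classification so that boundary cells
(`s = 0`, `r = 1`) do not misclassify on floating-point residue.

The threshold report gives, for "beats the current state" and for
"positive profit", the minimum selection fraction achieving the condition
and the maximum revision rate still admissible at that selection. At the
calibrated rates: any uptake beats the current state while `r ≤ 30%`
(the per-IONA-patient saving `0.203·c_repair + 0.797·c_mda − c_disp −
r·c_repair` turns negative near `r ≈ 37%`), and positive profit first
appears at 60% uptake with `r = 0`.

## ICUR helper

`finance.icur(savings, qaly_gain)` divides annual savings by a
literature QALY gain (`defaults.QALY_GAIN_RANGE = (8.09, 17.0)` for
partial meniscectomy), giving ≈ $853–$1,793 per QALY at the published
savings. No discounting or multi-year horizon is modelled.

## Synthetic hospital data

`synthetic.generate_cohort` emulates the two institutional extracts the
model would consume in production: a booking schedule (year, patient,
MRI arm, procedure, state) and case-costing records (billing, cost per
patient). Yearly volumes follow the configured Normal; patients are
assigned a joint (arm, procedure) cell by categorical sampling from the
tree; per-case amounts are the latent unit rates times multiplicative
Gaussian noise `1 + N(0, cv)` floored at zero, default CV 0.2 (no
per-case dispersion is published; 20% is a typical case-cost spread).
Booking records carry the MRI arm so tests can check arm-conditional
logic; aggregation never uses it.

What the generator does **not** emulate: wait-time processes,
seasonality, cost covariates (surgeon, implant), coding errors, or
year-over-year drift. Passing round-trip tests therefore show that
aggregation and calibration invert the generative model — zero-noise
recovery is exact; at CV 0.2 over 20 years, rates recover within 5% —
not that the calibration is robust to structurally misspecified real
accounting data.

## Numerical conventions and degenerate inputs

* Presentation rounding is half-away-from-zero (spreadsheet convention);
  internal arithmetic is full-precision double.
* Currency serialises at 2 decimals, CAD; fractions at full precision.
* Zero revenue flags the margin as undefined (`None`) rather than NaN
  arithmetic; empty cohorts, empty study lists, mismatched volumes,
  out-of-range fractions, and `s > 0` in the current state all raise
  typed errors naming the offending field.
* Fixed seed ⇒ bit-identical simulation arrays and byte-identical
  pipeline CSVs.

## Problem sizes

Default runs use the study conditions: N = 198 expected patients/year,
10,000 simulation draws, 11×11 sensitivity grids, 5 synthetic booking
years (20 in the noisy recovery check). A full pipeline run completes in
a few seconds on one CPU.

## Known limitations

* The calibrated rate vector cannot reconcile the published IONA revision
  lines exactly (see above); financial outputs carry that few-percent
  bias, conservatively understating savings.
* Throughput is a diversion count, not a queueing model: it approximates
  waitlist relief but says nothing about waiting-time distributions or
  clinic capacity absorbed by added IONA slots.
* The revision rate is a literature proxy (MRI-irreparable-but-repaired
  share), not an observed IONA outcome; no primary IONA efficacy data
  existed to inform it.
* Single-year horizon, no discounting, one institution's payment system
  (Ontario QBP); transferring the model requires re-entering rates and
  volumes in the configuration.
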