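# Base-case model configuration: pooled literature evidence for the
# decision tree, the institution's annual-volume distribution, the
# base-case scenario, and the published mean financial line items used
# to calibrate the five unpublished per-case unit rates.
schema_version: 1

evidence:
  repairable: {events: 240, total: 508}      # MRI reads likely repairable
  irreparable: {events: 268, total: 508}     # MRI reads likely irreparable
  repairable_arm:
    repaired: {events: 173, total: 240}
    resected: {events: 67, total: 240}
  irreparable_arm:
    repaired: {events: 62, total: 268}
    resected: {events: 206, total: 268}
  fp_rate: 0.12              # MRI false positives -> diagnostic arthroscopy
  use_printed_rounding: true # snap stage percentages to one decimal (reproduction mode)

volume:
  mean: 198.0   # patients booked for meniscectomy/repair per year
  sd: 31.0
  years: 5      # booking years emulated by the synthetic generator

scenario:
  proposed:
    selection_fraction: 0.5  # share of MRI-irreparable patients choosing IONA
    revision_rate: 0.203     # share of IONA patients revised to an OR repair

finance:
  printed_lines:  # mean CAD/year; current-state and IONA statement lines
    current_or_meniscectomy_da_billing: 147440.21
    current_or_repair_billing: 101115.79
    current_or_meniscectomy_da_cost: 152605.31
    current_or_repair_cost: 128809.92
    proposed_iona_meniscectomy_da_billing: 53068.64
    proposed_iona_revision_billing: 12733.33
    proposed_iona_meniscectomy_da_cost: 32111.60
    proposed_iona_revision_cost: 23925.68

simulation:
  n_sims: 10000
  seed: 42

sensitivity:
  step: 0.10
  metrics: [profit, margin, throughput]
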