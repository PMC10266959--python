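"""Default base-case configuration.

The shipped defaults are the study conditions of the underlying analysis:
pooled literature counts for the decision tree (six studies, n = 508),
the institution's annual volume distribution (mean 198, SD 31, five
booking years 2016-2020), the base-case scenario (50% IONA selection,
20.3% revision), and the published mean financial line items against
which the five unpublished unit rates are calibrated.
"""
from __future__ import annotations

import copy

from .config import ModelConfig, config_from_dict

#: Published mean financial line items (CAD/year) used for calibration:
#: the four current-state lines and the four IONA lines of the proposed state.
PRINTED_LINES = {
    "current_or_meniscectomy_da_billing": 147_440.21,
    "current_or_repair_billing": 101_115.79,
    "current_or_meniscectomy_da_cost": 152_605.31,
    "current_or_repair_cost": 128_809.92,
    "proposed_iona_meniscectomy_da_billing": 53_068.64,
    "proposed_iona_revision_billing": 12_733.33,
    "proposed_iona_meniscectomy_da_cost": 32_111.60,
    "proposed_iona_revision_cost": 23_925.68,
}

#: Documented but unused by the model, which starts at surgically booked
#: patients: prevalence of MRI-confirmed isolated medial meniscal tears
#: among patients with new-onset symptomatic knee pain.
MRI_TEAR_PREVALENCE = 0.20

#: QALY gain range for partial meniscectomy reported in the utility
#: literature, used by the ICUR helper.
QALY_GAIN_RANGE = (8.09, 17.0)

DEFAULT_CONFIG_DICT = {
    "schema_version": 1,
    "evidence": {
        # pooled literature counts: MRI repairability vs eventual treatment
        "repairable": {"events": 240, "total": 508},
        "irreparable": {"events": 268, "total": 508},
        "repairable_arm": {
            "repaired": {"events": 173, "total": 240},
            "resected": {"events": 67, "total": 240},
        },
        "irreparable_arm": {
            "repaired": {"events": 62, "total": 268},
            "resected": {"events": 206, "total": 268},
        },
        "fp_rate": 0.12,  # MRI false positives resolve as diagnostic arthroscopy
        "use_printed_rounding": True,
    },
    "volume": {"mean": 198.0, "sd": 31.0, "years": 5},
    "scenario": {"proposed": {"selection_fraction": 0.5, "revision_rate": 0.203}},
    "finance": {"printed_lines": dict(PRINTED_LINES)},
    "simulation": {"n_sims": 10_000, "seed": 42},
    "sensitivity": {"step": 0.10, "metrics": ["profit", "margin", "throughput"]},
}


def default_config() -> ModelConfig:
    """The validated base-case configuration."""
    return config_from_dict(copy.deepcopy(DEFAULT_CONFIG_DICT))
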