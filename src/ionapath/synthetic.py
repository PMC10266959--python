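"""Synthetic hospital-shaped data: booking schedule and case-costing records.

Emulates the two institutional extracts the model consumes — a multi-year
OR booking schedule and per-case billing/cost records — with known latent
parameters so the aggregation -> calibration -> simulation chain is
testable end to end.  Yearly volumes are Normal(mean, sd) truncated at
zero; each patient is assigned an MRI arm and terminal procedure by
categorical sampling from the decision tree; per-case billing and cost
are the configured unit rates under multiplicative Gaussian noise
(``1 + Normal(0, noise_cv)``, floored at zero).

What this generator does not emulate: referral and imaging wait-time
processes, within-year seasonality, case-level cost covariates (surgeon,
implant choice), or coding errors.  Booking records carry the MRI arm so
tests can check arm-conditional logic; aggregation never relies on it.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .evidence import ArmProbabilities
from .finance import UnitRates, per_case_amounts
from .pathway import CaseMix, ProcedureKind, ScenarioParams, branch_distribution

BOOKING_COLUMNS = ["year", "patient_id", "mri_arm", "procedure", "state_label"]
CASE_COST_COLUMNS = ["patient_id", "billing", "cost"]

#: Procedures reached only through the MRI-likely-irreparable arm.
_IRREPARABLE_ONLY = {
    ProcedureKind.IONA_MENISCECTOMY,
    ProcedureKind.IONA_DIAGNOSTIC,
    ProcedureKind.IONA_REVISION,
}


class SyntheticDataError(ValueError):
    """Invalid generator inputs or empty cohorts."""


def generate_cohort(
    years: int,
    volume_mean: float,
    volume_sd: float,
    probs: ArmProbabilities,
    params: ScenarioParams,
    rates: UnitRates,
    *,
    noise_cv: float = 0.2,
    seed: Optional[int] = None,
    start_year: int = 2016,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``years`` of bookings and case costs under one state."""
    if years < 1:
        raise SyntheticDataError(f"years must be >= 1, got {years}")
    if noise_cv < 0:
        raise SyntheticDataError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = np.random.default_rng(seed)

    # joint (arm, procedure) distribution keeps the booking record's MRI
    # arm consistent with its terminal procedure
    dist = branch_distribution(probs, params)
    top = probs.p_repairable + probs.p_irreparable
    p_rep_arm = {  # share of each OR branch fed by the repairable arm
        ProcedureKind.OR_REPAIR: probs.p_repairable / top * probs.repairable.p_repair,
        ProcedureKind.OR_MENISCECTOMY: probs.p_repairable / top * probs.repairable.p_resect,
        ProcedureKind.OR_DIAGNOSTIC: probs.p_repairable / top * probs.repairable.p_diagnostic,
    }
    cells = []  # (mri_arm, procedure, probability)
    for kind, p in dist.items():
        if kind in _IRREPARABLE_ONLY:
            cells.append(("irreparable", kind, p))
        else:
            rep_part = min(p_rep_arm.get(kind, 0.0), p)
            cells.append(("repairable", kind, rep_part))
            cells.append(("irreparable", kind, p - rep_part))
    pvec = np.array([c[2] for c in cells])
    pvec = pvec / pvec.sum()

    amounts = per_case_amounts(rates)
    bookings, costs = [], []
    patient_counter = 0
    for year_idx in range(years):
        volume = int(max(0.0, np.floor(rng.normal(volume_mean, volume_sd) + 0.5)))
        if volume == 0:
            continue
        assignment = rng.choice(len(cells), size=volume, p=pvec)
        noise = 1.0 + rng.normal(0.0, noise_cv, size=(volume, 2)) if noise_cv > 0 else np.ones((volume, 2))
        for idx, cell_idx in enumerate(assignment):
            arm, kind, _ = cells[cell_idx]
            patient_counter += 1
            pid = f"P{patient_counter:06d}"
            bill_rate, cost_rate = amounts[kind]
            bookings.append((start_year + year_idx, pid, arm, kind.value, params.state))
            costs.append(
                (
                    pid,
                    max(0.0, bill_rate * noise[idx, 0]),
                    max(0.0, cost_rate * noise[idx, 1]),
                )
            )

    bookings_df = pd.DataFrame(bookings, columns=BOOKING_COLUMNS)
    costs_df = pd.DataFrame(costs, columns=CASE_COST_COLUMNS)
    return bookings_df, costs_df


@dataclass(frozen=True)
class CohortSummary:
    """Aggregates in the shapes consumed by calibration and simulation."""

    years: int
    volume_mean: float
    volume_sd: Optional[float]  # None (flagged) for single-year cohorts
    case_mix: CaseMix  # mean annual patients per procedure
    proportions: Dict[ProcedureKind, float]
    line_items: Dict[str, float]  # mean annual CAD per statement line
    state: str


_LINE_GROUPS = {
    "or_meniscectomy_da": (ProcedureKind.OR_MENISCECTOMY, ProcedureKind.OR_DIAGNOSTIC),
    "or_repair": (ProcedureKind.OR_REPAIR,),
    "iona_meniscectomy_da": (ProcedureKind.IONA_MENISCECTOMY, ProcedureKind.IONA_DIAGNOSTIC),
    "iona_revision": (ProcedureKind.IONA_REVISION,),
}


def aggregate_cohort(bookings: pd.DataFrame, case_costs: pd.DataFrame) -> CohortSummary:
    """Summarise a cohort into volume statistics, case mix, and line items.

    Line-item keys follow the calibration convention:
    ``{state}_{group}_billing`` / ``{state}_{group}_cost`` with IONA
    groups prefixed ``{state}_iona_...``; values are mean annual totals.
    """
    if bookings.empty or case_costs.empty:
        raise SyntheticDataError("cannot aggregate an empty cohort")
    states = bookings["state_label"].unique()
    if len(states) != 1:
        raise SyntheticDataError(f"cohort mixes states: {sorted(states)}")
    state = str(states[0])

    yearly = bookings.groupby("year")["patient_id"].count()
    years = int(yearly.size)
    volume_mean = float(yearly.mean())
    volume_sd = float(yearly.std(ddof=1)) if years > 1 else None

    per_kind = bookings.groupby("procedure")["patient_id"].count()
    mean_counts = {
        kind: float(per_kind.get(kind.value, 0)) / years for kind in ProcedureKind
    }
    case_mix = CaseMix(mean_counts)
    total = case_mix.total
    proportions = {k: (v / total if total > 0 else 0.0) for k, v in mean_counts.items()}

    merged = bookings.merge(case_costs, on="patient_id", validate="one_to_one")
    line_items: Dict[str, float] = {}
    for group, kinds in _LINE_GROUPS.items():
        subset = merged[merged["procedure"].isin([k.value for k in kinds])]
        if subset.empty:
            continue
        key = f"{state}_{group}"
        line_items[f"{key}_billing"] = float(subset["billing"].sum()) / years
        line_items[f"{key}_cost"] = float(subset["cost"].sum()) / years
    return CohortSummary(
        years=years,
        volume_mean=volume_mean,
        volume_sd=volume_sd,
        case_mix=case_mix,
        proportions=proportions,
        line_items=line_items,
        state=state,
    )


def write_cohort(
    bookings: pd.DataFrame, case_costs: pd.DataFrame, out_dir: Path | str
) -> Tuple[Path, Path]:
    """Write ``bookings.csv`` and ``case_costs.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bookings_path = out / "bookings.csv"
    costs_path = out / "case_costs.csv"
    bookings.to_csv(bookings_path, index=False)
    case_costs.to_csv(costs_path, index=False, float_format="%.2f")
    return bookings_path, costs_path


def read_cohort(data_dir: Path | str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort previously written by :func:`write_cohort`."""
    data = Path(data_dir)
    bookings = pd.read_csv(data / "bookings.csv")
    case_costs = pd.read_csv(data / "case_costs.csv")
    for frame, expected in ((bookings, BOOKING_COLUMNS), (case_costs, CASE_COST_COLUMNS)):
        missing = set(expected) - set(frame.columns)
        if missing:
            raise SyntheticDataError(f"cohort file missing columns: {sorted(missing)}")
    return bookings, case_costs
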