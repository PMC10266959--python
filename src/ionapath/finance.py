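"""DuPont financial decomposition of a case mix.

Revenue is bundled-payment (QBP) compensation per procedure; expenses are
all-inclusive case costs (equipment, saline, sterilization, anesthesia).
Profit = revenue - expenses and profit margin = profit / revenue, per
standard accounting (GAAP) conventions.

Billing heuristic: IONA meniscectomy, diagnostic IONA, and IONA revision
are all billed at the OR meniscectomy/diagnostic-arthroscopy QBP rate, so
every patient is billed exactly once.  Expense mapping: office procedures
cost one IONA disposable set; an IONA revision consumes the disposable
*and* a full OR repair.

The hospital's per-case unit rates are not published; ``calibrate_unit_rates``
recovers the five-rate vector by ordinary least squares against the eight
published mean financial line items (four current-state lines plus the
four IONA lines of the proposed state), given the base-case expected case
mixes those lines were generated from.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .pathway import CaseMix, ProcedureKind

logger = logging.getLogger(__name__)


class FinanceError(ValueError):
    """Invalid rates, statements, or ICUR inputs."""


class CalibrationError(FinanceError):
    """Unit-rate calibration failed (ill-conditioned or poor fit)."""


#: Statement line keys, shared by revenue and expense sides.
LINE_KEYS = ("or_meniscectomy_da", "or_repair", "iona_meniscectomy_da", "iona_revision")

#: Canonical keys for the published mean line items used in calibration.
CALIBRATION_LINE_KEYS = (
    "current_or_meniscectomy_da_billing",
    "current_or_repair_billing",
    "current_or_meniscectomy_da_cost",
    "current_or_repair_cost",
    "proposed_iona_meniscectomy_da_billing",
    "proposed_iona_revision_billing",
    "proposed_iona_meniscectomy_da_cost",
    "proposed_iona_revision_cost",
)

#: Maximum tolerated relative residual on any calibrated line.
CALIBRATION_RESIDUAL_TOL = 0.10


@dataclass(frozen=True)
class UnitRates:
    """Per-case billing and cost rates, CAD/case.

    ``billing_meniscectomy_da`` covers OR meniscectomy and diagnostic
    arthroscopy (published lines pool them) and, by the billing heuristic,
    all IONA procedures.  ``cost_iona_disposable`` is the per-IONA
    disposable cost, the only new expense of the office pathway.
    """

    billing_meniscectomy_da: float
    billing_repair: float
    cost_meniscectomy_da: float
    cost_repair: float
    cost_iona_disposable: float

    def __post_init__(self) -> None:
        for name in (
            "billing_meniscectomy_da",
            "billing_repair",
            "cost_meniscectomy_da",
            "cost_repair",
            "cost_iona_disposable",
        ):
            if getattr(self, name) < 0:
                raise FinanceError(f"{name} must be non-negative, got {getattr(self, name)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rate": list(self.__dataclass_fields__), "cad_per_case": [getattr(self, f) for f in self.__dataclass_fields__]}
        )


@dataclass(frozen=True)
class FinancialStatement:
    """One state's annual revenue/expense lines, totals, profit, margin."""

    revenue: Dict[str, float]
    expenses: Dict[str, float]
    revenue_total: float
    expenses_total: float
    profit: float
    profit_margin: Optional[float]  # None (flagged) when revenue_total is 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("revenue", k, v) for k, v in self.revenue.items()]
        rows += [("revenue", "total", self.revenue_total)]
        rows += [("expense", k, v) for k, v in self.expenses.items()]
        rows += [("expense", "total", self.expenses_total)]
        rows += [("profit", "profit", self.profit)]
        rows += [("profit", "margin", float("nan") if self.profit_margin is None else self.profit_margin)]
        return pd.DataFrame(rows, columns=["side", "line", "cad_per_year"])


def statement(mix: CaseMix, rates: UnitRates) -> FinancialStatement:
    """Evaluate the DuPont tree for one case mix."""
    n_mda = mix[ProcedureKind.OR_MENISCECTOMY] + mix[ProcedureKind.OR_DIAGNOSTIC]
    n_rep = mix[ProcedureKind.OR_REPAIR]
    n_iona = mix[ProcedureKind.IONA_MENISCECTOMY] + mix[ProcedureKind.IONA_DIAGNOSTIC]
    n_rev = mix[ProcedureKind.IONA_REVISION]

    revenue = {
        "or_meniscectomy_da": n_mda * rates.billing_meniscectomy_da,
        "or_repair": n_rep * rates.billing_repair,
        "iona_meniscectomy_da": n_iona * rates.billing_meniscectomy_da,
        "iona_revision": n_rev * rates.billing_meniscectomy_da,
    }
    expenses = {
        "or_meniscectomy_da": n_mda * rates.cost_meniscectomy_da,
        "or_repair": n_rep * rates.cost_repair,
        "iona_meniscectomy_da": n_iona * rates.cost_iona_disposable,
        "iona_revision": n_rev * (rates.cost_iona_disposable + rates.cost_repair),
    }
    revenue_total = sum(revenue.values())
    expenses_total = sum(expenses.values())
    profit = revenue_total - expenses_total
    margin = profit / revenue_total if revenue_total > 0 else None
    return FinancialStatement(
        revenue=revenue,
        expenses=expenses,
        revenue_total=revenue_total,
        expenses_total=expenses_total,
        profit=profit,
        profit_margin=margin,
    )


#: Per-procedure (billing, cost) coefficient names, used both by the
#: statement mapping above and by the synthetic per-case generator.
def per_case_amounts(rates: UnitRates) -> Dict[ProcedureKind, tuple]:
    """(billing, cost) per single case of each procedure kind."""
    b_m, b_r = rates.billing_meniscectomy_da, rates.billing_repair
    c_m, c_r, c_d = rates.cost_meniscectomy_da, rates.cost_repair, rates.cost_iona_disposable
    return {
        ProcedureKind.OR_MENISCECTOMY: (b_m, c_m),
        ProcedureKind.OR_DIAGNOSTIC: (b_m, c_m),
        ProcedureKind.OR_REPAIR: (b_r, c_r),
        ProcedureKind.IONA_MENISCECTOMY: (b_m, c_d),
        ProcedureKind.IONA_DIAGNOSTIC: (b_m, c_d),
        ProcedureKind.IONA_REVISION: (b_m, c_d + c_r),
    }


@dataclass(frozen=True)
class CalibrationResult:
    rates: UnitRates
    residuals: Dict[str, float]  # per-line relative residual (fitted - observed)/observed

    @property
    def max_abs_residual(self) -> float:
        return max(abs(v) for v in self.residuals.values())


def calibrate_unit_rates(
    printed_lines: Mapping[str, float],
    current_mix: CaseMix,
    proposed_mix: CaseMix,
    *,
    weight_by_magnitude: bool = False,
) -> CalibrationResult:
    """Least-squares recovery of the five unit rates from published lines.

    ``printed_lines`` must contain the eight :data:`CALIBRATION_LINE_KEYS`.
    Each line is modelled as (count from the given base-case mix) x (the
    rate combination that generates it); the stacked linear system is
    solved by ordinary least squares (optionally weighted by line
    magnitude).  Raises :class:`CalibrationError` if the system is
    ill-conditioned or any relative residual reaches 10% — the published
    lines are internally inconsistent at the few-percent level, so a
    larger misfit signals a wrong case mix rather than table noise.
    """
    missing = [k for k in CALIBRATION_LINE_KEYS if k not in printed_lines]
    if missing:
        raise CalibrationError(f"printed_lines missing: {', '.join(missing)}")

    cur_mda = current_mix[ProcedureKind.OR_MENISCECTOMY] + current_mix[ProcedureKind.OR_DIAGNOSTIC]
    cur_rep = current_mix[ProcedureKind.OR_REPAIR]
    iona_mda = (
        proposed_mix[ProcedureKind.IONA_MENISCECTOMY]
        + proposed_mix[ProcedureKind.IONA_DIAGNOSTIC]
    )
    iona_rev = proposed_mix[ProcedureKind.IONA_REVISION]

    # columns: [billing_mda, billing_repair, cost_mda, cost_repair, cost_disposable]
    rows = {
        "current_or_meniscectomy_da_billing": [cur_mda, 0, 0, 0, 0],
        "current_or_repair_billing": [0, cur_rep, 0, 0, 0],
        "current_or_meniscectomy_da_cost": [0, 0, cur_mda, 0, 0],
        "current_or_repair_cost": [0, 0, 0, cur_rep, 0],
        "proposed_iona_meniscectomy_da_billing": [iona_mda, 0, 0, 0, 0],
        "proposed_iona_revision_billing": [iona_rev, 0, 0, 0, 0],
        "proposed_iona_meniscectomy_da_cost": [0, 0, 0, 0, iona_mda],
        "proposed_iona_revision_cost": [0, 0, 0, iona_rev, iona_rev],
    }
    A = np.array([rows[k] for k in CALIBRATION_LINE_KEYS], dtype=float)
    y = np.array([float(printed_lines[k]) for k in CALIBRATION_LINE_KEYS])
    if weight_by_magnitude:
        w = 1.0 / np.maximum(np.abs(y), 1e-12)
        A = A * w[:, None]
        y = y * w

    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise CalibrationError("calibration system is singular: a rate is unidentified")
    solution, *_ = np.linalg.lstsq(A, y, rcond=None)
    if np.any(solution < 0):
        raise CalibrationError(f"calibration produced a negative rate: {solution}")

    rates = UnitRates(*solution)
    fitted_rows = np.array([rows[k] for k in CALIBRATION_LINE_KEYS], dtype=float) @ solution
    observed = np.array([float(printed_lines[k]) for k in CALIBRATION_LINE_KEYS])
    residuals = {
        k: (f - o) / o if o != 0 else 0.0
        for k, f, o in zip(CALIBRATION_LINE_KEYS, fitted_rows, observed)
    }
    result = CalibrationResult(rates=rates, residuals=residuals)
    if result.max_abs_residual >= CALIBRATION_RESIDUAL_TOL:
        worst = max(residuals, key=lambda k: abs(residuals[k]))
        raise CalibrationError(
            f"calibration residual {residuals[worst]:.1%} on {worst} exceeds "
            f"{CALIBRATION_RESIDUAL_TOL:.0%}"
        )
    for field_name in rates.__dataclass_fields__:
        logger.info("calibrated %s = %.2f CAD/case", field_name, getattr(rates, field_name))
    return result


def icur(annual_savings: float, qaly_gain: float) -> float:
    """Incremental cost-utility ratio: annual savings per QALY gained."""
    if qaly_gain <= 0:
        raise FinanceError(f"qaly_gain must be positive, got {qaly_gain}")
    return annual_savings / qaly_gain
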