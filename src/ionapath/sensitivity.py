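"""Two-way sensitivity grids over IONA selection and revision rates.

Each grid sweeps the selection fraction ``s`` (rows) against the revision
rate ``r`` (columns), evaluating the proposed state deterministically at a
fixed annual volume (the Monte Carlo means coincide with the deterministic
values, so per-cell simulation is supported but off by default).

Traffic-light classification:

* profit / margin grids — GREEN when the cell is positive, YELLOW when
  negative but better than the current-state baseline, RED when below the
  baseline; exact equality with the baseline is YELLOW and flagged.
* throughput grids — GREEN when above the base-case (heuristics-model)
  throughput, YELLOW when positive but at or below it, RED when negative;
  equality with the baseline or zero is flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evidence import ArmProbabilities
from .finance import UnitRates, statement
from .pathway import ScenarioParams, expected_case_mix
from .throughput import throughput_from_mixes


class SensitivityError(ValueError):
    """Invalid grid specification."""


class CellClass(str, Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


@dataclass(frozen=True)
class SensitivityGrid:
    """Rectangular (s x r) grid of one metric with traffic-light classes."""

    metric: str  # 'profit' | 'margin' | 'throughput' | 'throughput_fraction'
    s_values: Tuple[float, ...]
    r_values: Tuple[float, ...]
    values: np.ndarray  # shape (len(s_values), len(r_values))
    classes: np.ndarray  # same shape, dtype=object of CellClass
    baseline: float
    flagged: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)

    def value_at(self, s: float, r: float) -> float:
        i = self.s_values.index(s)
        j = self.r_values.index(r)
        return float(self.values[i, j])

    def class_at(self, s: float, r: float) -> CellClass:
        i = self.s_values.index(s)
        j = self.r_values.index(r)
        return self.classes[i, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"r={r:g}" for r in self.r_values])
        df.insert(0, "s", list(self.s_values))
        return df

    def classes_to_frame(self) -> pd.DataFrame:
        labels = np.vectorize(lambda c: c.value)(self.classes)
        df = pd.DataFrame(labels, columns=[f"r={r:g}" for r in self.r_values])
        df.insert(0, "s", list(self.s_values))
        return df


def default_axis(step: float = 0.10) -> Tuple[float, ...]:
    """0..1 inclusive at the given step (default 10 percentage points)."""
    if not 0 < step <= 1:
        raise SensitivityError(f"step must be in (0, 1], got {step}")
    n = int(round(1.0 / step))
    return tuple(round(i * step, 10) for i in range(n + 1))


def _check_axes(s_values: Sequence[float], r_values: Sequence[float]) -> None:
    if not len(s_values) or not len(r_values):
        raise SensitivityError("s_values and r_values must be non-empty")


def _classify_profit(value: float, baseline: float, flagged: List[Tuple[int, int]], ij) -> CellClass:
    if value == baseline:
        flagged.append(ij)
        return CellClass.YELLOW
    if value > 0:
        return CellClass.GREEN
    if value > baseline:
        return CellClass.YELLOW
    return CellClass.RED


def _classify_throughput(value: float, baseline: float, flagged: List[Tuple[int, int]], ij) -> CellClass:
    if value == baseline or value == 0.0:
        flagged.append(ij)
        return CellClass.YELLOW if value >= 0 else CellClass.RED
    if value > baseline:
        return CellClass.GREEN
    if value > 0:
        return CellClass.YELLOW
    return CellClass.RED


def profit_grid(
    probs: ArmProbabilities,
    rates: UnitRates,
    N: float,
    s_values: Optional[Sequence[float]] = None,
    r_values: Optional[Sequence[float]] = None,
    *,
    metric: str = "profit",
) -> SensitivityGrid:
    """Proposed-state profit (or profit margin) over the (s, r) grid."""
    if N <= 0:
        raise SensitivityError(f"N must be positive, got {N}")
    if metric not in ("profit", "margin"):
        raise SensitivityError(f"metric must be 'profit' or 'margin', got {metric!r}")
    s_values = tuple(s_values) if s_values is not None else default_axis()
    r_values = tuple(r_values) if r_values is not None else default_axis()
    _check_axes(s_values, r_values)

    baseline_st = statement(expected_case_mix(N, probs, ScenarioParams.current()), rates)
    baseline = baseline_st.profit if metric == "profit" else (baseline_st.profit_margin or 0.0)

    values = np.empty((len(s_values), len(r_values)))
    classes = np.empty_like(values, dtype=object)
    flagged: List[Tuple[int, int]] = []
    for i, s in enumerate(s_values):
        for j, r in enumerate(r_values):
            params = ScenarioParams.proposed(selection_fraction=s, revision_rate=r)
            st = statement(expected_case_mix(N, probs, params), rates)
            value = st.profit if metric == "profit" else (st.profit_margin or 0.0)
            values[i, j] = value
            classes[i, j] = _classify_profit(value, baseline, flagged, (i, j))
    return SensitivityGrid(
        metric=metric,
        s_values=s_values,
        r_values=r_values,
        values=values,
        classes=classes,
        baseline=baseline,
        flagged=tuple(flagged),
    )


def throughput_grid(
    probs: ArmProbabilities,
    N: float,
    s_values: Optional[Sequence[float]] = None,
    r_values: Optional[Sequence[float]] = None,
    *,
    baseline_params: Optional[ScenarioParams] = None,
    as_fraction: bool = False,
) -> SensitivityGrid:
    """Diverted count (or fraction of N) over the (s, r) grid.

    The baseline is the base-case (heuristics-model) throughput, by
    default s = 0.5, r = 0.203.
    """
    if N <= 0:
        raise SensitivityError(f"N must be positive, got {N}")
    s_values = tuple(s_values) if s_values is not None else default_axis()
    r_values = tuple(r_values) if r_values is not None else default_axis()
    _check_axes(s_values, r_values)
    if baseline_params is None:
        baseline_params = ScenarioParams.proposed()

    current_mix = expected_case_mix(N, probs, ScenarioParams.current())

    def diverted_at(params: ScenarioParams) -> float:
        tp = throughput_from_mixes(current_mix, expected_case_mix(N, probs, params))
        value = tp.fraction if as_fraction else tp.diverted
        # the subtraction form leaves O(1e-14) residue where the exact
        # answer is 0 (s = 0 or r = 1); snap so boundary cells classify
        return 0.0 if abs(value) < 1e-9 else value

    baseline = diverted_at(baseline_params)
    values = np.empty((len(s_values), len(r_values)))
    classes = np.empty_like(values, dtype=object)
    flagged: List[Tuple[int, int]] = []
    for i, s in enumerate(s_values):
        for j, r in enumerate(r_values):
            value = diverted_at(ScenarioParams.proposed(selection_fraction=s, revision_rate=r))
            values[i, j] = value
            classes[i, j] = _classify_throughput(value, baseline, flagged, (i, j))
    return SensitivityGrid(
        metric="throughput_fraction" if as_fraction else "throughput",
        s_values=s_values,
        r_values=r_values,
        values=values,
        classes=classes,
        baseline=baseline,
        flagged=tuple(flagged),
    )


@dataclass(frozen=True)
class Threshold:
    """Smallest selection fraction achieving a condition, and the largest
    revision rate still admissible at that selection fraction."""

    min_selection: float
    max_revision: float


@dataclass(frozen=True)
class ThresholdReport:
    beats_baseline: Optional[Threshold]
    positive: Optional[Threshold]

    @property
    def empty(self) -> bool:
        return self.beats_baseline is None and self.positive is None


def find_thresholds(grid: SensitivityGrid) -> ThresholdReport:
    """Extract break-even thresholds from a profit or margin grid.

    ``beats_baseline``: the minimum s for which some cell strictly exceeds
    the current-state baseline, with the maximum r still qualifying at
    that s.  ``positive``: the same for strictly positive cells.  Either
    entry is absent when no cell qualifies (an empty report, not an error).
    """
    if grid.metric not in ("profit", "margin"):
        raise SensitivityError("thresholds are defined for profit or margin grids")

    def extract(mask: np.ndarray) -> Optional[Threshold]:
        if not mask.any():
            return None
        rows = np.where(mask.any(axis=1))[0]
        i = rows.min()
        j = np.where(mask[i])[0].max()
        return Threshold(min_selection=grid.s_values[i], max_revision=grid.r_values[j])

    return ThresholdReport(
        beats_baseline=extract(grid.values > grid.baseline),
        positive=extract(grid.values > 0.0),
    )
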