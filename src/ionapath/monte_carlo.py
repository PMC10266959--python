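"""Monte Carlo engine over annual patient volumes.

Annual volume is the only stochastic input: draws come from a Normal
distribution on the observed mean and SD of annual bookings, truncated
below at zero and rounded to whole patients.  Each draw is evaluated in
*both* states (paired design), allocation within the tree being
deterministic-fractional, so every financial metric is exactly
proportional to the draw and the between-state differences inherit the
volume distribution's coefficient of variation.

The per-metric summary reports the mean and SD across draws; the state
comparison reports the difference of means, the percentage difference of
means, and both the paired t-test (primary — the simulation is naturally
paired) and the unpaired Welch variant (reported alongside, since a
paired test on differences that are exactly proportional to volume is
degenerate-significant even for economically negligible differences).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_half_away
from .evidence import ArmProbabilities
from .finance import UnitRates, statement
from .pathway import ScenarioParams, expected_case_mix
from .throughput import throughput_from_mixes


class SimulationError(ValueError):
    """Invalid simulation configuration or inputs."""


@dataclass(frozen=True)
class SimulationConfig:
    """Volume distribution and scenario for one paired simulation run."""

    n_sims: int = 10_000
    volume_mean: float = 198.0
    volume_sd: float = 31.0
    seed: Optional[int] = None
    current: ScenarioParams = field(default_factory=ScenarioParams.current)
    proposed: ScenarioParams = field(default_factory=ScenarioParams.proposed)

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise SimulationError(f"n_sims must be >= 1, got {self.n_sims}")
        if self.volume_sd < 0:
            raise SimulationError(f"volume_sd must be >= 0, got {self.volume_sd}")
        if self.volume_mean < 0:
            raise SimulationError(f"volume_mean must be >= 0, got {self.volume_mean}")


def draw_volumes(config: SimulationConfig) -> np.ndarray:
    """Annual volumes: Normal(mean, sd), truncated at 0, whole patients."""
    rng = np.random.default_rng(config.seed)
    draws = rng.normal(config.volume_mean, config.volume_sd, size=config.n_sims)
    draws = np.clip(draws, 0.0, None)
    return np.floor(draws + 0.5)  # round half away (draws are non-negative)


_METRIC_ORDER = (
    "revenue_total",
    "expenses_total",
    "profit",
    "profit_margin",
    "revenue_or_meniscectomy_da",
    "revenue_or_repair",
    "revenue_iona_meniscectomy_da",
    "revenue_iona_revision",
    "expense_or_meniscectomy_da",
    "expense_or_repair",
    "expense_iona_meniscectomy_da",
    "expense_iona_revision",
)


def _unit_metrics(probs: ArmProbabilities, rates: UnitRates, params: ScenarioParams):
    """Per-patient metric values (the statement is linear in volume)."""
    mix = expected_case_mix(1.0, probs, params)
    st = statement(mix, rates)
    unit = {
        "revenue_total": st.revenue_total,
        "expenses_total": st.expenses_total,
        "profit": st.profit,
    }
    for key, value in st.revenue.items():
        unit[f"revenue_{key}"] = value
    for key, value in st.expenses.items():
        unit[f"expense_{key}"] = value
    margin = st.profit_margin if st.profit_margin is not None else float("nan")
    return unit, margin


def _sample_sd(values: np.ndarray) -> float:
    """Sample SD; exactly 0 for constant sequences (no cancellation noise)."""
    if values.size <= 1 or np.ptp(values) == 0.0:
        return 0.0
    return float(np.std(values, ddof=1))


@dataclass(frozen=True)
class SimulationSummary:
    """Across-draw mean/SD table plus throughput headline figures."""

    table: pd.DataFrame  # columns: metric, state, mean, sd
    diverted_mean: float
    diverted_sd: float
    volume_mean: float

    @property
    def headline_diverted(self) -> float:
        """Mean diverted count rounded to whole patients."""
        return round_half_away(self.diverted_mean)

    @property
    def throughput_pct(self) -> float:
        """Headline throughput: rounded mean diverted over mean volume, %.

        The SD companion divides the diverted-count SD by the same mean
        volume rather than forming a per-draw ratio (per-draw the ratio is
        constant under deterministic allocation).
        """
        if self.volume_mean == 0:
            return 0.0
        return round_half_away(self.headline_diverted / self.volume_mean * 100.0, 1)

    @property
    def throughput_pct_sd(self) -> float:
        if self.volume_mean == 0:
            return 0.0
        return self.diverted_sd / self.volume_mean * 100.0

    def metric(self, name: str, state: str) -> tuple:
        row = self.table[(self.table.metric == name) & (self.table.state == state)]
        if row.empty:
            raise KeyError(f"no metric {name!r} for state {state!r}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


@dataclass(frozen=True)
class McsResult:
    """Paired per-draw metric arrays for both states, plus the summary."""

    volumes: np.ndarray
    current: Dict[str, np.ndarray]
    proposed: Dict[str, np.ndarray]
    diverted: np.ndarray
    config: SimulationConfig

    def summary(self) -> SimulationSummary:
        rows = []
        for state_name, metrics in (("current", self.current), ("proposed", self.proposed)):
            for name in _METRIC_ORDER:
                values = metrics[name]
                rows.append((name, state_name, float(np.mean(values)), _sample_sd(values)))
        rows.append(
            ("diverted", "proposed", float(np.mean(self.diverted)), _sample_sd(self.diverted))
        )
        table = pd.DataFrame(rows, columns=["metric", "state", "mean", "sd"])
        return SimulationSummary(
            table=table,
            diverted_mean=float(np.mean(self.diverted)),
            diverted_sd=_sample_sd(self.diverted),
            volume_mean=self.config.volume_mean,
        )


def run_mcs(
    config: SimulationConfig, probs: ArmProbabilities, rates: UnitRates
) -> McsResult:
    """Draw volumes once and evaluate both states on every draw."""
    if not isinstance(rates, UnitRates):
        raise SimulationError("calibrated unit rates are required before simulation")
    volumes = draw_volumes(config)

    state_metrics: Dict[str, Dict[str, np.ndarray]] = {}
    for state_name, params in (("current", config.current), ("proposed", config.proposed)):
        unit, margin = _unit_metrics(probs, rates, params)
        metrics = {name: volumes * unit[name] for name in unit}
        metrics["profit_margin"] = np.full_like(volumes, margin, dtype=float)
        state_metrics[state_name] = metrics

    cur_mix = expected_case_mix(1.0, probs, config.current)
    prop_mix = expected_case_mix(1.0, probs, config.proposed)
    unit_diverted = throughput_from_mixes(cur_mix, prop_mix).diverted
    diverted = volumes * unit_diverted

    return McsResult(
        volumes=volumes,
        current=state_metrics["current"],
        proposed=state_metrics["proposed"],
        diverted=diverted,
        config=config,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Between-state comparison of one metric across paired draws."""

    metric: str
    mean_current: float
    mean_proposed: float
    difference: float  # proposed - current, on means
    pct_difference: float  # (proposed - current) / current * 100, on means
    t_paired: float
    p_paired: float
    t_welch: float
    p_welch: float
    degenerate: bool  # paired differences have zero variance


def compare_states(result: McsResult, metrics: Optional[list] = None) -> Dict[str, ComparisonResult]:
    """Paired (primary) and Welch t-tests per metric, on shared draws."""
    if result.volumes.size < 2:
        raise SimulationError("need at least 2 draws to compare states")
    if metrics is None:
        metrics = ["revenue_total", "expenses_total", "profit", "profit_margin"]
    out = {}
    for name in metrics:
        cur = result.current[name]
        prop = result.proposed[name]
        diff = prop - cur
        mean_cur, mean_prop = float(np.mean(cur)), float(np.mean(prop))
        pct = (mean_prop - mean_cur) / mean_cur * 100.0 if mean_cur != 0 else float("nan")
        degenerate = bool(np.ptp(diff) == 0.0)  # constant per-draw difference
        if degenerate:
            t_p = p_p = float("nan")
        else:
            t_p, p_p = stats.ttest_rel(prop, cur)
        if np.ptp(cur) == 0.0 and np.ptp(prop) == 0.0:
            t_w = p_w = float("nan")
        else:
            t_w, p_w = stats.ttest_ind(prop, cur, equal_var=False)
        out[name] = ComparisonResult(
            metric=name,
            mean_current=mean_cur,
            mean_proposed=mean_prop,
            difference=mean_prop - mean_cur,
            pct_difference=pct,
            t_paired=float(t_p),
            p_paired=float(p_p),
            t_welch=float(t_w),
            p_welch=float(p_w),
            degenerate=degenerate,
        )
    return out
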