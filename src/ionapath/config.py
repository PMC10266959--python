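"""Model configuration: schema, validation, YAML loading.

One structured-text (YAML) file holds every model parameter — pooled
evidence counts, the annual-volume distribution, scenario parameters,
the financial block (either published mean line items for calibration or
explicit unit rates, never both), and simulation/sensitivity settings.
Validation reports every violated constraint with its field path, not
just the first.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import evidence
from .finance import CALIBRATION_LINE_KEYS, UnitRates
from .monte_carlo import SimulationConfig
from .pathway import ScenarioParams


class ConfigError(ValueError):
    """Configuration file failed to parse or validate."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CountsBlock(_Block):
    events: int = Field(ge=0)
    total: int = Field(gt=0)

    @model_validator(mode="after")
    def _events_le_total(self) -> "CountsBlock":
        if self.events > self.total:
            raise ValueError(f"events ({self.events}) exceed total ({self.total})")
        return self

    def to_study(self, label: str) -> evidence.StudyCounts:
        return evidence.StudyCounts(label=label, events=self.events, total=self.total)


class ArmCountsBlock(_Block):
    repaired: CountsBlock
    resected: CountsBlock


class EvidenceBlock(_Block):
    repairable: CountsBlock
    irreparable: CountsBlock
    repairable_arm: ArmCountsBlock
    irreparable_arm: ArmCountsBlock
    fp_rate: float = Field(ge=0.0, le=1.0)
    use_printed_rounding: bool = True


class VolumeBlock(_Block):
    mean: float = Field(ge=0.0)
    sd: float = Field(ge=0.0)
    years: int = Field(default=5, ge=1)


class ProposedScenarioBlock(_Block):
    selection_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    revision_rate: float = Field(default=0.203, ge=0.0, le=1.0)


class ScenarioBlock(_Block):
    proposed: ProposedScenarioBlock = ProposedScenarioBlock()


class UnitRatesBlock(_Block):
    billing_meniscectomy_da: float = Field(ge=0.0)
    billing_repair: float = Field(ge=0.0)
    cost_meniscectomy_da: float = Field(ge=0.0)
    cost_repair: float = Field(ge=0.0)
    cost_iona_disposable: float = Field(ge=0.0)


class FinanceBlock(_Block):
    printed_lines: Optional[Dict[str, float]] = None
    unit_rates: Optional[UnitRatesBlock] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "FinanceBlock":
        if (self.printed_lines is None) == (self.unit_rates is None):
            raise ValueError(
                "finance block must provide exactly one of 'printed_lines' or 'unit_rates'"
            )
        if self.printed_lines is not None:
            missing = [k for k in CALIBRATION_LINE_KEYS if k not in self.printed_lines]
            if missing:
                raise ValueError(f"printed_lines missing keys: {', '.join(missing)}")
        return self


class SimulationBlock(_Block):
    n_sims: int = Field(default=10_000, ge=1)
    seed: int = 42


class SensitivityBlock(_Block):
    step: float = Field(default=0.10, gt=0.0, le=1.0)
    metrics: List[Literal["profit", "margin", "throughput", "throughput_fraction"]] = Field(
        default_factory=lambda: ["profit", "margin", "throughput"]
    )


class ModelConfig(_Block):
    """Validated top-level configuration."""

    schema_version: int = 1
    evidence: EvidenceBlock
    volume: VolumeBlock
    scenario: ScenarioBlock = ScenarioBlock()
    finance: FinanceBlock
    simulation: SimulationBlock = SimulationBlock()
    sensitivity: SensitivityBlock = SensitivityBlock()

    # -- conversions into domain objects ---------------------------------

    def arm_probabilities(self) -> evidence.ArmProbabilities:
        ev = self.evidence
        return evidence.build_arm_probabilities(
            repairable=evidence.pool_proportion([ev.repairable.to_study("MRI likely repairable")]),
            irreparable=evidence.pool_proportion(
                [ev.irreparable.to_study("MRI likely irreparable")]
            ),
            repairable_arm_counts={
                "repaired": ev.repairable_arm.repaired.to_study("repairable/repaired"),
                "resected": ev.repairable_arm.resected.to_study("repairable/resected"),
            },
            irreparable_arm_counts={
                "repaired": ev.irreparable_arm.repaired.to_study("irreparable/repaired"),
                "resected": ev.irreparable_arm.resected.to_study("irreparable/resected"),
            },
            fp_rate=ev.fp_rate,
            use_printed_rounding=ev.use_printed_rounding,
        )

    def scenario_params(self) -> Dict[str, ScenarioParams]:
        p = self.scenario.proposed
        return {
            "current": ScenarioParams.current(),
            "proposed": ScenarioParams.proposed(
                selection_fraction=p.selection_fraction, revision_rate=p.revision_rate
            ),
        }

    def explicit_unit_rates(self) -> Optional[UnitRates]:
        if self.finance.unit_rates is None:
            return None
        return UnitRates(**self.finance.unit_rates.model_dump())

    def simulation_config(
        self, n_sims: Optional[int] = None, seed: Optional[int] = None
    ) -> SimulationConfig:
        scenarios = self.scenario_params()
        return SimulationConfig(
            n_sims=n_sims if n_sims is not None else self.simulation.n_sims,
            volume_mean=self.volume.mean,
            volume_sd=self.volume.sd,
            seed=seed if seed is not None else self.simulation.seed,
            current=scenarios["current"],
            proposed=scenarios["proposed"],
        )

    def content_hash(self) -> str:
        """Stable SHA-256 of the canonicalised configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: Path | str) -> ModelConfig:
    """Load and validate a YAML model configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping at top level")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ModelConfig:
    """Validate an in-memory configuration mapping."""
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
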