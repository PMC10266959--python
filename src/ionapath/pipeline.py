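"""End-to-end pipeline: pooling -> tree -> calibration -> MCS -> sensitivity.

``run_pipeline`` executes every stage from one configuration and writes
CSV outputs plus a run manifest (seed, configuration hash, versions) so a
run is regenerable from the manifest alone.  Output is byte-stable under
a fixed seed: currency columns serialise at two decimals, everything else
at full precision.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig
from .evidence import ArmProbabilities
from .finance import CalibrationResult, UnitRates, calibrate_unit_rates, statement
from .monte_carlo import McsResult, compare_states, run_mcs
from .pathway import CaseMix, expected_case_mix
from .sensitivity import SensitivityGrid, ThresholdReport, default_axis, find_thresholds, profit_grid, throughput_grid
from .throughput import ThroughputResult, throughput_from_mixes

logger = logging.getLogger(__name__)

CURRENCY_FORMAT = "%.2f"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    probs: ArmProbabilities
    rates: UnitRates
    calibration: Optional[CalibrationResult]
    current_mix: CaseMix
    proposed_mix: CaseMix
    throughput: ThroughputResult
    mcs: McsResult
    comparisons: Dict
    grids: Dict[str, SensitivityGrid]
    thresholds: Optional[ThresholdReport]
    outputs: Dict[str, Path]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return inner

    return wrap


def calibrated_rates(config: ModelConfig) -> tuple:
    """Arm probabilities plus unit rates (explicit or calibrated)."""
    probs = config.arm_probabilities()
    scenarios = config.scenario_params()
    n = config.volume.mean
    current_mix = expected_case_mix(n, probs, scenarios["current"])
    proposed_mix = expected_case_mix(n, probs, scenarios["proposed"])
    explicit = config.explicit_unit_rates()
    if explicit is not None:
        return probs, explicit, None, current_mix, proposed_mix
    calibration = calibrate_unit_rates(config.finance.printed_lines, current_mix, proposed_mix)
    return probs, calibration.rates, calibration, current_mix, proposed_mix


def run_pipeline(
    config: ModelConfig,
    out_dir: Path | str,
    *,
    n_sims: Optional[int] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run every stage and write outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    probs, rates, calibration, current_mix, proposed_mix = _stage("calibration")(
        calibrated_rates
    )(config)
    tp = _stage("throughput")(throughput_from_mixes)(current_mix, proposed_mix)

    sim_config = config.simulation_config(n_sims=n_sims, seed=seed)
    mcs = _stage("monte_carlo")(run_mcs)(sim_config, probs, rates)
    summary = mcs.summary()
    comparisons = _stage("comparison")(compare_states)(mcs)

    axis = default_axis(config.sensitivity.step)
    grids: Dict[str, SensitivityGrid] = {}
    for metric in config.sensitivity.metrics:
        if metric in ("profit", "margin"):
            grids[metric] = _stage("sensitivity")(profit_grid)(
                probs, rates, config.volume.mean, axis, axis, metric=metric
            )
        else:
            grids[metric] = _stage("sensitivity")(throughput_grid)(
                probs,
                config.volume.mean,
                axis,
                axis,
                baseline_params=config.scenario_params()["proposed"],
                as_fraction=(metric == "throughput_fraction"),
            )
    thresholds = find_thresholds(grids["profit"]) if "profit" in grids else None

    outputs: Dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame, currency: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format=CURRENCY_FORMAT if currency else None)
        outputs[name] = path

    mix_frame = pd.concat(
        [
            current_mix.to_frame().assign(state="current"),
            proposed_mix.to_frame().assign(state="proposed"),
        ]
    )
    write_csv("case_mix.csv", mix_frame)
    write_csv("unit_rates.csv", rates.to_frame(), currency=True)
    write_csv("mcs_summary.csv", summary.table)
    comp_frame = pd.DataFrame(
        [
            {
                "metric": c.metric,
                "mean_current": c.mean_current,
                "mean_proposed": c.mean_proposed,
                "difference": c.difference,
                "pct_difference": c.pct_difference,
                "t_paired": c.t_paired,
                "p_paired": c.p_paired,
                "t_welch": c.t_welch,
                "p_welch": c.p_welch,
                "degenerate": c.degenerate,
            }
            for c in comparisons.values()
        ]
    )
    write_csv("mcs_comparison.csv", comp_frame)
    for metric, grid in grids.items():
        write_csv(f"sensitivity_{metric}.csv", grid.to_frame())
        write_csv(f"sensitivity_{metric}_classes.csv", grid.classes_to_frame())
    if thresholds is not None:
        rows = []
        for name, th in (("beats_current", thresholds.beats_baseline), ("positive_profit", thresholds.positive)):
            if th is not None:
                rows.append({"condition": name, "min_selection": th.min_selection, "max_revision": th.max_revision})
        write_csv("thresholds.csv", pd.DataFrame(rows, columns=["condition", "min_selection", "max_revision"]))

    report_lines = [
        "Care-pathway diversion model: run report",
        f"annual volume: Normal({config.volume.mean:g}, {config.volume.sd:g}), "
        f"{sim_config.n_sims} simulations, seed {sim_config.seed}",
        f"base case: selection {config.scenario.proposed.selection_fraction:.0%}, "
        f"revision {config.scenario.proposed.revision_rate:.1%}",
        "",
        f"mean diverted patients/year: {summary.diverted_mean:.2f} "
        f"(SD {summary.diverted_sd:.2f}) -> headline {summary.headline_diverted:.0f} "
        f"({summary.throughput_pct:.1f}% of volume)",
    ]
    for metric in ("revenue_total", "expenses_total", "profit"):
        cur_mean, cur_sd = summary.metric(metric, "current")
        prop_mean, prop_sd = summary.metric(metric, "proposed")
        comp = comparisons[metric]
        report_lines.append(
            f"{metric}: current ${cur_mean:,.2f} (SD ${cur_sd:,.2f}) vs proposed "
            f"${prop_mean:,.2f} (SD ${prop_sd:,.2f}); diff {comp.pct_difference:+.1f}%, "
            f"paired p={comp.p_paired:.3g}, Welch p={comp.p_welch:.3g}"
        )
    savings = summary.metric("expenses_total", "current")[0] - summary.metric("expenses_total", "proposed")[0]
    report_lines.append(f"annual expense savings: ${savings:,.2f}")
    if thresholds is not None and thresholds.beats_baseline is not None:
        th = thresholds.beats_baseline
        report_lines.append(
            f"profit beats current state from selection {th.min_selection:.0%} "
            f"(revision up to {th.max_revision:.0%})"
        )
    if thresholds is not None and thresholds.positive is not None:
        th = thresholds.positive
        report_lines.append(
            f"positive profit from selection {th.min_selection:.0%} "
            f"(revision up to {th.max_revision:.0%})"
        )
    report_path = out / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    outputs["report.txt"] = report_path

    manifest = {
        "package": "ionapath",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": sim_config.seed,
        "n_sims": sim_config.n_sims,
        "config_sha256": config.content_hash(),
        "outputs": sorted(outputs),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest.json"] = manifest_path

    for line in report_lines:
        logger.info("%s", line)

    return PipelineResult(
        probs=probs,
        rates=rates,
        calibration=calibration,
        current_mix=current_mix,
        proposed_mix=proposed_mix,
        throughput=tp,
        mcs=mcs,
        comparisons=comparisons,
        grids=grids,
        thresholds=thresholds,
        outputs=outputs,
    )
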