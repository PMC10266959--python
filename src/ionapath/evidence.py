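"""Pooled literature evidence for the meniscal-tear decision tree.

The decision tree's branch probabilities come from a literature pool of
preoperative-MRI repairability studies: a top-level split into
MRI-likely-repairable vs MRI-likely-irreparable, and, within each MRI arm,
the observed shares of patients eventually repaired or resected.  Because
a fixed fraction of MRI-positive knees are false positives (arthroscopy
finds no treatable tear), the pooled repair/resection shares are scaled by
``1 - fp_rate`` and the remaining mass becomes the diagnostic-arthroscopy
branch of each arm.

Pooling is a fixed-effect summation of counts across studies; no
heterogeneity weighting is applied.  Percentages are carried at full
precision internally.  ``use_printed_rounding`` instead snaps each pooled
percentage to one decimal before the false-positive adjustment (and again
after), emulating a source that tabulates stage percentages at one decimal
— headline patient counts downstream reconcile only with the rounded
values, so this mode is the default for reproduction runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_away

ARM_SUM_TOL = 0.005  # one-decimal table values can miss 1.0 by half a tenth per branch


class EvidenceError(ValueError):
    """Invalid study counts or arm probabilities."""


@dataclass(frozen=True)
class StudyCounts:
    """Event/total counts for one stage, pooled or per study."""

    label: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise EvidenceError(f"{self.label}: total must be positive, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise EvidenceError(
                f"{self.label}: events must be in [0, total], got {self.events}/{self.total}"
            )


@dataclass(frozen=True)
class PooledEstimate:
    """Fixed-effect pooled proportion with its underlying counts."""

    events: int
    total: int
    proportion: float

    @property
    def percent(self) -> float:
        """Percentage at full precision."""
        return self.proportion * 100.0

    @property
    def printed_percent(self) -> float:
        """Percentage rounded to one decimal, ties away from zero."""
        return round_half_away(self.percent, 1)


@dataclass(frozen=True)
class ArmSplit:
    """Treatment shares within one MRI arm; sums to 1 within tolerance."""

    p_repair: float
    p_resect: float
    p_diagnostic: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_repair, self.p_resect, self.p_diagnostic)


@dataclass(frozen=True)
class ArmProbabilities:
    """Full branch-probability set of the decision tree."""

    p_repairable: float
    p_irreparable: float
    repairable: ArmSplit
    irreparable: ArmSplit
    fp_rate: float

    def __post_init__(self) -> None:
        fields = {
            "p_repairable": self.p_repairable,
            "p_irreparable": self.p_irreparable,
            "fp_rate": self.fp_rate,
        }
        for arm_name, arm in (("repairable", self.repairable), ("irreparable", self.irreparable)):
            fields.update(
                {
                    f"{arm_name}.p_repair": arm.p_repair,
                    f"{arm_name}.p_resect": arm.p_resect,
                    f"{arm_name}.p_diagnostic": arm.p_diagnostic,
                }
            )
        for name, value in fields.items():
            if not 0.0 <= value <= 1.0:
                raise EvidenceError(f"{name} must be in [0, 1], got {value}")
        if abs(self.p_repairable + self.p_irreparable - 1.0) > ARM_SUM_TOL:
            raise EvidenceError(
                "repairable and irreparable fractions must be complementary, got "
                f"{self.p_repairable} + {self.p_irreparable}"
            )
        for arm_name, arm in (("repairable", self.repairable), ("irreparable", self.irreparable)):
            total = arm.p_repair + arm.p_resect + arm.p_diagnostic
            if abs(total - 1.0) > ARM_SUM_TOL:
                raise EvidenceError(
                    f"{arm_name} arm branches sum to {total:.4f}, outside 1 ± {ARM_SUM_TOL}"
                )


def pool_proportion(studies: Sequence[StudyCounts] | Iterable[StudyCounts]) -> PooledEstimate:
    """Fixed-effect pooling: sum events and totals across studies."""
    studies = list(studies)
    if not studies:
        raise EvidenceError("no studies to pool")
    events = sum(s.events for s in studies)
    total = sum(s.total for s in studies)
    if total <= 0:
        raise EvidenceError("pooled total is zero")
    return PooledEstimate(events=events, total=total, proportion=events / total)


def adjust_for_diagnostic_arthroscopy(pooled_fraction: float, fp_rate: float) -> float:
    """Scale a within-arm treatment share by one minus the MRI false-positive rate.

    The false-positive mass of each MRI arm resolves as diagnostic
    arthroscopy; the remaining ``1 - fp_rate`` is shared by repair and
    resection in their pooled proportions.
    """
    for name, value in (("pooled_fraction", pooled_fraction), ("fp_rate", fp_rate)):
        if not 0.0 <= value <= 1.0:
            raise EvidenceError(f"{name} must be in [0, 1], got {value}")
    return pooled_fraction * (1.0 - fp_rate)


def build_arm_probabilities(
    repairable: PooledEstimate,
    irreparable: PooledEstimate,
    repairable_arm_counts: Mapping[str, StudyCounts],
    irreparable_arm_counts: Mapping[str, StudyCounts],
    fp_rate: float,
    use_printed_rounding: bool = False,
) -> ArmProbabilities:
    """Assemble the tree's branch probabilities from pooled evidence.

    ``*_arm_counts`` map ``"repaired"`` and ``"resected"`` to pooled counts
    within that MRI arm.  ``p_diagnostic`` equals ``fp_rate`` in both arms.
    """
    if repairable.total != irreparable.total:
        raise EvidenceError(
            "repairable and irreparable stages must come from the same pool, got totals "
            f"{repairable.total} and {irreparable.total}"
        )

    def top_level(est: PooledEstimate) -> float:
        if use_printed_rounding:
            return est.printed_percent / 100.0
        return est.proportion

    def arm_split(counts: Mapping[str, StudyCounts], arm_name: str) -> ArmSplit:
        shares = {}
        for branch in ("repaired", "resected"):
            if branch not in counts:
                raise EvidenceError(f"{arm_name} arm is missing '{branch}' counts")
            pooled = pool_proportion([counts[branch]])
            frac = pooled.printed_percent / 100.0 if use_printed_rounding else pooled.proportion
            adjusted = adjust_for_diagnostic_arthroscopy(frac, fp_rate)
            if use_printed_rounding:
                adjusted = round_half_away(adjusted * 100.0, 1) / 100.0
            shares[branch] = adjusted
        split = ArmSplit(
            p_repair=shares["repaired"], p_resect=shares["resected"], p_diagnostic=fp_rate
        )
        total = sum(split.as_tuple())
        if abs(total - 1.0) > ARM_SUM_TOL:
            raise EvidenceError(
                f"{arm_name} arm branches sum to {total:.4f}, outside 1 ± {ARM_SUM_TOL}"
            )
        return split

    return ArmProbabilities(
        p_repairable=top_level(repairable),
        p_irreparable=top_level(irreparable),
        repairable=arm_split(repairable_arm_counts, "repairable"),
        irreparable=arm_split(irreparable_arm_counts, "irreparable"),
        fp_rate=fp_rate,
    )
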