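"""Decision-tree pathway model: annual volume -> expected case mix.

Two care states share one tree.  In the *current* state every surgically
booked patient goes to the operating room (OR) and resolves as an OR
repair, OR meniscectomy, or OR diagnostic arthroscopy.  In the *proposed*
state, patients whose MRI reads likely-irreparable are offered in-office
needle arthroscopy (IONA): a fraction ``s`` accepts, of whom a fraction
``r`` turn out to have repairable tears and are revised to a full OR
repair (consuming both the office procedure and an OR slot); the rest
resolve in the office as an IONA meniscectomy or diagnostic IONA.

Structural assumptions baked into the tree: the model starts at patients
already booked for surgery (no non-surgical branch); every IONA revision
is a repair (no crossover to meniscectomy); the repairable arm is never
offered IONA.

Allocation is deterministic-fractional by default — each branch receives
its exact expected mass, so annual randomness enters only through the
volume draw.  A multinomial sampling mode exists for stress testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .evidence import ArmProbabilities


class PathwayError(ValueError):
    """Invalid scenario parameters or case mix."""


class ProcedureKind(str, Enum):
    """The six terminal procedures of the tree."""

    OR_MENISCECTOMY = "OR_MENISCECTOMY"
    OR_REPAIR = "OR_REPAIR"
    OR_DIAGNOSTIC = "OR_DIAGNOSTIC"
    IONA_MENISCECTOMY = "IONA_MENISCECTOMY"
    IONA_DIAGNOSTIC = "IONA_DIAGNOSTIC"
    IONA_REVISION = "IONA_REVISION"


#: Procedures that occupy an OR slot.  An IONA revision is OR-bound: the
#: failed office procedure is followed by a full OR repair.
OR_BOUND: frozenset = frozenset(
    {
        ProcedureKind.OR_MENISCECTOMY,
        ProcedureKind.OR_REPAIR,
        ProcedureKind.OR_DIAGNOSTIC,
        ProcedureKind.IONA_REVISION,
    }
)

#: Office-only procedures — the ones that divert a patient away from the OR.
OFFICE_ONLY: frozenset = frozenset(
    {ProcedureKind.IONA_MENISCECTOMY, ProcedureKind.IONA_DIAGNOSTIC}
)


@dataclass(frozen=True)
class ScenarioParams:
    """State selector plus the two behavioural parameters.

    selection_fraction : share of MRI-irreparable patients choosing IONA
        over OR arthroscopy (base case 0.5 — no literature value exists,
        so an indifferent 50/50 split is assumed).
    revision_rate : share of IONA patients requiring a subsequent OR
        repair (base case 0.203, the pooled rate at which an MRI read of
        irreparable proves repairable at arthroscopy).
    """

    state: str
    selection_fraction: float = 0.0
    revision_rate: float = 0.203

    def __post_init__(self) -> None:
        if self.state not in ("current", "proposed"):
            raise PathwayError(f"state must be 'current' or 'proposed', got {self.state!r}")
        for name in ("selection_fraction", "revision_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise PathwayError(f"{name} must be in [0, 1], got {value}")
        if self.state == "current" and self.selection_fraction > 0:
            raise PathwayError("current state has no IONA option; selection_fraction must be 0")

    @classmethod
    def current(cls) -> "ScenarioParams":
        return cls(state="current", selection_fraction=0.0)

    @classmethod
    def proposed(cls, selection_fraction: float = 0.5, revision_rate: float = 0.203) -> "ScenarioParams":
        return cls(
            state="proposed",
            selection_fraction=selection_fraction,
            revision_rate=revision_rate,
        )


@dataclass(frozen=True)
class CaseMix:
    """Patients per year in each terminal procedure (fractional allowed)."""

    counts: Dict[ProcedureKind, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {kind: float(self.counts.get(kind, 0.0)) for kind in ProcedureKind}
        for kind, value in counts.items():
            if value < 0:
                raise PathwayError(f"negative count for {kind.value}: {value}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, kind: ProcedureKind) -> float:
        return self.counts[kind]

    @property
    def total(self) -> float:
        """Total annual volume N (every patient resolves in one branch)."""
        return sum(self.counts.values())

    def __add__(self, other: "CaseMix") -> "CaseMix":
        return CaseMix({k: self.counts[k] + other.counts[k] for k in ProcedureKind})

    def scaled(self, factor: float) -> "CaseMix":
        if factor < 0:
            raise PathwayError("scale factor must be non-negative")
        return CaseMix({k: v * factor for k, v in self.counts.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"procedure": [k.value for k in ProcedureKind],
             "patients_per_year": [self.counts[k] for k in ProcedureKind]}
        )


def branch_distribution(
    probs: ArmProbabilities, params: ScenarioParams
) -> Dict[ProcedureKind, float]:
    """Per-patient probability of each terminal procedure.

    Arm splits are renormalised to sum exactly to one (table values at one
    decimal can miss by up to the stated tolerance), so the distribution
    is exactly a probability mass function and patient conservation is
    exact for any input.  When the revision rate departs from its base
    value, the non-revision IONA mass splits between meniscectomy and
    diagnostic IONA in proportion to the irreparable arm's resect:diagnostic
    ratio, which reproduces the base case exactly at the base revision rate.
    """
    s = params.selection_fraction if params.state == "proposed" else 0.0
    r = params.revision_rate
    top = probs.p_repairable + probs.p_irreparable
    p_rep = probs.p_repairable / top
    p_irr = probs.p_irreparable / top

    rep = probs.repairable.as_tuple()
    rep_sum = sum(rep)
    rep = tuple(x / rep_sum for x in rep)
    irr = probs.irreparable.as_tuple()
    irr_sum = sum(irr)
    irr = tuple(x / irr_sum for x in irr)

    office_mass = irr[1] + irr[2]
    resect_share = irr[1] / office_mass if office_mass > 0 else 0.0

    iona = p_irr * s
    stay = p_irr * (1.0 - s)
    dist = {
        ProcedureKind.OR_REPAIR: p_rep * rep[0] + stay * irr[0],
        ProcedureKind.OR_MENISCECTOMY: p_rep * rep[1] + stay * irr[1],
        ProcedureKind.OR_DIAGNOSTIC: p_rep * rep[2] + stay * irr[2],
        ProcedureKind.IONA_REVISION: iona * r,
        ProcedureKind.IONA_MENISCECTOMY: iona * (1.0 - r) * resect_share,
        ProcedureKind.IONA_DIAGNOSTIC: iona * (1.0 - r) * (1.0 - resect_share),
    }
    return dist


def expected_case_mix(
    N: float,
    probs: ArmProbabilities,
    params: ScenarioParams,
    *,
    multinomial: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> CaseMix:
    """Allocate an annual volume across the tree's terminal branches.

    Deterministic-fractional by default: branch count = N x branch
    probability.  With ``multinomial=True`` the integer volume is sampled
    across branches instead (stress-testing mode; requires ``rng``).
    """
    if N < 0:
        raise PathwayError(f"annual volume must be non-negative, got {N}")
    dist = branch_distribution(probs, params)
    if multinomial:
        if rng is None:
            raise PathwayError("multinomial allocation requires an rng")
        kinds = list(dist)
        draws = rng.multinomial(int(round(N)), [dist[k] for k in kinds])
        return CaseMix(dict(zip(kinds, draws.astype(float))))
    return CaseMix({k: N * p for k, p in dist.items()})


def or_bound_count(mix: CaseMix) -> float:
    """Annual patients occupying an OR slot (IONA revisions included)."""
    return sum(mix[k] for k in OR_BOUND)
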