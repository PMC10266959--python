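"""Waitlist-diversion (throughput) model.

Throughput is the annual number of patients diverted away from the OR by
the office pathway, used as a proxy for surgical-waitlist reduction:

    diverted = (OR-bound patients, current state) - (OR-bound, proposed)
    fraction = diverted / N

Because only MRI-irreparable patients are offered IONA, and a revised
IONA still occupies an OR slot, the subtraction collapses to the closed
form ``N * p_irreparable * s * (1 - r)``.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_away
from .pathway import CaseMix, or_bound_count


class ThroughputError(ValueError):
    """Mismatched case mixes."""


@dataclass(frozen=True)
class ThroughputResult:
    """Annual diverted patients and their share of total volume."""

    diverted: float
    fraction: float
    total: float

    @property
    def headline_count(self) -> float:
        """Diverted patients rounded to whole patients (ties away from zero)."""
        return round_half_away(self.diverted)

    @property
    def headline_fraction_pct(self) -> float:
        """Headline percentage: rounded count over total volume, one decimal."""
        if self.total == 0:
            return 0.0
        return round_half_away(self.headline_count / self.total * 100.0, 1)


def throughput_from_mixes(current: CaseMix, proposed: CaseMix) -> ThroughputResult:
    """Diverted patients by subtraction of OR-bound counts."""
    if abs(current.total - proposed.total) > 1e-6 * max(1.0, current.total):
        raise ThroughputError(
            f"case mixes cover different volumes: {current.total} vs {proposed.total}"
        )
    n = current.total
    diverted = or_bound_count(current) - or_bound_count(proposed)
    fraction = diverted / n if n > 0 else 0.0
    return ThroughputResult(diverted=diverted, fraction=fraction, total=n)


def diverted_closed_form(N: float, p_irreparable: float, s: float, r: float) -> float:
    """Closed form of the diverted count: N * p_irreparable * s * (1 - r)."""
    return N * p_irreparable * s * (1.0 - r)
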