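"""Ordinal traffic-light risk levels used throughout the screening engine."""
from __future__ import annotations

import enum
from collections.abc import Iterable

_COLOR = {"low": "green", "moderate": "yellow", "relevant": "orange", "not_scored": "none"}
_RANK = {"low": 0, "moderate": 1, "relevant": 2}


class RiskLevel(enum.Enum):
    """Three-level traffic-light risk plus a sentinel for unscored answers.

    The scored levels are strictly ordered ``LOW < MODERATE < RELEVANT`` and map
    one-to-one onto the colors green, yellow and orange.  ``NOT_SCORED`` marks
    answers that carry no risk information (missing, "prefer not to answer",
    "unknown" lab category, or items excluded from scoring); it has no position
    in the ordering and is skipped during aggregation.
    """

    LOW = "low"
    MODERATE = "moderate"
    RELEVANT = "relevant"
    NOT_SCORED = "not_scored"

    @property
    def color(self) -> str:
        return _COLOR[self.value]

    @property
    def scored(self) -> bool:
        return self is not RiskLevel.NOT_SCORED

    def _rank(self) -> int:
        if not self.scored:
            raise ValueError("NOT_SCORED has no position in the risk ordering")
        return _RANK[self.value]

    def __lt__(self, other: object):
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self._rank() < other._rank()

    def __le__(self, other: object):
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self._rank() <= other._rank()

    def __gt__(self, other: object):
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self._rank() > other._rank()

    def __ge__(self, other: object):
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self._rank() >= other._rank()


def max_scored(levels: Iterable[RiskLevel]) -> RiskLevel:
    """Aggregate risks as the maximum over scored levels.

    ``NOT_SCORED`` entries are ignored; an input with no scored level at all
    aggregates to ``NOT_SCORED``.
    """
    scored = [lv for lv in levels if lv.scored]
    if not scored:
        return RiskLevel.NOT_SCORED
    return max(scored)
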