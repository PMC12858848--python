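"""Stressor protocol schedules.

A recording session alternates a pre-stress rest block with stressor blocks,
each followed by a recovery block.  Six states are distinguished: rest plus
five stressor categories (cognitive, emotional, physical, psychosocial,
environmental).  Recovery blocks are labeled ``rest``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class StressState(str, Enum):
    """The six labeled states a time interval can carry."""

    REST = "rest"
    COGNITIVE = "cognitive"
    EMOTIONAL = "emotional"
    PHYSICAL = "physical"
    PSYCHOSOCIAL = "psychosocial"
    ENVIRONMENTAL = "environmental"


#: Stressor categories in the fixed order used by :func:`make_protocol_schedule`.
STRESSOR_ORDER = (
    StressState.COGNITIVE,
    StressState.ENVIRONMENTAL,
    StressState.EMOTIONAL,
    StressState.PSYCHOSOCIAL,
    StressState.PHYSICAL,
)


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    label: StressState

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise ValueError(f"segment start {self.start_s} must precede end {self.end_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StressorSchedule:
    """An ordered, non-overlapping list of labeled time intervals."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValueError("schedule segments overlap or are unsorted")

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    def label_at(self, t_s: float) -> StressState | None:
        """State label at time ``t_s`` (segments are half-open ``[start, end)``)."""
        for seg in self.segments:
            if seg.start_s <= t_s < seg.end_s:
                return seg.label
        return None

    def to_records(self) -> list[dict]:
        return [
            {"start_s": s.start_s, "end_s": s.end_s, "label": s.label.value}
            for s in self.segments
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "StressorSchedule":
        return cls(
            tuple(
                Segment(r["start_s"], r["end_s"], StressState(r["label"]))
                for r in records
            )
        )


def make_protocol_schedule(
    n_stressors: int, block_s: float = 600.0, recovery_s: float = 600.0
) -> StressorSchedule:
    """Build the study protocol: rest, then stressor/recovery pairs.

    The session opens with a pre-stress rest block of ``block_s`` seconds,
    then one ``block_s`` stressor block per category (in :data:`STRESSOR_ORDER`),
    each followed by a ``recovery_s`` rest block.

    Parameters
    ----------
    n_stressors:
        Number of stressor categories to include, at most five.
    block_s:
        Duration of the pre-stress rest block and of each stressor block.
    recovery_s:
        Duration of each post-stressor recovery block (labeled rest).
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    if n_stressors < 0:
        raise ValueError("n_stressors must be non-negative")
    if n_stressors > len(STRESSOR_ORDER):
        raise ValueError(
            f"only {len(STRESSOR_ORDER)} stressor categories exist, got {n_stressors}"
        )
    segments = [Segment(0.0, float(block_s), StressState.REST)]
    t = float(block_s)
    for state in STRESSOR_ORDER[:n_stressors]:
        segments.append(Segment(t, t + block_s, state))
        t += block_s
        segments.append(Segment(t, t + recovery_s, StressState.REST))
        t += recovery_s
    return StressorSchedule(tuple(segments))
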