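"""Paired noise-burst stimulus conditions and the gap/NB1 ratio.

A stimulus is a leading noise burst (NB1), a silent gap, and a trailing
noise burst (NB2).  The grouping variable of the whole analysis is the
ratio of gap duration to NB1 duration; responses fall into a *suppressed*
category when the ratio is at or below the boundary (0.5 by default) and a
*balanced/enhanced* category above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "StimulusCondition",
    "default_grid",
    "gap_nb1_ratio",
    "display_ratio",
    "NB1_DURATIONS_MS",
    "GAP_DURATIONS_MS",
    "NB2_DURATION_MS",
]

#: The 4x4 stimulus grid used throughout: leading-burst durations crossed
#: with gap durations, trailing burst fixed at 50 ms.
NB1_DURATIONS_MS = (5.0, 10.0, 30.0, 100.0)
GAP_DURATIONS_MS = (2.0, 3.0, 5.0, 10.0)
NB2_DURATION_MS = 50.0


@dataclass(frozen=True)
class StimulusCondition:
    """One NB1/gap/NB2 duration triple (all in ms)."""

    nb1_ms: float
    gap_ms: float
    nb2_ms: float = NB2_DURATION_MS

    def __post_init__(self) -> None:
        for name in ("nb1_ms", "gap_ms", "nb2_ms"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")

    @property
    def onset_to_onset_ms(self) -> float:
        """Interval between NB1 onset and NB2 onset (NB1 duration + gap)."""
        return self.nb1_ms + self.gap_ms

    @property
    def ratio(self) -> float:
        """Gap duration divided by NB1 duration."""
        return gap_nb1_ratio(self)

    def label(self) -> str:
        return f"nb1_{self.nb1_ms:g}ms_gap_{self.gap_ms:g}ms"


def default_grid() -> list[StimulusCondition]:
    """All 16 conditions of the standard grid, NB1-major order."""
    return [
        StimulusCondition(nb1_ms=nb1, gap_ms=gap)
        for nb1 in NB1_DURATIONS_MS
        for gap in GAP_DURATIONS_MS
    ]


def gap_nb1_ratio(condition: StimulusCondition) -> float:
    """Ratio of gap duration to leading-burst duration (dimensionless)."""
    if condition.nb1_ms <= 0:
        raise ValueError("nb1_ms must be positive")
    return condition.gap_ms / condition.nb1_ms


def display_ratio(ratio: float, decimals: int = 2) -> float:
    """Round a ratio the way the condition tables print it (two decimals)."""
    return round(ratio, decimals)


def min_onset_interval_ms(grid: Sequence[StimulusCondition]) -> float:
    """Smallest NB1-onset to NB2-onset interval over a stimulus grid."""
    if not grid:
        raise ValueError("empty stimulus grid")
    return min(c.onset_to_onset_ms for c in grid)
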