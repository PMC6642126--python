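"""In-memory containers for averaged ABR recordings and onset epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .stimuli import StimulusCondition

__all__ = ["ABRRecording", "OnsetEpoch", "EPOCH_MS"]

#: Post-onset analysis window (ms): the ABR is essentially over within 8 ms.
EPOCH_MS = 8.0


@dataclass
class ABRRecording:
    """Averaged voltage trace for one subject x stimulus condition.

    ``trace_uv`` is the sweep-averaged scalp potential in microvolts,
    sampled at ``sampling_rate_hz``; ``nb1_onset_ms``/``nb2_onset_ms``
    locate the two burst onsets within the trace.
    """

    trace_uv: np.ndarray
    sampling_rate_hz: float
    nb1_onset_ms: float
    nb2_onset_ms: float
    condition: StimulusCondition
    subject_id: str

    def __post_init__(self) -> None:
        self.trace_uv = np.asarray(self.trace_uv, dtype=float)
        if self.trace_uv.ndim != 1:
            raise ValueError("trace_uv must be one-dimensional")
        dt_ms = 1000.0 / self.sampling_rate_hz
        expected = self.condition.onset_to_onset_ms
        actual = self.nb2_onset_ms - self.nb1_onset_ms
        if abs(actual - expected) > dt_ms:
            raise ValueError(
                f"onset interval {actual:g} ms does not match condition "
                f"({expected:g} ms) within one sample period"
            )
        if self.duration_ms < self.nb2_onset_ms + EPOCH_MS:
            raise ValueError(
                "trace must extend at least 8 ms beyond the NB2 onset"
            )

    @property
    def duration_ms(self) -> float:
        return len(self.trace_uv) * 1000.0 / self.sampling_rate_hz

    def with_trace(self, trace_uv: np.ndarray) -> "ABRRecording":
        """Copy of this recording with a replaced voltage trace."""
        return replace(self, trace_uv=np.asarray(trace_uv, dtype=float))


@dataclass
class OnsetEpoch:
    """Exactly 8 ms of response following one burst onset."""

    samples_uv: np.ndarray
    sampling_rate_hz: float
    alignment: Literal["NB1", "NB2"]
    condition: StimulusCondition
    subject_id: str

    def __post_init__(self) -> None:
        self.samples_uv = np.asarray(self.samples_uv, dtype=float)
        expected = int(round(EPOCH_MS / 1000.0 * self.sampling_rate_hz))
        if len(self.samples_uv) != expected:
            raise ValueError(
                f"epoch must hold exactly {expected} samples "
                f"({EPOCH_MS:g} ms at {self.sampling_rate_hz:g} Hz), "
                f"got {len(self.samples_uv)}"
            )

    @property
    def time_axis_ms(self) -> np.ndarray:
        """Post-onset latency of each sample, in ms."""
        return np.arange(len(self.samples_uv)) * 1000.0 / self.sampling_rate_hz
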