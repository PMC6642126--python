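"""Band-pass filtering, onset-epoch extraction and time-domain parameters.

Recordings are zero-phase band-pass filtered (300-3000 Hz, 4th-order
Butterworth applied forward and backward), the two 8 ms post-onset
windows are cut out, and the classical time-domain summary parameters are
computed: the RMS ratio of the two onset responses over 1-7 ms and the
peak-to-trough amplitude ratio of wave III.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ABRRecording, OnsetEpoch, EPOCH_MS

__all__ = [
    "zero_phase_bandpass",
    "filter_recording",
    "extract_onset_epochs",
    "time_domain_params",
    "TimeDomainParams",
]


@dataclass(frozen=True)
class TimeDomainParams:
    """RMS and wave-III peak ratios of the NB2 vs NB1 onset response.

    Values above 1 indicate a stronger response to the trailing burst.
    """

    rms_ratio: float
    peak3_ratio: float


def zero_phase_bandpass(
    trace: np.ndarray,
    sampling_rate_hz: float,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
    order: int = 4,
) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero net phase shift)."""
    if not 0 < low_hz < high_hz < sampling_rate_hz / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for sampling rate "
            f"{sampling_rate_hz} Hz"
        )
    trace = np.asarray(trace, dtype=float)
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate_hz, output="sos"
    )
    # sosfiltfilt needs a minimum run-in length for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(trace) <= padlen:
        raise ValueError(
            f"trace too short to filter ({len(trace)} samples, need > {padlen})"
        )
    return signal.sosfiltfilt(sos, trace)


def filter_recording(recording: ABRRecording, **kwargs) -> ABRRecording:
    """Return a copy of the recording with the band-pass applied."""
    return recording.with_trace(
        zero_phase_bandpass(recording.trace_uv, recording.sampling_rate_hz, **kwargs)
    )


def extract_onset_epochs(recording: ABRRecording) -> tuple[OnsetEpoch, OnsetEpoch]:
    """Cut the two 8 ms post-onset windows [onset, onset + 8 ms)."""
    fs = recording.sampling_rate_hz
    n_epoch = int(round(EPOCH_MS / 1000.0 * fs))
    epochs = []
    for onset_ms, alignment in (
        (recording.nb1_onset_ms, "NB1"),
        (recording.nb2_onset_ms, "NB2"),
    ):
        start = int(round(onset_ms / 1000.0 * fs))
        stop = start + n_epoch
        if start < 0 or stop > len(recording.trace_uv):
            raise ValueError(
                f"{alignment} onset at {onset_ms:g} ms places the 8 ms epoch "
                "outside the recorded trace"
            )
        epochs.append(
            OnsetEpoch(
                samples_uv=recording.trace_uv[start:stop].copy(),
                sampling_rate_hz=fs,
                alignment=alignment,
                condition=recording.condition,
                subject_id=recording.subject_id,
            )
        )
    return epochs[0], epochs[1]


def _rms_1_7ms(epoch: OnsetEpoch) -> float:
    t = epoch.time_axis_ms
    window = (t >= 1.0) & (t <= 7.0)  # closed window; boundary samples included
    return float(np.sqrt(np.mean(epoch.samples_uv[window] ** 2)))


def _peak3_amplitude(
    epoch: OnsetEpoch, window_ms: tuple[float, float]
) -> float:
    """Peak-to-trough amplitude of wave III.

    Wave III is taken as the largest positive peak within ``window_ms``;
    its amplitude is measured to the following minimum (the trough before
    the next wave).
    """
    t = epoch.time_axis_ms
    x = epoch.samples_uv
    in_window = np.where((t >= window_ms[0]) & (t <= window_ms[1]))[0]
    if in_window.size == 0:
        raise ValueError("wave III search window contains no samples")
    peak_idx = in_window[np.argmax(x[in_window])]
    after = x[peak_idx:]
    # trough = first local minimum after the peak; fall back to the global
    # minimum of the remaining trace for monotone tails
    minima = signal.argrelmin(after)[0]
    trough_val = after[minima[0]] if minima.size else after.min()
    return float(x[peak_idx] - trough_val)


def time_domain_params(
    epoch1: OnsetEpoch,
    epoch2: OnsetEpoch,
    peak3_window_ms: tuple[float, float] = (2.5, 4.5),
) -> TimeDomainParams:
    """RMS ratio (1-7 ms window) and wave-III peak-to-trough ratio.

    Both ratios are NB2 response over NB1 response, so values above 1 mean
    the trailing burst evoked the stronger brainstem activation.
    """
    if len(epoch1.samples_uv) != len(epoch2.samples_uv):
        raise ValueError("epochs must share the same sample grid")
    if epoch1.sampling_rate_hz != epoch2.sampling_rate_hz:
        raise ValueError("epochs must share the same sampling rate")
    rms1 = _rms_1_7ms(epoch1)
    rms2 = _rms_1_7ms(epoch2)
    if rms1 == 0:
        raise ZeroDivisionError("reference (NB1) epoch is flat; RMS ratio undefined")
    p1 = _peak3_amplitude(epoch1, peak3_window_ms)
    p2 = _peak3_amplitude(epoch2, peak3_window_ms)
    if p1 == 0:
        raise ZeroDivisionError("reference (NB1) wave III amplitude is zero")
    return TimeDomainParams(rms_ratio=rms2 / rms1, peak3_ratio=p2 / p1)
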