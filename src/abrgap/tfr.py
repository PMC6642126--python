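"""Time-frequency analysis of onset epochs.

The analysis uses the discrete Wigner-Ville distribution (WVD) of the
analytic signal for its joint time-frequency resolution, with optional
Choi-Williams filtering to suppress the oscillatory cross-terms the WVD
produces between signal components.  Differential representations
(leading minus trailing response) are reduced to mean band powers on a
0.5 ms time grid over three contiguous 250 Hz bands:

* LFB 400-650 Hz — slow modulatory components;
* MFB 650-900 Hz — the dominant ABR wave content (1.1-1.5 ms periods);
* HFB 900-1150 Hz — sharpening / high-synchrony components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert

from .recording import OnsetEpoch

__all__ = [
    "TimeFrequencyRepresentation",
    "BandDefinition",
    "BinnedBandPower",
    "wigner_ville",
    "choi_williams",
    "differential_tfr",
    "band_bin_powers",
    "feature_window",
    "DEFAULT_BANDS",
]


@dataclass
class TimeFrequencyRepresentation:
    """Power as a joint function of post-onset latency and frequency."""

    power: np.ndarray  # (time, frequency)
    time_axis_ms: np.ndarray
    freq_axis_hz: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.time_axis_ms = np.asarray(self.time_axis_ms, dtype=float)
        self.freq_axis_hz = np.asarray(self.freq_axis_hz, dtype=float)
        if self.power.shape != (len(self.time_axis_ms), len(self.freq_axis_hz)):
            raise ValueError("power matrix shape does not match axes")
        for name, ax in (("time", self.time_axis_ms), ("frequency", self.freq_axis_hz)):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")

    def same_axes(self, other: "TimeFrequencyRepresentation") -> bool:
        return (
            self.power.shape == other.power.shape
            and np.allclose(self.time_axis_ms, other.time_axis_ms)
            and np.allclose(self.freq_axis_hz, other.freq_axis_hz)
        )


@dataclass(frozen=True)
class BandDefinition:
    """Three contiguous frequency bands of equal width (Hz)."""

    lfb: tuple[float, float] = (400.0, 650.0)
    mfb: tuple[float, float] = (650.0, 900.0)
    hfb: tuple[float, float] = (900.0, 1150.0)

    def __post_init__(self) -> None:
        if not (self.lfb[1] == self.mfb[0] and self.mfb[1] == self.hfb[0]):
            raise ValueError("bands must be contiguous (LFB|MFB|HFB)")
        widths = {round(hi - lo, 9) for lo, hi in (self.lfb, self.mfb, self.hfb)}
        if len(widths) != 1 or min(widths) <= 0:
            raise ValueError("bands must have equal positive widths")

    def items(self):
        return (("lfb", self.lfb), ("mfb", self.mfb), ("hfb", self.hfb))

    @property
    def span(self) -> tuple[float, float]:
        return (self.lfb[0], self.hfb[1])


DEFAULT_BANDS = BandDefinition()


@dataclass
class BinnedBandPower:
    """Mean differential power per (0.5 ms bin x band)."""

    bin_edges_ms: np.ndarray  # length n_bins + 1
    values: dict[str, np.ndarray]  # band -> per-bin means
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_ms) - 1

    @property
    def lf_change(self) -> np.ndarray:
        return self.values["lfb"]

    @property
    def hf_change(self) -> np.ndarray:
        return self.values["hfb"]

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def _instantaneous_autocorr(z: np.ndarray, n_points: int) -> np.ndarray:
    """Lag kernel K[n, m] = z[n+m] z*[n-m], lag-wrapped for the final FFT."""
    L = len(z)
    max_lag = min(n_points // 2, L)
    n = np.arange(L)[:, None]
    m = np.arange(max_lag)[None, :]
    idx_p = n + m
    idx_m = n - m
    valid = (idx_p < L) & (idx_m >= 0)
    vals = np.where(
        valid,
        z[np.clip(idx_p, 0, L - 1)] * np.conj(z[np.clip(idx_m, 0, L - 1)]),
        0.0,
    )
    K = np.zeros((L, n_points), dtype=complex)
    K[:, :max_lag] = vals
    K[:, n_points - max_lag + 1 :] = np.conj(vals[:, 1:max_lag][:, ::-1])
    return K


def _freq_axis(fs: float, n_points: int) -> np.ndarray:
    # lag variable is sampled at 2*dt, so bin k maps to k*fs/(2*n_points)
    return np.arange(n_points) * fs / (2.0 * n_points)


def _finalize(K: np.ndarray, epoch: OnsetEpoch, n_points: int, meta: dict):
    fs = epoch.sampling_rate_hz
    W = np.fft.fft(K, axis=1).real * (2.0 / fs)
    return TimeFrequencyRepresentation(
        power=W,
        time_axis_ms=epoch.time_axis_ms,
        freq_axis_hz=_freq_axis(fs, n_points),
        metadata={
            "alignment": epoch.alignment,
            "condition": epoch.condition,
            "subject_id": epoch.subject_id,
            **meta,
        },
    )


def wigner_ville(epoch: OnsetEpoch, n_points: int = 2048) -> TimeFrequencyRepresentation:
    """Discrete Wigner-Ville distribution of the epoch's analytic signal.

    The signal is made analytic with a frequency-domain Hilbert transform
    (suppressing negative-frequency interference); the lag kernel is
    transformed with an ``n_points``-long FFT, so the frequency axis runs
    from 0 to the Nyquist frequency in steps of ``fs / (2 n_points)``.
    The time marginal integrates to the analytic signal's instantaneous
    power, and total power integrates to its energy.
    """
    x = np.asarray(epoch.samples_uv, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    if n_points < x.size:
        raise ValueError(
            f"n_points ({n_points}) must be at least the epoch length ({x.size})"
        )
    z = hilbert(x)
    K = _instantaneous_autocorr(z, n_points)
    return _finalize(K, epoch, n_points, {"estimator": "wvd", "n_points": n_points})


def choi_williams(
    epoch: OnsetEpoch, sigma: float = 1.0, n_points: int = 2048
) -> TimeFrequencyRepresentation:
    """Wigner-Ville distribution with Choi-Williams cross-term suppression.

    The lag kernel is taken to the ambiguity (doppler-lag) domain, where
    the exponential kernel ``exp(-(theta * tau)^2 / sigma)`` attenuates
    components away from the axes — the signature of cross-terms — while
    leaving auto-terms near the axes (and hence peak locations) intact.
    Larger ``sigma`` means less smoothing; as ``sigma -> inf`` the raw
    WVD is recovered.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(epoch.samples_uv, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    if n_points < x.size:
        raise ValueError(
            f"n_points ({n_points}) must be at least the epoch length ({x.size})"
        )
    fs = epoch.sampling_rate_hz
    z = hilbert(x)
    K = _instantaneous_autocorr(z, n_points)
    # ambiguity domain: FFT over time for each lag column
    A = np.fft.fft(K, axis=0)
    doppler_hz = np.fft.fftfreq(K.shape[0], d=1.0 / fs)  # cycles/s
    lag_idx = np.fft.fftfreq(n_points, d=1.0 / n_points)  # signed lag index
    tau_s = 2.0 * lag_idx / fs
    theta = 2.0 * np.pi * doppler_hz
    kernel = np.exp(-np.square(np.outer(theta, tau_s)) / sigma)
    K_filtered = np.fft.ifft(A * kernel, axis=0)
    return _finalize(
        K_filtered, epoch, n_points,
        {"estimator": "choi-williams", "sigma": sigma, "n_points": n_points},
    )


def differential_tfr(
    tfr_abr1: TimeFrequencyRepresentation,
    tfr_abr2: TimeFrequencyRepresentation,
) -> TimeFrequencyRepresentation:
    """Elementwise TFR(ABR1) - TFR(ABR2).

    Positive values mean more power in the response to the leading burst.
    """
    if not tfr_abr1.same_axes(tfr_abr2):
        raise ValueError("TFR axes do not match")
    meta = {
        k: v
        for k, v in tfr_abr1.metadata.items()
        if tfr_abr2.metadata.get(k) == v and k != "alignment"
    }
    meta["kind"] = "differential"
    return TimeFrequencyRepresentation(
        power=tfr_abr1.power - tfr_abr2.power,
        time_axis_ms=tfr_abr1.time_axis_ms.copy(),
        freq_axis_hz=tfr_abr1.freq_axis_hz.copy(),
        metadata=meta,
    )


def band_bin_powers(
    dtfr: TimeFrequencyRepresentation,
    bands: BandDefinition = DEFAULT_BANDS,
    bin_ms: float = 0.5,
    epoch_span_ms: tuple[float, float] = (0.0, 8.0),
) -> BinnedBandPower:
    """Mean differential power in each (time bin x band) rectangle.

    Each value is the arithmetic mean of the cells whose time and
    frequency coordinates fall inside the half-open rectangle
    ``[t, t + bin_ms) x [low, high)``.
    """
    t = dtfr.time_axis_ms
    f = dtfr.freq_axis_hz
    lo, hi = epoch_span_ms
    if t[0] > lo or t[-1] < hi - bin_ms:
        raise ValueError("dTFR time axis does not cover the epoch span")
    df = f[1] - f[0] if len(f) > 1 else 0.0
    if f[0] > bands.span[0] or f[-1] < bands.span[1] - df:
        raise ValueError("dTFR frequency axis does not cover the bands")
    n_bins = int(round((hi - lo) / bin_ms))
    edges = lo + bin_ms * np.arange(n_bins + 1)
    values: dict[str, np.ndarray] = {}
    for name, (f_lo, f_hi) in bands.items():
        in_band = (f >= f_lo) & (f < f_hi)
        if not in_band.any():
            raise ValueError(f"no frequency cells in band {name} [{f_lo}, {f_hi}) Hz")
        band_power = dtfr.power[:, in_band]
        means = np.empty(n_bins)
        for b in range(n_bins):
            in_bin = (t >= edges[b]) & (t < edges[b + 1])
            if not in_bin.any():
                raise ValueError(f"no time samples in bin [{edges[b]}, {edges[b+1]}) ms")
            means[b] = band_power[in_bin].mean()
        values[name] = means
    return BinnedBandPower(
        bin_edges_ms=edges, values=values, metadata=dict(dtfr.metadata)
    )


def feature_window(
    binned: BinnedBandPower,
    window_ms: tuple[float, float] = (3.0, 5.0),
    bands: Sequence[str] = ("lfb", "mfb", "hfb"),
) -> np.ndarray:
    """Per-band mean over the bins inside ``window_ms`` (half-open).

    The (LFB, MFB, HFB) triple over 3-5 ms is the supervised-classifier
    feature vector; the (LFB, HFB) pair feeds clustering and scatter
    plots.
    """
    edges = binned.bin_edges_ms
    bin_ms = edges[1] - edges[0]
    for w in window_ms:
        if abs((w - edges[0]) / bin_ms - round((w - edges[0]) / bin_ms)) > 1e-9:
            raise ValueError(f"window edge {w} ms is not aligned to the bin grid")
    lo, hi = window_ms
    if lo < edges[0] or hi > edges[-1] or hi <= lo:
        raise ValueError("feature window outside the binned range")
    centers = binned.bin_centers_ms
    sel = (centers >= lo) & (centers < hi)
    return np.array([binned.values[b][sel].mean() for b in bands])
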