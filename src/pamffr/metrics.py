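"""Scalar measurements on averaged responses.

Amplitude measures: peak-to-peak (the PAM convention, default search
window 8–18 ms), root-mean-square (the FFR convention, default analysis
window 10–110 ms — the 100 ms stimulus plus ~10 ms neural conduction
delay), and narrow-band spectral amplitude at the stimulus fundamental
and harmonics.  Timing measures: latency of the maximal positive
deflection in a search window, and maximal normalized cross-correlation
over a ±20 ms lag range (used to compare model-derived with measured
FFRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "PAM_WINDOW",
    "FFR_RMS_WINDOW",
    "FFR_ONSET_WINDOW",
    "XcorrResult",
    "peak_to_peak",
    "rms_amplitude",
    "onset_latency",
    "spectrum_amplitude",
    "xcorr_max",
]

#: Default search window for the PAM artifact (ms).
PAM_WINDOW = (8.0, 18.0)
#: Default FFR rms analysis window (ms): stimulus duration + conduction delay.
FFR_RMS_WINDOW = (10.0, 110.0)
#: Default FFR onset-latency search window (ms).
FFR_ONSET_WINDOW = (6.0, 12.0)


@dataclass(frozen=True)
class XcorrResult:
    """Maximal normalized cross-correlation and the lag where it occurs."""

    r_max: float      # Pearson correlation at the best lag, in [-1, 1]
    lag_ms: float     # lag of the maximum, ms; positive = second input lags

    def __post_init__(self) -> None:
        if abs(self.r_max) > 1 + 1e-9:
            raise ValueError("correlation magnitude cannot exceed 1")


def _windowed(w: Waveform, window) -> Waveform:
    if window is None:
        return w
    return w.segment(window[0], window[1])


def peak_to_peak(w: Waveform, window=PAM_WINDOW) -> float:
    """max - min of the samples inside ``window`` (ms); always >= 0."""
    seg = _windowed(w, window)
    return float(seg.samples.max() - seg.samples.min())


def rms_amplitude(w: Waveform, window=FFR_RMS_WINDOW) -> float:
    """Root-mean-square voltage over ``window`` (ms)."""
    seg = _windowed(w, window)
    return float(np.sqrt(np.mean(seg.samples**2)))


def onset_latency(w: Waveform, search=FFR_ONSET_WINDOW) -> float:
    """Latency (ms) of the maximal positive deflection inside ``search``.

    Follows the ABR wave-peak convention: the reported time is the sample
    of maximum (signed) amplitude.  A flat segment has no defined peak and
    raises ``ValueError``.
    """
    seg = _windowed(w, search)
    if np.ptp(seg.samples) == 0:
        raise ValueError("flat waveform in search window: peak latency undefined")
    i = int(np.argmax(seg.samples))
    return float(seg.times[i])


def spectrum_amplitude(w: Waveform, freq: float, window=FFR_RMS_WINDOW) -> float:
    """Amplitude (μV) of the discrete spectrum at the bin nearest ``freq``.

    The analysis window is zero-padded to 1 Hz bin resolution with a
    rectangular taper (appropriate for a periodic steady-state signal) and
    normalized so a pure sinusoid of amplitude A returns ≈ A.
    """
    seg = _windowed(w, window)
    if freq >= seg.fs / 2:
        raise ValueError(f"frequency {freq:g} Hz is at or above Nyquist ({seg.fs / 2:g} Hz)")
    n = seg.samples.size
    min_cycles = 2.0
    if n / seg.fs < min_cycles / freq:
        raise ValueError("analysis window shorter than two cycles of the target frequency")
    nfft = max(n, int(round(seg.fs)))  # pad to ~1 Hz bins
    spec = np.fft.rfft(seg.samples, nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / seg.fs)
    k = int(np.argmin(np.abs(freqs - freq)))
    return float(2.0 * np.abs(spec[k]) / n)


def xcorr_max(a: Waveform, b: Waveform, max_lag_ms: float = 20.0,
              min_overlap: int = 16) -> XcorrResult:
    """Maximal Pearson correlation between ``a`` and ``b`` over lags |τ| ≤ max_lag.

    At lag τ the correlation is computed between a(t) and b(t + τ) on the
    overlapping portion of the two records, i.e. if ``b`` is a delayed
    copy of ``a`` the maximum is found at a positive lag equal to the
    delay.  The signed maximum is returned.  Zero-variance inputs raise.
    """
    if a.fs != b.fs:
        raise ValueError("waveforms must share a sampling rate")
    x, y = a.samples, b.samples
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    max_lag = int(round(max_lag_ms * 1e-3 * a.fs))
    best_r, best_lag = -2.0, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: x.size - lag or None], y[lag:]
        else:
            xs, ys = x[-lag:], y[: y.size + lag]
        m = min(xs.size, ys.size)
        if m < min_overlap:
            continue
        xs, ys = xs[:m], ys[:m]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
        if r > best_r:
            best_r, best_lag = r, lag
    if best_r < -1.5:
        raise ValueError("no lag with sufficient overlap")
    return XcorrResult(r_max=min(best_r, 1.0), lag_ms=best_lag * 1000.0 / a.fs)
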