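"""Filtering, artifact rejection, ensemble averaging, and PAM isolation.

The acquisition chain being emulated band-passes the EEG at 50–3 000 Hz
with a 60 Hz mains notch, rejects any sweep exceeding ±50 μV, and
ensemble-averages the survivors.  The postauricular-muscle (PAM) artifact
is then isolated by sample-wise subtraction of the neck-referenced (C7)
average from the mastoid-referenced average: the neural response is common
to both references while the muscle potential is picked up only at the
mastoid.

Filters are realized zero-phase (forward–backward second-order Butterworth
band-pass plus a Q=30 IIR notch) so that latency measurements downstream
are unbiased.  Rejection is applied to the raw, unfiltered sweep, matching
hardware that rejects online before averaging; the (linear) filters are
applied to the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import scipy.signal

from .waveform import Waveform

__all__ = [
    "EpochSpec",
    "SweepSet",
    "AveragedResponse",
    "bandpass_notch",
    "reject_and_average",
    "isolate_pam",
]

#: Recording passband edges (Hz) and mains notch.
BAND_LOW = 50.0
BAND_HIGH = 3000.0
NOTCH_FREQ = 60.0
NOTCH_Q = 30.0

#: Epoch windows, ms from stimulus onset.
ABR_WINDOW = (0.0, 24.7)
FFR_WINDOW = (0.0, 127.0)


@dataclass(frozen=True)
class EpochSpec:
    """Epoching and rejection parameters for one recording condition."""

    window: tuple = FFR_WINDOW         # (start, stop) ms
    fs: float = 20000.0
    reject_threshold: float = 50.0     # μV, any-sample absolute criterion
    target_sweeps: int = 2000

    def __post_init__(self) -> None:
        if self.window[0] < 0:
            raise ValueError("epoch window must start at or after stimulus onset")
        if not self.reject_threshold > 0:
            raise ValueError("rejection threshold must be positive")

    @property
    def n_samples(self) -> int:
        return int(round((self.window[1] - self.window[0]) * 1e-3 * self.fs))


@dataclass
class SweepSet:
    """Epoch-by-sample matrix for one subject/condition/channel, pre-averaging."""

    data: np.ndarray                   # (n_epochs, n_samples), μV
    fs: float
    channel: str                       # "mastoid" (Fpz-M2) or "c7" (Fpz-C7)
    subject_id: str = ""
    stimulus: str = ""
    position: int = 0                  # gaze position label 1-5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SweepSet data must be 2-D (epochs x samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class AveragedResponse:
    """Ensemble average of the surviving sweeps for one condition."""

    waveform: Waveform
    n_sweeps_used: int
    n_sweeps_input: int
    channel: str = ""
    subject_id: str = ""
    stimulus: str = ""
    position: int = 0


@lru_cache(maxsize=8)
def _band_sos(fs: float, low: float, high: float):
    return scipy.signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=8)
def _notch_ba(fs: float, freq: float, q: float):
    return scipy.signal.iirnotch(freq, q, fs=fs)


def bandpass_notch(w: Waveform, low: float = BAND_LOW, high: float = BAND_HIGH,
                   notch: Optional[float] = NOTCH_FREQ, q: float = NOTCH_Q) -> Waveform:
    """Zero-phase 50–3 000 Hz band-pass plus 60 Hz notch.

    DC is removed by the band-pass.  Raises if the sampling rate cannot
    represent the upper band edge.
    """
    if not w.fs > 2 * high:
        raise ValueError(
            f"fs={w.fs:g} Hz too low for band edge {high:g} Hz (need fs > {2 * high:g})"
        )
    x = w.samples
    sos = _band_sos(w.fs, low, high)
    y = scipy.signal.sosfiltfilt(sos, x, padlen=min(x.size - 1, 600))
    if notch is not None:
        # the high-Q notch rings for ~Q/(pi*f0) seconds; pad generously so
        # short epochs still see deep mains rejection
        b, a = _notch_ba(w.fs, notch, q)
        y = scipy.signal.filtfilt(b, a, y, padlen=min(x.size - 1, 6000))
    return Waveform(y, w.fs, w.t0)


def noise_bandwidth_gain(fs: float, low: float = BAND_LOW, high: float = BAND_HIGH) -> float:
    """RMS gain of the zero-phase band-pass for white unit-variance noise.

    Forward-backward filtering applies |H(f)|^2, so the output variance of
    white noise is the mean of |H|^4 over frequency.  Used by the synthetic
    generator to express noise levels as the standard deviation of the
    band-limited samples.
    """
    sos = _band_sos(fs, low, high)
    freqs, h = scipy.signal.sosfreqz(sos, worN=4096, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def reject_and_average(sweeps: SweepSet, spec: EpochSpec) -> AveragedResponse:
    """Exclude sweeps with any sample beyond ±threshold; average the rest.

    Mirrors online artifact rejection: a sweep is discarded outright if a
    single sample exceeds the amplitude criterion (±50 μV by default).
    """
    if sweeps.n_epochs < 1:
        raise ValueError("need at least one sweep")
    thr = spec.reject_threshold
    keep = ~np.any(np.abs(sweeps.data) > thr, axis=1)
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError(
            f"all {sweeps.n_epochs} sweeps exceeded the ±{thr:g} μV rejection threshold"
        )
    avg = sweeps.data[keep].mean(axis=0)
    return AveragedResponse(
        waveform=Waveform(avg, sweeps.fs, spec.window[0]),
        n_sweeps_used=n_used,
        n_sweeps_input=sweeps.n_epochs,
        channel=sweeps.channel,
        subject_id=sweeps.subject_id,
        stimulus=sweeps.stimulus,
        position=sweeps.position,
    )


def isolate_pam(mastoid: AveragedResponse, neck: AveragedResponse) -> Waveform:
    """PAM isolation by channel subtraction (mastoid minus neck).

    Components common to both references (the neural response) cancel;
    what remains is dominated by the muscle potential picked up only by
    the mastoid electrode.
    """
    wm, wc = mastoid.waveform, neck.waveform
    if not wm.same_grid(wc):
        raise ValueError(
            "mastoid and neck averages are on different sampling grids "
            f"(fs {wm.fs} vs {wc.fs}, n {len(wm)} vs {len(wc)}, t0 {wm.t0} vs {wc.t0})"
        )
    if mastoid.subject_id != neck.subject_id or mastoid.position != neck.position:
        raise ValueError("channel subtraction requires the same subject and condition")
    return Waveform(wm.samples - wc.samples, wm.fs, wm.t0)
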