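"""Click and periodic pulse-train stimuli.

FFR-eliciting "pitch" stimuli are periodic click trains: a train of unit
impulses with period T = 1/F0 convolved with a single rectangular click.
The same pulse train drives both the synthetic cohort generator and the
convolution model of the sustained response, so the two stages share one
stimulus definition.

Pulse placement convention: the first pulse sits at t = 0 (stimulus
onset), so that derived responses align with recording epochs that start
at onset.  A train of duration ``d`` ms at fundamental ``f0`` Hz contains
exactly ``ceil(d * f0 / 1000)`` impulses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = ["StimSpec", "make_click", "make_pulse_train", "make_click_train"]

#: Upper edge of the recording passband (Hz); the sampling rate must cover it.
_PASSBAND_HIGH = 3000.0


@dataclass(frozen=True)
class StimSpec:
    """Parameters of a click / click-train stimulus.

    Parameters
    ----------
    f0:
        Fundamental frequency of the pulse train in Hz (100 or 200 in the
        standard protocol; any positive value is accepted).
    duration_ms:
        Train duration ``d`` in ms (default 100).
    click_width_us:
        Rectangular click width in microseconds (default 100).
    polarity:
        ``"rarefaction"`` (negative-going, the default) or
        ``"condensation"`` (sign-flipped).
    fs:
        Sampling rate in Hz (default 20 000).
    level_dbspl:
        Presentation level, metadata only (default 80 dB SPL).
    rep_rate:
        Presentations per second, metadata only (default 9.09).
    """

    f0: float = 100.0
    duration_ms: float = 100.0
    click_width_us: float = 100.0
    polarity: str = "rarefaction"
    fs: float = 20000.0
    level_dbspl: float = 80.0
    rep_rate: float = 9.09

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if not self.fs >= 2 * _PASSBAND_HIGH:
            raise ValueError(
                f"fs={self.fs} Hz does not cover the {_PASSBAND_HIGH:g} Hz "
                "recording passband (need fs >= 2*3000 Hz)"
            )
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")
        if self.polarity not in ("rarefaction", "condensation"):
            raise ValueError("polarity must be 'rarefaction' or 'condensation'")
        # one period must be representable on the sample grid
        if 1000.0 / self.f0 < 1000.0 / self.fs:
            raise ValueError("period 1/f0 must span at least one sample")

    @property
    def period_ms(self) -> float:
        """Inter-pulse period T = 1/f0, in ms."""
        return 1000.0 / self.f0

    @property
    def n_pulses(self) -> int:
        """Number of impulses in the train: ceil(d * f0)."""
        # guard against float fuzz at exact multiples (100 ms * 100 Hz = 10)
        x = self.duration_ms * self.f0 / 1000.0
        return int(math.ceil(x - 1e-9))


def make_click(spec: StimSpec) -> Waveform:
    """A single rectangular click.

    Rarefaction polarity is rendered as a negative-going deflection of
    unit magnitude; condensation is the sign-flipped copy.  The waveform
    contains exactly the nonzero samples of the pulse,
    ``round(click_width_us * fs)`` of them (at least one).
    """
    n = int(round(spec.click_width_us * 1e-6 * spec.fs))
    if n < 1:
        raise ValueError(
            f"click width {spec.click_width_us} μs is below the minimum "
            f"representable width of {1e6 / spec.fs:g} μs at fs={spec.fs:g} Hz"
        )
    amp = -1.0 if spec.polarity == "rarefaction" else 1.0
    return Waveform(np.full(n, amp), spec.fs, 0.0)


def make_pulse_train(spec: StimSpec) -> Waveform:
    """Periodic unit-impulse train: impulses at t = 0, T, 2T, ... for t < d."""
    if spec.duration_ms < spec.period_ms - 1e-9:
        raise ValueError(
            f"duration {spec.duration_ms} ms is shorter than one period "
            f"T={spec.period_ms:g} ms; the train must contain at least one pulse"
        )
    n_samples = int(round(spec.duration_ms * 1e-3 * spec.fs))
    samples = np.zeros(n_samples)
    for k in range(spec.n_pulses):
        idx = int(round(k * spec.period_ms * 1e-3 * spec.fs))
        if idx < n_samples:
            samples[idx] = 1.0
    return Waveform(samples, spec.fs, 0.0)


def make_click_train(spec: StimSpec) -> Waveform:
    """Periodic click train: the pulse train convolved with one click.

    Every pulse of the train carries an identical click (same bandwidth,
    width, amplitude); the result is the linear superposition of
    per-pulse clicks.
    """
    train = make_pulse_train(spec)
    click = make_click(spec)
    return Waveform(np.convolve(train.samples, click.samples), spec.fs, 0.0)
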