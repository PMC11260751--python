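"""Uniformly sampled voltage traces.

The :class:`Waveform` is the common carrier for everything the package
touches: acoustic click trains, auditory brainstem responses (ABR),
postauricular-muscle (PAM) wavelets, frequency-following responses (FFR),
and the averaged EEG recordings they are measured from.  Amplitudes are in
microvolts for physiological signals and unitless for stimuli; time is in
milliseconds throughout the package, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform"]


@dataclass
class Waveform:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples:
        Voltage sequence (μV; unitless for stimuli).
    fs:
        Sampling rate in Hz. Must be positive.
    t0:
        Time of the first sample in milliseconds (default 0, i.e. the
        epoch starts at stimulus onset).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must all be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return self.t0 + np.arange(self.samples.size) * 1000.0 / self.fs

    @property
    def duration(self) -> float:
        """Epoch length in milliseconds (n_samples / fs)."""
        return self.samples.size * 1000.0 / self.fs

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.fs, self.t0)

    def window_indices(self, start: float, stop: float) -> np.ndarray:
        """Indices of samples with time in the closed interval [start, stop] ms."""
        t = self.times
        idx = np.nonzero((t >= start - 1e-9) & (t <= stop + 1e-9))[0]
        return idx

    def segment(self, start: float, stop: float) -> "Waveform":
        """Extract the sub-waveform on the closed time interval [start, stop] ms."""
        idx = self.window_indices(start, stop)
        if idx.size == 0:
            raise ValueError(
                f"window [{start}, {stop}] ms does not overlap waveform support "
                f"[{self.t0}, {self.t0 + self.duration}] ms"
            )
        return Waveform(self.samples[idx], self.fs, float(self.times[idx[0]]))

    def same_grid(self, other: "Waveform", atol: float = 1e-9) -> bool:
        return (
            self.fs == other.fs
            and len(self) == len(other)
            and abs(self.t0 - other.t0) <= atol
        )
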