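"""Shared in-memory containers for continuous signals and spike trains.

Continuous recordings (LFP, plethysmograph pressure, accelerometer) are
held as uniformly sampled arrays with explicit sampling-rate metadata;
spike trains are ordered event-time arrays with optional waveform
features.  Everything downstream works in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesSignal:
    """Uniformly sampled continuous signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples,)
        Sample values.
    rate_hz : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    channel : str
        Free-form channel label (e.g. ``"OB"``, ``"dmPFC"``, ``"accel"``).
    units : str
        Physical units of the samples.
    """

    data: np.ndarray
    rate_hz: float
    t0: float = 0.0
    channel: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("signal data must be one-dimensional")
        if not self.rate_hz > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate_hz

    def slice(self, t_start: float, t_stop: float) -> "TimeSeriesSignal":
        """Return the sub-signal covering ``[t_start, t_stop)``."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.rate_hz)))
        i1 = min(self.n_samples, int(np.ceil((t_stop - self.t0) * self.rate_hz)))
        return TimeSeriesSignal(
            self.data[i0:i1], self.rate_hz,
            t0=self.t0 + i0 / self.rate_hz,
            channel=self.channel, units=self.units,
        )


@dataclass
class SpikeTrain:
    """Ordered spike times for one unit, with optional waveform features."""

    times: np.ndarray
    unit_id: str = ""
    waveform_features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def in_epochs(self, epochs: np.ndarray) -> np.ndarray:
        """Spike times falling inside any ``(start, stop)`` epoch row."""
        epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
        if epochs.size == 0:
            return np.empty(0)
        keep = np.zeros(self.times.size, dtype=bool)
        for start, stop in epochs:
            keep |= (self.times >= start) & (self.times < stop)
        return self.times[keep]


def epochs_duration(epochs: np.ndarray) -> float:
    """Total duration (s) of a list of (start, stop) epochs."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.size == 0:
        return 0.0
    return float(np.sum(epochs[:, 1] - epochs[:, 0]))
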