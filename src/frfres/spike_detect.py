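"""Threshold-crossing spike detection on extracellular voltage traces.

Multi-unit spikes are extracted the classical way: bandpass the raw trace
to the spike band (200-2000 Hz by default), then take every strict local
minimum whose amplitude exceeds a negative threshold expressed in standard
deviations of the filtered trace (default 3.5 SD).  Because the threshold
is SD-relative, detection is invariant to the overall gain of the
recording chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = ["VoltageTrace", "SpikeTrain", "bandpass", "detect_spikes"]

DEFAULT_BAND = (200.0, 2000.0)
DEFAULT_K_SD = 3.5
DEFAULT_DEAD_TIME_MS = 1.0


@dataclass
class VoltageTrace:
    """A raw or filtered extracellular voltage trace.

    ``t0`` is the time of the first sample relative to stimulus onset (s).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    trial_id: int | None = None
    stim_id: int | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SpikeTrain:
    """Ordered spike times (s, relative to stimulus onset) for one trial."""

    times: np.ndarray
    trial_id: int | None = None
    stim_id: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def bandpass(
    trace: VoltageTrace,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
    order: int = 4,
) -> VoltageTrace:
    """Zero-phase Butterworth bandpass of the spike band.

    A 4th-order Butterworth is applied forward-backward (``sosfiltfilt``),
    which doubles the effective order and cancels group delay, so spike
    times are not shifted by the filter.
    """
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    if hi >= trace.fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {trace.fs / 2} Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    return replace(trace, samples=sosfiltfilt(sos, trace.samples))


def detect_spikes(
    trace: VoltageTrace,
    k_sd: float = DEFAULT_K_SD,
    dead_time_ms: float = DEFAULT_DEAD_TIME_MS,
    robust_sd: bool = False,
) -> SpikeTrain:
    """Detect negative threshold-crossing peaks in a bandpassed trace.

    A spike is a strict local minimum whose amplitude is below
    ``-k_sd * SD`` where SD is estimated per trace from the amplitude
    distribution (plain sample SD by default; ``robust_sd=True`` uses the
    scaled median absolute deviation instead).  A refractory ``dead_time_ms``
    keeps the closest-spaced detections at least that far apart; on flat
    plateaus the earliest sample is taken.
    """
    x = np.asarray(trace.samples, dtype=float)
    if len(x) < 0.010 * trace.fs:
        raise ValueError("trace shorter than 10 ms: SD estimate unreliable")
    if k_sd <= 0:
        raise ValueError("k_sd is a magnitude; it must be positive")
    if robust_sd:
        sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    else:
        sd = float(np.std(x))
    if sd == 0:
        return SpikeTrain(times=np.empty(0), trial_id=trace.trial_id, stim_id=trace.stim_id)
    distance = max(1, round(dead_time_ms / 1000.0 * trace.fs))
    _, props = find_peaks(
        -x, height=k_sd * sd, distance=distance, plateau_size=(1, None)
    )
    idx = props["left_edges"]  # earliest sample of a tied plateau
    times = trace.t0 + idx / trace.fs
    return SpikeTrain(times=times, trial_id=trace.trial_id, stim_id=trace.stim_id)
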