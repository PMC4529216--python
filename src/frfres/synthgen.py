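"""Synthetic data generator: LN-Poisson sites with known ground truth.

The generator embodies the linear-nonlinear-Poisson view of a cortical
multi-unit: an observed response is a Poisson draw around a deterministic
tuning function r over the (F1, F2) stimulus grid,

    observed(S) ~ Poisson((r(S) + background) * window_duration),

with an independent Poisson baseline count at the background rate.  It
supplies every fixture the pipeline needs — trial tables with known r for
FRF and resolution parameter-recovery checks, flat (null) sites for
calibrating the inclusion test, and raw voltage traces with injected spike
waveforms for exercising threshold-crossing detection.

Defaults emulate the study conditions: 55 stimuli on the 10-20 kHz /
0.1-octave grid, 15 repeats per stimulus, a background rate of 12.5 Hz
(one expected spike per 80 ms baseline window), and evoked amplitudes a
few times background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .frf import TRIAL_COLUMNS, TrialTable
from .resolution import _smoothing_operator
from .spike_detect import SpikeTrain, VoltageTrace
from .stimuli import FormantGrid, make_formant_grid

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_trials",
    "make_spike_template",
    "simulate_trace",
    "DEFAULT_BACKGROUND_HZ",
    "DEFAULT_AMPLITUDE_HZ",
    "DEFAULT_N_REPEATS",
]

DEFAULT_BACKGROUND_HZ = 12.5  # one expected baseline spike per 80 ms window
DEFAULT_AMPLITUDE_HZ = 50.0  # evoked peak a few times background
DEFAULT_N_REPEATS = 15
KINDS = ("flat", "bump", "ridge", "gradient", "smoothed_noise")


@dataclass
class GroundTruth:
    """Deterministic evoked tuning function r (Hz) over the valid cells.

    ``r[sid]`` is the evoked rate above background for stimulus ``sid`` in
    manifest order; total onset rate is r + background.
    """

    r: np.ndarray
    background_rate: float
    kind: str
    params: dict
    grid: FormantGrid
    manifest: pd.DataFrame = field(repr=False)
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.r < 0):
            raise ValueError("ground-truth rates must be non-negative")


def _cell_octs(grid: FormantGrid) -> np.ndarray:
    centers_oct = grid.oct_coord(grid.centers)
    return np.array([(centers_oct[i], centers_oct[j]) for i, j in grid.pair_indices])


def make_ground_truth(
    kind: str,
    params: dict | None = None,
    grid: FormantGrid | None = None,
    seed: int | None = None,
    background_rate: float = DEFAULT_BACKGROUND_HZ,
) -> GroundTruth:
    """Construct a reproducible tuning function of the requested kind.

    Kinds (params, defaults):
      - ``flat``: constant evoked rate (``rate``, 0 Hz) — the null site.
      - ``bump``: Gaussian hill at ``center`` (Hz pair, grid middle) of
        ``width`` octaves (0.15) and ``amplitude`` Hz (50).
      - ``ridge``: elevated where the formant separation log2(F2/F1) is at
        most ``half_width`` octaves (0.15) — the diagonal-stripe motif of
        sites excited when F1 and F2 are close together.
      - ``gradient``: linear ramp in (F1+F2) octave position, 0 to
        ``amplitude``.
      - ``smoothed_noise``: seeded white noise over the valid cells,
        smoothed by normalized masked convolution with a Gaussian of width
        ``w`` octaves (0.1), then affinely mapped to
        [background, background + amplitude]; the knob for ground-truth
        smoothness in parameter-recovery studies.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; choose from {KINDS}")
    params = dict(params or {})
    if grid is None:
        grid = make_formant_grid()
    octs = _cell_octs(grid)
    amplitude = float(params.get("amplitude", DEFAULT_AMPLITUDE_HZ))
    if amplitude < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")

    if kind == "flat":
        rate = float(params.get("rate", 0.0))
        if rate < 0:
            raise ValueError("flat rate must be non-negative")
        r = np.full(len(octs), rate)
    elif kind == "bump":
        mid = grid.centers[len(grid.centers) // 2]
        c1, c2 = params.get("center", (grid.centers[2], mid))
        width = float(params.get("width", 0.15))
        d2 = (octs[:, 0] - grid.oct_coord(c1)) ** 2 + (octs[:, 1] - grid.oct_coord(c2)) ** 2
        r = amplitude * np.exp(-d2 / (2.0 * width**2))
    elif kind == "ridge":
        half_width = float(params.get("half_width", 0.15))
        sep = octs[:, 1] - octs[:, 0]
        r = np.where(sep <= half_width + 1e-12, amplitude, 0.0)
    elif kind == "gradient":
        pos = octs.sum(axis=1)
        pos = (pos - pos.min()) / (pos.max() - pos.min())
        r = amplitude * pos
    else:  # smoothed_noise
        w = float(params.get("w", 0.1))
        if w <= 0:
            raise ValueError("smoothed_noise width w must be positive")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(len(octs))
        smooth = _smoothing_operator(octs, w) @ noise
        lo, hi = smooth.min(), smooth.max()
        if hi - lo < 1e-12:
            r = np.full(len(octs), background_rate + amplitude / 2.0)
        else:
            r = background_rate + amplitude * (smooth - lo) / (hi - lo)

    manifest = grid.manifest()
    return GroundTruth(
        r=r,
        background_rate=float(background_rate),
        kind=kind,
        params=params,
        grid=grid,
        manifest=manifest,
        seed=seed,
    )


def simulate_trials(
    gt: GroundTruth,
    n_repeats: int = DEFAULT_N_REPEATS,
    rng: np.random.Generator | None = None,
    onset_window_ms=(20.0, 100.0),
    baseline_window_ms=(400.0, 480.0),
) -> TrialTable:
    """Draw a Poisson trial table around the ground truth.

    onset_count ~ Poisson((r + background) * onset_duration) and
    baseline_count ~ Poisson(background * baseline_duration), independent
    across trials, so spike-count variance matches the mean (Fano = 1).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    rng = np.random.default_rng(rng)
    dur_on = (onset_window_ms[1] - onset_window_ms[0]) / 1000.0
    dur_bl = (baseline_window_ms[1] - baseline_window_ms[0]) / 1000.0
    n_stim = len(gt.r)
    lam_on = (gt.r + gt.background_rate) * dur_on
    onset = rng.poisson(np.repeat(lam_on, n_repeats))
    base = rng.poisson(gt.background_rate * dur_bl, size=n_stim * n_repeats)
    trials = pd.DataFrame(
        {
            "stim_id": np.repeat(np.arange(n_stim), n_repeats),
            "repeat_idx": np.tile(np.arange(n_repeats), n_stim),
            "onset_count": onset,
            "baseline_count": base,
        },
        columns=TRIAL_COLUMNS,
    )
    return TrialTable(
        trials=trials,
        manifest=gt.manifest,
        onset_window_ms=tuple(onset_window_ms),
        baseline_window_ms=tuple(baseline_window_ms),
    )


def make_spike_template(fs: float, duration_ms: float = 1.6) -> np.ndarray:
    """Biphasic, negative-dominant extracellular spike waveform.

    A sharp negative trough followed by a slower positive overshoot,
    normalized so the trough is exactly -1 (amplitudes are then expressed
    in units of noise SD).
    """
    t = np.arange(round(duration_ms / 1000.0 * fs)) / fs * 1000.0  # ms
    w = -np.exp(-((t - 0.4) ** 2) / (2 * 0.12**2)) + 0.45 * np.exp(
        -((t - 0.95) ** 2) / (2 * 0.3**2)
    )
    return w / abs(w.min())


def simulate_trace(
    train: SpikeTrain,
    fs: float = 24_000.0,
    spike_template: np.ndarray | None = None,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    duration: float = 0.5,
    amplitude_sd: float = 8.0,
    noise_band: tuple[float, float] = (100.0, 6000.0),
) -> VoltageTrace:
    """Band-limited Gaussian noise with spike templates superposed.

    Each spike time in ``train`` places one template whose trough reaches
    ``amplitude_sd`` times the noise SD (overlapping templates superpose).
    The noise is white Gaussian bandpassed to ``noise_band`` and rescaled
    to ``noise_sd`` so detection thresholds stated in SD units are exact.
    """
    rng = np.random.default_rng(rng)
    n = round(duration * fs)
    noise = rng.standard_normal(n)
    sos = butter(2, noise_band, btype="bandpass", fs=fs, output="sos")
    noise = sosfiltfilt(sos, noise)
    noise *= noise_sd / noise.std()
    x = noise
    if spike_template is None:
        spike_template = make_spike_template(fs)
    tpl = spike_template * amplitude_sd * noise_sd
    for t in train.times:
        i0 = round(t * fs)
        i1 = min(n, i0 + len(tpl))
        if i0 < 0 or i0 >= n:
            continue
        x[i0:i1] += tpl[: i1 - i0]
    return VoltageTrace(
        samples=x, fs=fs, t0=0.0, trial_id=train.trial_id, stim_id=train.stim_id
    )
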