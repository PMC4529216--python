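"""Two-formant pulse-resonance stimulus synthesis.

Pulse-resonance sounds (PRSs) are the acoustic backbone of most animal
vocalizations: a periodic pulse source (the glottal-pulse analog) drives a
set of resonators, so the harmonics of the fundamental nearest each
resonance peak ("formant") are loudest.  This module builds the standard
two-formant stimulus bank: a click train at a fixed fundamental passed
through a serial cascade of two second-order formant resonators, with the
formant centers (F1 < F2) drawn from a logarithmically spaced grid.

The default grid spans 10-20 kHz at 0.1-octave spacing (11 centers, 55
unordered F1<F2 pairs); the default fundamental is 151 Hz, stimulus length
200 ms, with 5 ms raised-cosine onset/offset ramps and a common RMS
calibration so all stimuli play at the same level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import freqz, lfilter

__all__ = [
    "FormantGrid",
    "StimulusWaveform",
    "make_formant_grid",
    "synth_click_train",
    "apply_formant_cascade",
    "finalize_stimulus",
    "synth_stimulus",
    "write_bank",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["stim_id", "f1_hz", "f2_hz", "f1_oct", "f2_oct", "file"]

# Defaults for the stimulus bank.  The sampling rate is the TDT system rate
# used for playback; the fundamental of 151 Hz is deliberately not an
# integer divisor of typical analysis windows.
DEFAULT_FS = 97656.0
DEFAULT_F0 = 151.0
DEFAULT_DURATION = 0.2
DEFAULT_BW = 200.0
DEFAULT_RAMP_MS = 5.0
DEFAULT_RMS = 0.05


@dataclass(frozen=True)
class FormantGrid:
    """Log-spaced formant center frequencies and all ordered F1<F2 pairs.

    ``centers[k] = f_min * 2**(k * step_oct)``; ``pairs`` enumerates every
    unordered pair of distinct centers ordered so F1 < F2, giving C(n, 2)
    pairs for n centers.  Octave coordinates are measured relative to
    ``f_min``: ``oct_coord(f) = log2(f / f_min)``.
    """

    f_min: float
    f_max: float
    step_oct: float
    centers: np.ndarray
    pairs: list[tuple[float, float]] = field(repr=False)
    pair_indices: list[tuple[int, int]] = field(repr=False)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def span_oct(self) -> float:
        return math.log2(self.f_max / self.f_min)

    def oct_coord(self, f):
        """Octaves above ``f_min`` (vectorized)."""
        return np.log2(np.asarray(f, dtype=float) / self.f_min)

    def manifest(self) -> pd.DataFrame:
        """Stimulus manifest: one row per F1<F2 pair, without file names."""
        rows = []
        for sid, (f1, f2) in enumerate(self.pairs):
            rows.append(
                {
                    "stim_id": sid,
                    "f1_hz": f1,
                    "f2_hz": f2,
                    "f1_oct": float(self.oct_coord(f1)),
                    "f2_oct": float(self.oct_coord(f2)),
                }
            )
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS[:-1])


@dataclass
class StimulusWaveform:
    """A single stimulus: samples plus synthesis metadata."""

    samples: np.ndarray
    fs: float
    f0: float
    f1: float | None = None
    f2: float | None = None
    duration: float = 0.0
    rms_target: float | None = None

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def make_formant_grid(
    f_min: float = 10_000.0,
    f_max: float = 20_000.0,
    step_oct: float = 0.1,
) -> FormantGrid:
    """Build the formant grid: centers at ``f_min * 2**(k*step_oct)``.

    The span log2(f_max/f_min) must be an integer multiple of ``step_oct``
    (tolerance 1e-9 in octaves), so the top center lands exactly on f_max.
    """
    if f_min <= 0 or f_max <= f_min or step_oct <= 0:
        raise ValueError("require 0 < f_min < f_max and step_oct > 0")
    span = math.log2(f_max / f_min)
    n_steps = span / step_oct
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"octave span {span:.6f} is not an integer multiple of "
            f"step_oct={step_oct}; choose commensurate endpoints"
        )
    n_steps = round(n_steps)
    exponents = np.linspace(0.0, span, n_steps + 1)
    centers = f_min * np.exp2(exponents)
    pair_indices = list(combinations(range(n_steps + 1), 2))
    pairs = [(float(centers[i]), float(centers[j])) for i, j in pair_indices]
    return FormantGrid(
        f_min=float(f_min),
        f_max=float(f_max),
        step_oct=float(step_oct),
        centers=centers,
        pairs=pairs,
        pair_indices=pair_indices,
    )


def synth_click_train(
    f0: float = DEFAULT_F0,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
) -> StimulusWaveform:
    """Unit-amplitude impulse train at fundamental ``f0``.

    Impulses sit at ``round(k * fs / f0)`` for k = 0, 1, ... (cumulative
    rounding, so the train does not drift), starting at sample 0.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if f0 >= fs / 2:
        raise ValueError("f0 must be below the Nyquist frequency")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = round(duration * fs)
    x = np.zeros(n)
    k = np.arange(0, int(np.ceil(n * f0 / fs)) + 1)
    idx = np.round(k * fs / f0).astype(int)
    idx = idx[idx < n]
    x[idx] = 1.0
    return StimulusWaveform(samples=x, fs=float(fs), f0=float(f0), duration=n / fs)


def _resonator_coeffs(fc: float, bw: float, fs: float, zeros: bool):
    """Second-order resonator, pole radius exp(-pi*bw/fs), unity gain at fc."""
    r = math.exp(-math.pi * bw / fs)
    if not r < 1.0:
        raise ValueError(f"unstable resonator: pole radius {r:.4f} >= 1 (bw={bw})")
    w0 = 2.0 * math.pi * fc / fs
    a = np.array([1.0, -2.0 * r * math.cos(w0), r * r])
    if zeros:
        # matched zeros at DC and Nyquist flatten the skirt
        b = np.array([1.0, 0.0, -r * r])
    else:
        b = np.array([1.0])
    _, h = freqz(b, a, worN=[w0], fs=2.0 * math.pi)
    gain = abs(h[0])
    if gain == 0:
        raise ValueError("resonator gain vanishes at center frequency")
    return b / gain, a


def apply_formant_cascade(
    wave: StimulusWaveform,
    f1: float,
    f2: float,
    bw: float = DEFAULT_BW,
    zeros: bool = False,
) -> StimulusWaveform:
    """Serial application of two formant resonators centered at f1 and f2.

    Each resonator is a second-order all-pole filter with pole radius
    exp(-pi*bw/fs), normalized to unity gain at its center frequency
    (``zeros=True`` adds matched zeros at DC and Nyquist).  ``bw=inf``
    degenerates both resonators to unity filters (bypass).
    """
    fs = wave.fs
    if not (0 < f1 <= f2 < fs / 2):
        raise ValueError("require 0 < f1 <= f2 < fs/2")
    if not bw > 0:
        raise ValueError("bandwidth must be positive")
    y = wave.samples.astype(float)
    for fc in (f1, f2):
        b, a = _resonator_coeffs(fc, bw, fs, zeros)
        y = lfilter(b, a, y)
    return replace(wave, samples=y, f1=float(f1), f2=float(f2))


def finalize_stimulus(
    wave: StimulusWaveform,
    ramp_ms: float = DEFAULT_RAMP_MS,
    rms_target: float = DEFAULT_RMS,
) -> StimulusWaveform:
    """Apply raised-cosine onset/offset ramps, then calibrate RMS.

    The ramp is a cos^2 flank rising from 0 over ``ramp_ms``; calibration
    rescales the ramped waveform so its RMS equals ``rms_target`` (the
    software stand-in for a fixed playback sound level), so every stimulus
    in a bank plays at the same level irrespective of formant frequencies.
    """
    fs = wave.fs
    x = wave.samples.astype(float).copy()
    n = len(x)
    n_ramp = round(ramp_ms / 1000.0 * fs)
    if 2 * n_ramp > n:
        raise ValueError("ramps longer than the stimulus")
    if not np.any(x):
        raise ValueError("cannot calibrate an all-zero waveform")
    if n_ramp > 0:
        flank = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= flank
        x[n - n_ramp :] *= flank[::-1]
    rms = math.sqrt(float(np.mean(np.square(x))))
    if rms == 0:
        raise ValueError("waveform is zero after ramping; cannot calibrate")
    x *= rms_target / rms
    return replace(wave, samples=x, rms_target=float(rms_target))


def synth_stimulus(
    f1: float,
    f2: float,
    f0: float = DEFAULT_F0,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    bw: float = DEFAULT_BW,
    ramp_ms: float = DEFAULT_RAMP_MS,
    rms_target: float = DEFAULT_RMS,
    zeros: bool = False,
) -> StimulusWaveform:
    """Full synthesis chain: click train -> formant cascade -> ramps + RMS."""
    wave = synth_click_train(f0=f0, duration=duration, fs=fs)
    wave = apply_formant_cascade(wave, f1, f2, bw=bw, zeros=zeros)
    return finalize_stimulus(wave, ramp_ms=ramp_ms, rms_target=rms_target)


def write_bank(
    grid: FormantGrid,
    out_dir,
    f0: float = DEFAULT_F0,
    duration: float = DEFAULT_DURATION,
    fs: float = DEFAULT_FS,
    bw: float = DEFAULT_BW,
    ramp_ms: float = DEFAULT_RAMP_MS,
    rms_target: float = DEFAULT_RMS,
    dtype: str = "float32",
) -> pd.DataFrame:
    """Synthesize the full stimulus bank and write WAVs plus a CSV manifest.

    Returns the manifest (also written to ``out_dir/stimuli.csv``).  WAV
    samples are float32 by default; ``dtype='int16'`` writes PCM-16 with a
    fixed full-scale gain (samples must stay within [-1, 1]).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if dtype not in ("float32", "int16"):
        raise ValueError("dtype must be 'float32' or 'int16'")
    manifest = grid.manifest()
    files = []
    for row in manifest.itertuples():
        wave = synth_stimulus(
            row.f1_hz, row.f2_hz, f0=f0, duration=duration, fs=fs,
            bw=bw, ramp_ms=ramp_ms, rms_target=rms_target,
        )
        fname = f"stim{row.stim_id:03d}.wav"
        samples = wave.samples
        if dtype == "int16":
            if np.max(np.abs(samples)) > 1.0:
                raise ValueError(
                    f"stimulus {row.stim_id} exceeds full scale; lower rms_target"
                )
            data = np.round(samples * 32767.0).astype(np.int16)
        else:
            data = samples.astype(np.float32)
        try:
            wavfile.write(out_dir / fname, int(round(fs)), data)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        files.append(fname)
    manifest = manifest.assign(file=files)
    manifest.to_csv(out_dir / "stimuli.csv", index=False)
    meta = {
        "fs_hz": fs,
        "f0_hz": f0,
        "duration_s": duration,
        "formant_bw_hz": bw,
        "ramp_ms": ramp_ms,
        "rms_target": rms_target,
        "nominal_level_db_spl": 75.0,  # metadata only; not reproducible in software
        "dtype": dtype,
    }
    (out_dir / "bank_meta.json").write_text(json.dumps(meta, indent=2))
    return manifest
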