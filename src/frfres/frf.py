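"""Trial tables and formant receptive fields (FRFs).

The unit of analysis is the trial: one presentation of one two-formant
stimulus, summarized by two spike counts — an onset window (20-100 ms
post-onset, the evoked response) and a baseline window (400-480 ms, in the
silent gap after the stimulus).  An FRF is the per-stimulus mean onset
rate minus the background rate, laid out on the (F1, F2) grid; since
F1 < F2 the valid cells form the upper triangle of the square grid.

Background is the median baseline rate over *all* trials of the site (all
stimuli and repeats pooled), which makes the estimate robust to the
occasional spontaneous burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import FormantGrid, make_formant_grid

__all__ = [
    "TrialTable",
    "FRFMap",
    "count_in_window",
    "build_trial_table",
    "build_frf",
    "grid_from_manifest",
    "ONSET_WINDOW_MS",
    "BASELINE_WINDOW_MS",
]

# Half-open count windows [start, end) in ms relative to stimulus onset.
ONSET_WINDOW_MS = (20.0, 100.0)
BASELINE_WINDOW_MS = (400.0, 480.0)

TRIAL_COLUMNS = ["stim_id", "repeat_idx", "onset_count", "baseline_count"]


def count_in_window(train, win_start_ms: float, win_end_ms: float) -> int:
    """Spike count in the half-open window [win_start_ms, win_end_ms).

    ``train`` may be a SpikeTrain or a plain array of spike times in s.
    """
    if win_start_ms >= win_end_ms:
        raise ValueError("window start must precede window end")
    times = np.asarray(getattr(train, "times", train), dtype=float)
    if times.size == 0:
        return 0
    lo, hi = win_start_ms / 1000.0, win_end_ms / 1000.0
    return int(np.count_nonzero((times >= lo) & (times < hi)))


@dataclass
class TrialTable:
    """Per-trial onset/baseline spike counts plus the stimulus manifest.

    ``trials`` has columns stim_id, repeat_idx, onset_count, baseline_count;
    ``manifest`` has one row per stimulus with f1_hz/f2_hz/f1_oct/f2_oct.
    Repeat counts may be ragged across stimuli (flagged by ``is_ragged``).
    """

    trials: pd.DataFrame
    manifest: pd.DataFrame
    onset_window_ms: tuple[float, float] = ONSET_WINDOW_MS
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS

    def __post_init__(self):
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        counts = self.trials[["onset_count", "baseline_count"]].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("spike counts must be non-negative integers")
        unknown = set(self.trials.stim_id) - set(self.manifest.stim_id)
        if unknown:
            raise ValueError(f"trials reference unknown stim_ids: {sorted(unknown)}")

    @property
    def onset_duration_s(self) -> float:
        a, b = self.onset_window_ms
        return (b - a) / 1000.0

    @property
    def baseline_duration_s(self) -> float:
        a, b = self.baseline_window_ms
        return (b - a) / 1000.0

    @property
    def n_stimuli(self) -> int:
        return len(self.manifest)

    def repeats_per_stim(self) -> pd.Series:
        return self.trials.groupby("stim_id").size()

    @property
    def is_ragged(self) -> bool:
        return self.repeats_per_stim().nunique() > 1

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, trials_path, manifest_path, **kw) -> "TrialTable":
        trials = pd.read_csv(trials_path)
        manifest = pd.read_csv(manifest_path)
        return cls(trials=trials, manifest=manifest, **kw)


def grid_from_manifest(manifest: pd.DataFrame) -> FormantGrid:
    """Reconstruct the formant grid from a stimulus manifest."""
    freqs = np.unique(np.concatenate([manifest.f1_hz, manifest.f2_hz]))
    steps = np.diff(np.log2(freqs))
    step = float(np.median(steps))
    if not np.allclose(steps, step, atol=1e-6):
        raise ValueError("manifest frequencies are not on a uniform octave grid")
    return make_formant_grid(float(freqs[0]), float(freqs[-1]), step)


@dataclass
class FRFMap:
    """Baseline-adjusted mean onset rates on the (F1, F2) grid.

    ``values`` is an (n, n) array indexed ``[i_f2, i_f1]`` (F1 along
    columns / the x-axis), NaN at invalid cells; ``mask`` is True exactly
    where F1 < F2.  Values are rates in Hz and may be negative after
    background subtraction.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: FormantGrid
    background_rate: float = 0.0
    stim_cells: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.stim_cells:
            self.stim_cells = list(self.grid.pair_indices)
        if int(self.mask.sum()) != len(self.stim_cells):
            raise ValueError("mask does not match the stimulus cell list")

    @property
    def vector(self) -> np.ndarray:
        """Valid-cell values in manifest (stim_id) order."""
        i1 = np.array([c[0] for c in self.stim_cells])
        i2 = np.array([c[1] for c in self.stim_cells])
        return self.values[i2, i1]

    def with_vector(self, vec: np.ndarray) -> "FRFMap":
        """A copy of this map with the valid cells replaced by ``vec``."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(self.stim_cells),):
            raise ValueError("vector length does not match valid-cell count")
        values = np.full_like(self.values, np.nan)
        for v, (i1, i2) in zip(vec, self.stim_cells):
            values[i2, i1] = v
        return FRFMap(
            values=values,
            mask=self.mask.copy(),
            grid=self.grid,
            background_rate=self.background_rate,
            stim_cells=list(self.stim_cells),
        )

    def oct_coords(self) -> np.ndarray:
        """(n_stim, 2) octave coordinates (F1, F2) of the valid cells."""
        centers_oct = self.grid.oct_coord(self.grid.centers)
        return np.array(
            [(centers_oct[i1], centers_oct[i2]) for i1, i2 in self.stim_cells]
        )

    def to_csv(self, path) -> None:
        n = self.values.shape[0]
        df = pd.DataFrame(
            self.values,
            index=pd.Index(np.round(self.grid.centers[:n], 3), name="f2_hz"),
            columns=np.round(self.grid.centers[:n], 3),
        )
        df.columns.name = "f1_hz"
        df.to_csv(path)


def build_trial_table(
    trains,
    manifest: pd.DataFrame,
    onset_window_ms=ONSET_WINDOW_MS,
    baseline_window_ms=BASELINE_WINDOW_MS,
) -> TrialTable:
    """Count spikes per trial in the onset and baseline windows.

    ``trains`` is an iterable of SpikeTrain, each tagged with a manifest
    stim_id; repeat indices are assigned in input order within a stimulus.
    """
    known = set(manifest.stim_id)
    rows = []
    repeat_counter: dict[int, int] = {}
    for train in trains:
        sid = train.stim_id
        if sid not in known:
            raise ValueError(f"spike train references unknown stim_id {sid!r}")
        rep = repeat_counter.get(sid, 0)
        repeat_counter[sid] = rep + 1
        rows.append(
            {
                "stim_id": sid,
                "repeat_idx": rep,
                "onset_count": count_in_window(train, *onset_window_ms),
                "baseline_count": count_in_window(train, *baseline_window_ms),
            }
        )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return TrialTable(
        trials=trials,
        manifest=manifest,
        onset_window_ms=tuple(onset_window_ms),
        baseline_window_ms=tuple(baseline_window_ms),
    )


def build_frf(table: TrialTable, grid: FormantGrid | None = None) -> FRFMap:
    """Average trials into a baseline-adjusted FRF.

    Each valid cell holds ``mean(onset_rate) - background`` where the mean
    runs over that stimulus's repeats and ``background`` is the median
    baseline rate over all trials of the table.  Rates are counts divided
    by the window duration (0.08 s for the defaults).
    """
    if grid is None:
        grid = grid_from_manifest(table.manifest)
    if len(table.trials) == 0:
        raise ValueError("empty trial table")
    reps = table.repeats_per_stim()
    missing = set(table.manifest.stim_id) - set(reps.index)
    if missing:
        raise ValueError(f"stimuli with zero repeats: {sorted(missing)}")
    background = float(
        np.median(table.trials.baseline_count.to_numpy())
    ) / table.baseline_duration_s
    mean_onset = table.trials.groupby("stim_id").onset_count.mean()
    n = grid.n_centers
    values = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    # stim_id order must match grid.pairs (the manifest ordering)
    centers_oct = grid.oct_coord(grid.centers)
    stim_cells = []
    oct_by_sid = table.manifest.set_index("stim_id")
    for sid in table.manifest.stim_id:
        o1, o2 = oct_by_sid.loc[sid, ["f1_oct", "f2_oct"]]
        i1 = int(np.argmin(np.abs(centers_oct - o1)))
        i2 = int(np.argmin(np.abs(centers_oct - o2)))
        stim_cells.append((i1, i2))
        values[i2, i1] = mean_onset.loc[sid] / table.onset_duration_s - background
        mask[i2, i1] = True
    return FRFMap(
        values=values,
        mask=mask,
        grid=grid,
        background_rate=background,
        stim_cells=stim_cells,
    )
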