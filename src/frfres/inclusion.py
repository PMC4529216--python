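"""Site inclusion: is firing significantly stimulus-modulated?

The (F1, F2) stimulus plane is split into four approximately equal
"quadrants" — bottom-left (both formants low), top-right (both high),
top-left (low F1, high F2), and central — and a Kruskal-Wallis omnibus
test compares onset spike counts pooled by quadrant (four groups) against
the baseline counts of all trials (a fifth group).  A site is included
when the test rejects at alpha = 0.05: its median firing differs either
between quadrants or from baseline.

The quadrant predicates overlap as stated (top-right implies the
sum-threshold), so they are evaluated with precedence q1 -> q2 -> q3 -> q4
with strict inequalities, which reproduces the intended geometric
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kruskal

from .frf import TrialTable

__all__ = ["QuadrantPartition", "assign_quadrant", "inclusion_test"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class QuadrantPartition:
    """Thresholds splitting the formant plane into four quadrants.

    Defaults match an 11-center 10-20 kHz grid: the frequency split sits at
    the (rounded) middle center, 13.2 kHz, and the sum split at twice that.
    """

    f_split: float = 13_200.0
    sum_split: float = 26_400.0


def assign_quadrant(f1: float, f2: float, part: QuadrantPartition = QuadrantPartition()) -> int:
    """Quadrant of a stimulus, by precedence with strict inequalities.

    1 if F2 < f_split (bottom left); else 2 if F1 > f_split (top right);
    else 3 if F1 + F2 > sum_split (top left); else 4 (central).
    Boundary equalities fall through to later quadrants.
    """
    if f2 < part.f_split:
        return 1
    if f1 > part.f_split:
        return 2
    if f1 + f2 > part.sum_split:
        return 3
    return 4


def inclusion_test(
    table: TrialTable,
    part: QuadrantPartition = QuadrantPartition(),
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, bool]:
    """Kruskal-Wallis across quadrant onset counts plus pooled baseline.

    Five groups: the onset spike counts of all trials pooled by stimulus
    quadrant (four groups), and the baseline counts of all trials (the
    fifth).  Returns (p_value, include) with include = p < alpha; the
    tie-corrected statistic is used (spike counts are heavily tied).  If
    every count in every group is identical there is no evidence of
    modulation and (1.0, False) is returned.
    """
    man = table.manifest.set_index("stim_id")
    quad = {
        sid: assign_quadrant(man.loc[sid, "f1_hz"], man.loc[sid, "f2_hz"], part)
        for sid in man.index
    }
    trial_quads = table.trials.stim_id.map(quad)
    groups = [
        table.trials.onset_count[trial_quads == q].to_numpy() for q in (1, 2, 3, 4)
    ]
    groups = [g for g in groups if len(g)]
    groups.append(table.trials.baseline_count.to_numpy())
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 trials")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0, False
    _, p = kruskal(*groups)
    return float(p), bool(p < alpha)
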