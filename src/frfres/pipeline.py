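"""End-to-end orchestration: config, seeding, synthetic and real runs.

A run takes trial tables for many recording sites through inclusion
testing and resolution estimation, and aggregates the per-site best
sigmas into population summaries.  ``run_synthetic`` generates the sites
from the LN-Poisson ground-truth generator (and scores them against the
known truth); ``run_real`` consumes user-supplied trial/spike-time CSVs.

Reproducibility: a single top-level seed fans out into named substreams
(one per site, one for ground-truth construction, one for plotting
jitter) via ``numpy.random.SeedSequence`` spawn keys, so any site can be
re-simulated independently of the others.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frf import BASELINE_WINDOW_MS, ONSET_WINDOW_MS, TrialTable, build_trial_table
from .inclusion import DEFAULT_ALPHA, QuadrantPartition, inclusion_test
from .population import SiteResult, compare_groups, results_frame, summarize
from .resolution import (
    DEFAULT_N_BOOT,
    DEFAULT_N_TEST,
    DEFAULT_N_TRAIN,
    SIGMA_GRID,
    estimate_resolution,
)
from .spike_detect import SpikeTrain
from .stimuli import make_formant_grid
from .synthgen import (
    DEFAULT_AMPLITUDE_HZ,
    DEFAULT_BACKGROUND_HZ,
    DEFAULT_N_REPEATS,
    make_ground_truth,
    simulate_trials,
)

__all__ = ["RunConfig", "run_synthetic", "run_real", "analyze_sites"]

log = logging.getLogger("frfres")

RESULT_COLUMNS = [
    "site_id", "animal_id", "penetration_id", "depth_um",
    "best_sigma", "p_inclusion", "included",
]


@dataclass
class RunConfig:
    """All pipeline knobs, defaulting to the standard study conditions."""

    # stimulus grid and synthesis
    f_min: float = 10_000.0
    f_max: float = 20_000.0
    step_oct: float = 0.1
    f0: float = 151.0
    fs: float = 97_656.0
    stim_duration: float = 0.2
    ramp_ms: float = 5.0
    formant_bw: float = 200.0
    # count windows (ms, half-open)
    onset_window_ms: tuple = ONSET_WINDOW_MS
    baseline_window_ms: tuple = BASELINE_WINDOW_MS
    # spike detection
    band: tuple = (200.0, 2000.0)
    k_sd: float = 3.5
    dead_time_ms: float = 1.0
    # inclusion
    alpha: float = DEFAULT_ALPHA
    # cross-validation
    sigmas: tuple = SIGMA_GRID
    n_train: int = DEFAULT_N_TRAIN
    n_test: int = DEFAULT_N_TEST
    n_boot: int = DEFAULT_N_BOOT
    # synthetic population
    n_sites: int = 20
    n_repeats: int = DEFAULT_N_REPEATS
    background_rate: float = DEFAULT_BACKGROUND_HZ
    amplitude: float = DEFAULT_AMPLITUDE_HZ
    site_kinds: tuple = ("smoothed_noise",)
    smoothed_noise_ws: tuple = (0.05, 0.1, 0.2, 0.4)
    sites_per_penetration: int = 16
    depth_step_um: float = 100.0
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not (0 < self.f_min < self.f_max):
            problems.append("f_min/f_max: require 0 < f_min < f_max")
        if self.step_oct <= 0:
            problems.append("step_oct: must be positive")
        if self.n_train < 1:
            problems.append("n_train: must be >= 1")
        if self.n_test < 1:
            problems.append("n_test: must be >= 1")
        if self.n_boot < 2:
            problems.append("n_boot: must be >= 2")
        if self.n_repeats < self.n_train + self.n_test:
            problems.append("n_repeats: must cover n_train + n_test")
        if not all(s > 0 for s in self.sigmas):
            problems.append("sigmas: must all be positive")
        if not (0 < self.alpha < 1):
            problems.append("alpha: must be in (0, 1)")
        if self.n_sites < 1:
            problems.append("n_sites: must be >= 1")
        if any(k not in ("flat", "bump", "ridge", "gradient", "smoothed_noise")
               for k in self.site_kinds):
            problems.append("site_kinds: unknown kind")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("onset_window_ms", "baseline_window_ms", "band", "sigmas",
                    "site_kinds", "smoothed_noise_ws"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    """Independent, reproducible substream for one site."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(site_index,)))


def _site_params(config: RunConfig, i: int) -> tuple[str, dict]:
    kind = config.site_kinds[i % len(config.site_kinds)]
    params: dict = {"amplitude": config.amplitude}
    if kind == "smoothed_noise":
        ws = config.smoothed_noise_ws
        params["w"] = ws[(i // len(config.site_kinds)) % len(ws)]
    if kind == "flat":
        params = {"rate": 0.0}
    return kind, params


def analyze_sites(
    tables: dict[str, TrialTable],
    config: RunConfig,
    site_meta: dict[str, dict] | None = None,
) -> list[SiteResult]:
    """Inclusion test + resolution estimate for a set of sites.

    ``tables`` maps site_id to its TrialTable; ``site_meta`` may supply
    animal/penetration/depth tags per site.  Excluded sites carry a NaN
    best sigma.  RNG substreams are derived from the config seed and each
    site's position so sites are independently reproducible.
    """
    part = QuadrantPartition()
    results = []
    for i, (site_id, table) in enumerate(tables.items()):
        t_start = time.perf_counter()
        meta = (site_meta or {}).get(site_id, {})
        p, included = inclusion_test(table, part, alpha=config.alpha)
        best = float("nan")
        if included:
            rng = _site_rng(config.seed, 10_000 + i)
            curve = estimate_resolution(
                table, sigmas=config.sigmas, n_boot=config.n_boot,
                n_train=config.n_train, n_test=config.n_test, rng=rng,
            )
            best = curve.best_sigma
        results.append(
            SiteResult(
                site_id=site_id,
                animal_id=str(meta.get("animal_id", "synthetic")),
                penetration_id=str(meta.get("penetration_id", "p00")),
                depth_um=float(meta.get("depth_um", 0.0)),
                best_sigma=best,
                p_inclusion=p,
                included=included,
            )
        )
        log.debug(
            "site %s: p=%.3g included=%s best_sigma=%.4g (%.2fs)",
            site_id, p, included, best, time.perf_counter() - t_start,
        )
    return results


def _write_results(results, out_dir: Path, extra: dict | None = None) -> None:
    df = results_frame(results)
    df.to_csv(out_dir / "results.csv", index=False, float_format="%.10g")
    if any(r.included for r in results):
        summary = summarize(results)
    else:
        summary = {
            "n_sites": len(results),
            "n_included": 0,
            "n_excluded": len(results),
        }
        log.warning("no site passed the inclusion criterion")
    if len({r.penetration_id for r in results if r.included}) >= 2:
        summary["p_kw_penetration"] = compare_groups(results, "penetration")
    if len({r.depth_um for r in results if r.included}) >= 2:
        try:
            summary["p_kw_depth"] = compare_groups(results, "depth")
        except ValueError:
            pass
    if extra:
        summary.update(extra)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def run_synthetic(config: RunConfig, out_dir) -> list[SiteResult]:
    """Generate, analyze and summarize a synthetic population.

    Writes results.csv, summary.json, ground_truth.json and trials CSVs to
    ``out_dir``; fully reproducible from (config, seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    grid = make_formant_grid(config.f_min, config.f_max, config.step_oct)
    manifest = grid.manifest()
    manifest.assign(file="").to_csv(out_dir / "stimuli.csv", index=False)
    log.info("grid: %d centers, %d pairs", grid.n_centers, grid.n_pairs)

    tables, meta, gt_records = {}, {}, {}
    per_pen = config.sites_per_penetration
    for i in range(config.n_sites):
        kind, params = _site_params(config, i)
        rng = _site_rng(config.seed, i)
        gt_seed = int(rng.integers(2**31))
        gt = make_ground_truth(
            kind, params, grid=grid, seed=gt_seed,
            background_rate=config.background_rate,
        )
        table = simulate_trials(
            gt, n_repeats=config.n_repeats, rng=rng,
            onset_window_ms=config.onset_window_ms,
            baseline_window_ms=config.baseline_window_ms,
        )
        site_id = f"site{i:03d}"
        tables[site_id] = table
        meta[site_id] = {
            "animal_id": f"a{i // (4 * per_pen):02d}",
            "penetration_id": f"p{i // per_pen:02d}",
            "depth_um": (i % per_pen) * config.depth_step_um,
        }
        gt_records[site_id] = {
            "kind": kind,
            "params": params,
            "background_rate": gt.background_rate,
            "seed": gt_seed,
            "r": [float(v) for v in gt.r],
        }
        table.to_csv(out_dir / f"trials_{site_id}.csv")
    log.info("simulated %d sites in %.1fs", config.n_sites, time.perf_counter() - t0)

    results = analyze_sites(tables, config, meta)
    (out_dir / "ground_truth.json").write_text(json.dumps(gt_records, indent=2))
    _write_results(results, out_dir, extra={"seed": config.seed})
    config.to_yaml(out_dir / "config.yaml")
    log.info("run complete in %.1fs", time.perf_counter() - t0)
    return results


def _table_from_spike_times(trials: pd.DataFrame, manifest: pd.DataFrame,
                            config: RunConfig) -> TrialTable:
    trains = []
    for (sid, tid), grp in trials.groupby(["stim_id", "trial_id"], sort=True):
        times = np.sort(grp.spike_time_s.to_numpy())
        trains.append(SpikeTrain(times=times, trial_id=tid, stim_id=sid))
    return build_trial_table(
        trains, manifest,
        onset_window_ms=config.onset_window_ms,
        baseline_window_ms=config.baseline_window_ms,
    )


def run_real(trials_path, manifest_path, config: RunConfig, out_dir) -> list[SiteResult]:
    """Analyze user-supplied data: trial counts or spike times + manifest.

    The trials CSV is either the counts schema
    (stim_id, repeat_idx, onset_count, baseline_count[, site_id]) or the
    spike-times schema (trial_id, stim_id, spike_time_s[, site_id]).
    Outputs mirror ``run_synthetic`` minus ground-truth scoring.
    """
    config.validate()
    out_dir = Path(out_dir)
    trials = pd.read_csv(trials_path)
    manifest = pd.read_csv(manifest_path)
    if trials.empty:
        raise ValueError(f"empty trials file: {trials_path}")
    need_manifest = {"stim_id", "f1_hz", "f2_hz", "f1_oct", "f2_oct"}
    if not need_manifest <= set(manifest.columns):
        raise ValueError(
            f"manifest missing columns: {sorted(need_manifest - set(manifest.columns))}"
        )
    counts_schema = {"stim_id", "repeat_idx", "onset_count", "baseline_count"}
    times_schema = {"trial_id", "stim_id", "spike_time_s"}
    cols = set(trials.columns)
    unknown = set(trials.stim_id) - set(manifest.stim_id)
    if unknown:
        bad_rows = trials.index[trials.stim_id.isin(unknown)].tolist()[:10]
        raise ValueError(
            f"trials reference stim_ids missing from the manifest: "
            f"{sorted(unknown)[:10]} (first rows: {bad_rows})"
        )
    site_col = trials["site_id"] if "site_id" in cols else pd.Series(
        "site000", index=trials.index
    )
    tables = {}
    for site_id, grp in trials.groupby(site_col, sort=True):
        grp = grp.drop(columns=["site_id"], errors="ignore")
        if counts_schema <= cols:
            tables[str(site_id)] = TrialTable(
                trials=grp.reset_index(drop=True), manifest=manifest,
                onset_window_ms=config.onset_window_ms,
                baseline_window_ms=config.baseline_window_ms,
            )
        elif times_schema <= cols:
            tables[str(site_id)] = _table_from_spike_times(grp, manifest, config)
        else:
            raise ValueError(
                "trials CSV matches neither the counts schema "
                f"{sorted(counts_schema)} nor the spike-times schema "
                f"{sorted(times_schema)}; found columns {sorted(cols)}"
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    results = analyze_sites(tables, config)
    _write_results(results, out_dir, extra={"seed": config.seed})
    return results
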