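"""The core estimator: masked smoothing, CV splits, bandwidth selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from frfres.frf import build_frf
from frfres.resolution import (
    SIGMA_GRID,
    cv_split,
    estimate_resolution,
    kernel_weight,
    prediction_error,
    smooth_frf,
)
from frfres.synthgen import make_ground_truth, simulate_trials


def brute_force_smooth(frf, sigma):
    """Independent oracle: explicit double loop over valid cell pairs."""
    coords = frf.oct_coords()
    v = frf.vector
    out = np.empty_like(v)
    for i in range(len(v)):
        num = den = 0.0
        for j in range(len(v)):
            d = np.hypot(coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1])
            w = np.exp(-(d**2) / (2 * sigma**2))
            num += w * v[j]
            den += w
        out[i] = num / den
    return out


class TestKernelWeight:
    def test_center_weight_is_one(self):
        assert kernel_weight(0.0, 0.3) == 1.0

    def test_neighbor_weights_at_grid_spacing(self):
        # weight of a stimulus 0.1 octaves away, for three kernel widths
        assert kernel_weight(0.1, 0.08) == pytest.approx(0.4578, abs=2e-4)
        assert kernel_weight(0.1, 0.04) == pytest.approx(0.0439, abs=2e-4)
        assert kernel_weight(0.1, 0.02) == pytest.approx(3.73e-6, rel=2e-3)

    @given(
        d=st.floats(0.01, 0.5),
        sigma=st.floats(0.05, 5.0),
        factor=st.floats(1.01, 3.0),
    )
    def test_monotone_in_distance_and_width(self, d, sigma, factor):
        assert kernel_weight(d * factor, sigma) < kernel_weight(d, sigma)
        assert kernel_weight(d, sigma * factor) > kernel_weight(d, sigma)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            kernel_weight(0.1, 0.0)


class TestSmoothFRF:
    def test_constant_field_preserved_exactly(self, noise_table):
        frf = build_frf(noise_table).with_vector(np.full(55, 7.25))
        for sigma in SIGMA_GRID:
            out = smooth_frf(frf, sigma)
            assert np.allclose(out.vector, 7.25, atol=1e-12)

    def test_large_sigma_flattens_to_grand_mean(self, noise_table):
        frf = build_frf(noise_table)
        out = smooth_frf(frf, 5.12)
        # on a 1-octave grid a 5.12-octave kernel is nearly uniform:
        # every cell sits within 0.1% of the kernel-weighted grand mean
        scale = np.abs(frf.vector).max()
        assert np.all(np.abs(out.vector - frf.vector.mean()) < 1e-3 * scale)

    def test_small_sigma_leaves_raw_map(self, noise_table):
        # at sigma=0.02 the nearest neighbor weighs 3.7e-6: output == input
        frf = build_frf(noise_table)
        out = smooth_frf(frf, 0.02)
        assert np.allclose(out.vector, frf.vector, rtol=1e-4, atol=1e-4)

    def test_matches_brute_force_oracle(self, noise_table):
        frf = build_frf(noise_table)
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=55) * 40
            sigma = float(rng.choice(SIGMA_GRID))
            m = frf.with_vector(v)
            expected = brute_force_smooth(m, sigma)
            got = smooth_frf(m, sigma).vector
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-10)

    def test_rejects_nonpositive_sigma(self, noise_table):
        with pytest.raises(ValueError):
            smooth_frf(build_frf(noise_table), -0.1)


class TestPredictionError:
    def test_identical_maps_score_zero(self, noise_table):
        frf = build_frf(noise_table)
        assert prediction_error(frf, frf) == 0.0

    def test_constant_offset_scores_c_squared(self, noise_table):
        frf = build_frf(noise_table)
        shifted = frf.with_vector(frf.vector + 3.0)
        assert prediction_error(frf, shifted) == pytest.approx(9.0)

    def test_matches_loop_oracle(self, noise_table):
        rng = np.random.default_rng(1)
        frf = build_frf(noise_table)
        a = frf.with_vector(rng.normal(size=55))
        b = frf.with_vector(rng.normal(size=55))
        manual = sum((x - y) ** 2 for x, y in zip(a.vector, b.vector)) / 55
        assert prediction_error(a, b) == pytest.approx(manual, rel=1e-12)

    def test_mask_mismatch_rejected(self, noise_table):
        frf = build_frf(noise_table)
        other = build_frf(noise_table)
        other.mask = ~other.mask
        with pytest.raises(ValueError):
            prediction_error(frf, other)


class TestCVSplit:
    def test_disjoint_split_sizes(self, noise_table):
        rng = np.random.default_rng(0)
        train, test = cv_split(noise_table, 10, 5, rng)
        # both reductions cover all 55 cells and are valid FRFs
        assert train.mask.sum() == 55 and test.mask.sum() == 55
        assert not np.allclose(train.vector, test.vector)

    def test_leave_one_out_variant_runs(self, noise_table):
        train, test = cv_split(noise_table, 14, 1, np.random.default_rng(0))
        assert np.isfinite(test.vector).all()

    def test_fixed_seed_reproducible(self, noise_table):
        a = cv_split(noise_table, 10, 5, np.random.default_rng(3))
        b = cv_split(noise_table, 10, 5, np.random.default_rng(3))
        assert np.array_equal(a[0].vector, b[0].vector)
        assert np.array_equal(a[1].vector, b[1].vector)

    def test_insufficient_repeats_rejected(self, noise_table):
        with pytest.raises(ValueError, match="repeats"):
            cv_split(noise_table, 14, 5, np.random.default_rng(0))


class TestEstimateResolution:
    def test_determinism(self, noise_table):
        a = estimate_resolution(noise_table, n_boot=50, rng=np.random.default_rng(5))
        b = estimate_resolution(noise_table, n_boot=50, rng=np.random.default_rng(5))
        assert np.array_equal(a.mse_mean, b.mse_mean)
        assert a.best_sigma == b.best_sigma

    def test_interpolated_minimum_below_samples(self, noise_table):
        c = estimate_resolution(noise_table, n_boot=100, rng=np.random.default_rng(6))
        best_mse = np.min(c.spline_mse)
        assert np.all(best_mse <= c.mse_mean + 1e-9)
        assert min(SIGMA_GRID) <= c.best_sigma <= max(SIGMA_GRID)

    def test_vectorized_path_matches_op_composition(self, noise_table):
        # the batched inner loop must agree (statistically) with the
        # explicit cv_split -> smooth_frf -> prediction_error composition
        sigma = 0.16
        n = 400
        rng = np.random.default_rng(7)
        manual = np.array(
            [
                prediction_error(
                    smooth_frf(cv_split(noise_table, 10, 5, rng)[0], sigma),
                    cv_split(noise_table, 10, 5, rng)[1],
                )
                for _ in range(n // 2)
            ]
        )
        curve = estimate_resolution(
            noise_table, sigmas=[sigma], n_boot=n, rng=np.random.default_rng(8)
        )
        sem = manual.std(ddof=1) / np.sqrt(len(manual))
        assert abs(curve.mse_mean[0] - manual.mean()) < 4 * (sem + curve.mse_sem[0])

    def test_sem_shrinks_with_bootstrap_size(self, noise_table):
        sems = []
        for n_boot in (100, 400):
            c = estimate_resolution(
                noise_table, sigmas=[0.16], n_boot=n_boot,
                rng=np.random.default_rng(9),
            )
            sems.append(c.mse_sem[0])
        ratio = sems[0] / sems[1]
        assert 2.0 * 0.8 <= ratio <= 2.0 * 1.2  # ~ sqrt(400/100)

    def test_smoothness_recovery_coarse_vs_fine(self, grid):
        # coarse-grained truth -> wide best sigma; fine truth -> narrow
        best = {}
        for w in (0.05, 0.4):
            vals = []
            for i in range(8):
                rng = np.random.default_rng(np.random.SeedSequence(3, spawn_key=(i,)))
                gt = make_ground_truth(
                    "smoothed_noise", {"w": w, "amplitude": 50.0},
                    grid=grid, seed=int(rng.integers(2**31)),
                )
                table = simulate_trials(gt, 15, rng=rng)
                c = estimate_resolution(table, n_boot=60, rng=rng)
                vals.append(c.best_sigma)
            best[w] = np.median(vals)
        assert best[0.05] < best[0.4]

    def test_degenerate_all_zero_table_flagged_flat(self, flat_table):
        zeroed = flat_table.trials.copy()
        zeroed.onset_count = 0
        zeroed.baseline_count = 0
        from frfres.frf import TrialTable

        table = TrialTable(trials=zeroed, manifest=flat_table.manifest)
        c = estimate_resolution(table, n_boot=10, rng=np.random.default_rng(0))
        assert c.flat
        assert c.best_sigma == max(SIGMA_GRID)

    def test_share_splits_reuses_split_pool(self, noise_table):
        c = estimate_resolution(
            noise_table, n_boot=50, rng=np.random.default_rng(10), share_splits=True
        )
        assert np.isfinite(c.mse_mean).all()
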