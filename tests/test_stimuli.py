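"""Stimulus synthesis: formant grid, click trains, resonators, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.io import wavfile

from frfres.stimuli import (
    apply_formant_cascade,
    finalize_stimulus,
    make_formant_grid,
    synth_click_train,
    synth_stimulus,
    write_bank,
)


class TestFormantGrid:
    def test_default_grid_cardinality(self, grid):
        assert grid.n_centers == 11
        assert grid.n_pairs == 55
        assert grid.centers[-1] == pytest.approx(20_000.0)

    def test_endpoints_only(self):
        g = make_formant_grid(10_000, 20_000, 1.0)
        assert g.n_centers == 2
        assert g.n_pairs == 1

    def test_center_closed_form(self, grid):
        # centers[k] = f_min * 2**(k/10); k=5 is the half-octave point
        assert grid.centers[5] == pytest.approx(10_000 * 2**0.5, rel=1e-12)

    def test_pairs_ordered_f1_below_f2(self, grid):
        assert all(f1 < f2 for f1, f2 in grid.pairs)

    def test_octave_coordinates_span(self, grid):
        octs = grid.oct_coord(grid.centers)
        assert octs[0] == pytest.approx(0.0)
        assert octs[-1] == pytest.approx(1.0)

    def test_non_commensurate_span_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            make_formant_grid(10_000, 20_000, 0.13)

    @given(n_steps=st.integers(min_value=1, max_value=24))
    def test_pair_count_is_n_choose_2(self, n_steps):
        g = make_formant_grid(8_000, 8_000 * 2 ** (n_steps * 0.05), 0.05)
        n = g.n_centers
        assert n == n_steps + 1
        assert g.n_pairs == n * (n - 1) // 2
        # oracle: exhaustive enumeration of distinct unordered pairs
        assert len({tuple(sorted(p)) for p in g.pairs}) == g.n_pairs


class TestClickTrain:
    def test_impulse_count_at_default_parameters(self):
        wave = synth_click_train(151.0, 0.2, 97_656.0)
        assert int(wave.samples.sum()) == math.floor(0.2 * 151) + 1  # 31

    def test_single_impulse_at_origin(self):
        wave = synth_click_train(1.0, 0.5, 1000.0)
        assert wave.samples[0] == 1.0
        assert wave.samples.sum() == 1.0

    def test_spectral_lines_at_harmonics(self):
        fs = 97_656.0
        wave = synth_click_train(151.0, 0.2, fs)
        spec = np.abs(np.fft.rfft(wave.samples))
        freqs = np.fft.rfftfreq(len(wave.samples), 1 / fs)
        # the strongest peaks below 5 kHz sit at multiples of ~151 Hz
        peaks = freqs[np.argsort(spec[freqs < 5000])[-10:]]
        ratios = peaks[peaks > 75] / 151.0
        assert np.allclose(ratios, np.round(ratios), atol=0.05)

    def test_rejects_bad_fundamental(self):
        with pytest.raises(ValueError):
            synth_click_train(0.0, 0.2, 97_656.0)
        with pytest.raises(ValueError):
            synth_click_train(60_000.0, 0.2, 97_656.0)


class TestFormantCascade:
    def _spectrum(self, wave):
        spec = np.abs(np.fft.rfft(wave.samples))
        freqs = np.fft.rfftfreq(len(wave.samples), 1 / wave.fs)
        return freqs, spec

    def test_largest_harmonic_near_a_formant(self):
        wave = synth_click_train(151.0, 0.2, 97_656.0)
        out = apply_formant_cascade(wave, 10_700.0, 13_200.0, bw=200.0)
        freqs, spec = self._spectrum(out)
        peak = freqs[np.argmax(spec)]
        near = min(abs(math.log2(peak / 10_700)), abs(math.log2(peak / 13_200)))
        assert near < 0.05  # within 0.05 octave of one of the formants

    def test_bypass_returns_input_unchanged(self):
        wave = synth_click_train(151.0, 0.05, 97_656.0)
        out = apply_formant_cascade(wave, 10_000.0, 15_000.0, bw=np.inf)
        assert np.allclose(out.samples, wave.samples, atol=1e-12)

    def test_coincident_formants_single_prominence(self):
        wave = synth_click_train(151.0, 0.2, 97_656.0)
        out = apply_formant_cascade(wave, 15_000.0, 15_000.0, bw=200.0)
        freqs, spec = self._spectrum(out)
        assert abs(math.log2(freqs[np.argmax(spec)] / 15_000)) < 0.05

    def test_unstable_configuration_rejected(self):
        wave = synth_click_train(151.0, 0.05, 97_656.0)
        with pytest.raises(ValueError):
            apply_formant_cascade(wave, 10_000.0, 15_000.0, bw=-100.0)

    @pytest.mark.parametrize("zeros", [False, True])
    def test_resonance_monotone_over_one_octave(self, zeros):
        # the filter's own response at its center exceeds one octave away
        from scipy.signal import freqz

        from frfres.stimuli import _resonator_coeffs

        fs, fc = 97_656.0, 14_000.0
        b, a = _resonator_coeffs(fc, 200.0, fs, zeros)
        w = 2 * np.pi * np.array([fc / 2, fc, fc * 2]) / fs
        _, h = freqz(b, a, worN=w, fs=2 * np.pi)
        assert abs(h[1]) > abs(h[0]) and abs(h[1]) > abs(h[2])


class TestFinalize:
    def test_rms_calibration(self):
        wave = synth_click_train(151.0, 0.2, 97_656.0)
        wave = apply_formant_cascade(wave, 10_700.0, 13_200.0)
        out = finalize_stimulus(wave, ramp_ms=5.0, rms_target=0.05)
        assert abs(out.rms() - 0.05) / 0.05 < 1e-3

    def test_ramp_endpoints_on_constant_wave(self):
        from frfres.stimuli import StimulusWaveform

        fs = 10_000.0
        wave = StimulusWaveform(samples=np.ones(2000), fs=fs, f0=0.0, duration=0.2)
        n_ramp = round(0.005 * fs)
        # ramp only: recover the pre-scaling shape by undoing the RMS gain
        out = finalize_stimulus(wave, ramp_ms=5.0, rms_target=1.0)
        shape = out.samples / out.samples[len(out.samples) // 2]
        assert shape[0] == 0.0
        assert shape[n_ramp] == pytest.approx(1.0)
        assert np.all(np.diff(shape[: n_ramp + 1]) >= 0)  # monotone flank

    def test_equal_rms_across_formant_pairs(self):
        a = synth_stimulus(10_000.0, 12_311.0)
        b = synth_stimulus(14_142.0, 18_661.0)
        assert abs(a.rms() - b.rms()) / a.rms() < 1e-3

    def test_all_zero_rejected(self):
        from frfres.stimuli import StimulusWaveform

        wave = StimulusWaveform(samples=np.zeros(2000), fs=10_000.0, f0=0.0)
        with pytest.raises(ValueError):
            finalize_stimulus(wave, 5.0, 0.05)


class TestWriteBank:
    def test_manifest_and_roundtrip(self, tmp_path):
        g = make_formant_grid(10_000, 20_000, 0.5)  # 3 centers, 3 pairs: fast
        manifest = write_bank(g, tmp_path, duration=0.05)
        assert len(manifest) == 3
        assert list(manifest.columns) == [
            "stim_id", "f1_hz", "f2_hz", "f1_oct", "f2_oct", "file",
        ]
        fs, data = wavfile.read(tmp_path / manifest.file.iloc[0])
        assert fs == 97_656
        ref = synth_stimulus(
            manifest.f1_hz.iloc[0], manifest.f2_hz.iloc[0], duration=0.05
        )
        assert np.allclose(data, ref.samples, atol=1e-6)

    def test_default_grid_has_55_rows(self, grid, tmp_path):
        manifest = write_bank(grid, tmp_path, duration=0.01, ramp_ms=1.0)
        assert len(manifest) == 55
        assert (tmp_path / "stimuli.csv").exists()
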