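# frfres

How finely does the firing rate of auditory-cortex neurons resolve the
formant frequencies of vowel-like sounds?  `frfres` implements a complete
analysis pipeline for answering that question with two-formant
pulse-resonance stimuli: stimulus synthesis, threshold-crossing spike
detection, formant-receptive-field (FRF) construction, and a
cross-validated Gaussian kernel-smoothing estimator of the resolution
bandwidth σ, together with an LN-Poisson synthetic-data generator so that
every stage can be validated without animal recordings.

It is aimed at sensory electrophysiologists analyzing multi-unit
responses to parametric stimulus grids, and at methodologists interested
in cross-validated bandwidth selection as a measure of neural stimulus
resolution.

## The method

Stimuli are pulse-resonance sounds: a click train at fundamental f₀
(151 Hz) filtered by a cascade of two second-order resonators with center
frequencies F1 < F2 drawn from 11 log-spaced positions between 10 and
20 kHz (0.1-octave steps), giving 55 stimulus pairs.  The response of a
recording site to each stimulus is summarized by the onset spike rate
(20–100 ms after onset) minus the background rate (the median baseline
rate at 400–480 ms across all trials); averaged over repeats this gives
the FRF over the triangular (F1, F2) grid.

A site's observed response ř(S) is modeled as a Poisson draw around a
deterministic tuning function r(S).  Smoothing the FRF with a 2-D
Gaussian kernel

    w(S, S′) = exp(−|S − S′|² / 2σ²)    (distances in octaves)

pools neighboring stimuli and suppresses trial noise, but blurs genuine
tuning if σ is too wide.  The optimal σ is found by cross-validation: the
repeats of each stimulus are repeatedly split into 10 training and 5 test
repeats, the training FRF is smoothed at each σ ∈ {0.02, 0.04, …, 5.12}
octaves, and the mean squared difference to the test FRF is bootstrapped
over 500 random splits.  A cubic spline through (log₂ σ, mean MSE) is
minimized to give the best σ — simultaneously the optimal smoothing
bandwidth and an operational estimate of the site's formant resolution.
Because the 55 valid cells form a triangle, smoothing uses normalized
(masked) convolution: weights are renormalized over valid cells per
output cell, so constant fields are preserved exactly and the large-σ
limit is exactly the grand mean.

Sites enter the analysis only if a Kruskal-Wallis test across four
stimulus "quadrants" plus baseline shows significant stimulus modulation
(α = 0.05).  Population utilities summarize per-site σ distributions and
compare them across electrode penetrations and cortical depths.

## Worked example

```python
import numpy as np
from frfres import (make_ground_truth, simulate_trials, inclusion_test,
                    build_frf, estimate_resolution, octaves_to_percent)

# a synthetic site: tuning = white noise smoothed to 0.2-octave scale,
# 50 Hz evoked amplitude over a 12.5 Hz background, 15 repeats x 55 stimuli
gt = make_ground_truth("smoothed_noise", {"w": 0.2, "amplitude": 50.0}, seed=42)
table = simulate_trials(gt, n_repeats=15, rng=np.random.default_rng(42))

p, included = inclusion_test(table)       # p = 3.94e-183, included = True
frf = build_frf(table)                    # background 12.50 Hz,
                                          # FRF spans 12.5 to 72.5 Hz
curve = estimate_resolution(table, n_boot=500, rng=np.random.default_rng(0))
print(curve.best_sigma)                   # 0.092 octaves
print(octaves_to_percent(curve.best_sigma))  # 6.5 (% formant shift)
```

The bootstrap MSE curve behind that estimate:

```
sigma  0.02 oct  MSE  187.4 +/- 1.7 Hz^2
sigma  0.04 oct  MSE  171.5 +/- 1.5 Hz^2
sigma  0.08 oct  MSE  139.7 +/- 1.3 Hz^2   <- minimum region
sigma  0.16 oct  MSE  161.2 +/- 1.4 Hz^2
sigma  0.32 oct  MSE  233.3 +/- 1.6 Hz^2
...
sigma  5.12 oct  MSE  311.0 +/- 1.9 Hz^2
```

The spline-interpolated minimum at σ ≈ 0.09 octaves says this site's
firing distinguishes formants about 0.09 octaves (≈ 6.5% in frequency)
apart — under-smoothing (σ = 0.02) keeps sampling noise, over-smoothing
(σ ≥ 0.32) erases real tuning, and both predict held-out data worse.

## Command line

```sh
frfres synth-stimuli --out bank/              # 55 WAVs + manifest CSV
frfres simulate --seed 1 --out run/           # synthetic population
frfres detect --traces traces.csv --fs 24000 --out spikes.csv
frfres build-frf --trials trials.csv --manifest stimuli.csv --out frf.csv
frfres include --trials trials.csv --manifest stimuli.csv
frfres estimate-resolution --trials trials.csv --manifest stimuli.csv \
       --n-boot 500 --train 10 --test 5 --seed 1
frfres run-all --seed 1 --out run/            # everything, one command
```

Real data enter as a trial-counts CSV
(`stim_id,repeat_idx,onset_count,baseline_count`) or a spike-times CSV
(`trial_id,stim_id,spike_time_s`) plus the stimulus manifest.

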