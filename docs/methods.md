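# Methods

## Model and procedure

A recording site's response to a two-formant stimulus S = (F1, F2) is
treated as a linear-nonlinear-Poisson (LN-P) observation: a deterministic
tuning function r(S) (Hz, evoked rate above background) corrupted by
Poisson trial-to-trial variability.  Per trial two counts are taken in
half-open windows relative to stimulus onset — onset [20, 100) ms and
baseline [400, 480) ms — and rates are counts divided by the 0.08 s
window.  The formant receptive field (FRF) is the per-stimulus mean onset
rate minus the background rate, where background is the **median
per-trial baseline rate pooled over all stimuli and repeats** (median of
the 825 per-trial rates for 55 × 15 trials, not a median of per-stimulus
means; the pooled median is robust to occasional spontaneous bursts).
Because subtraction is affine, subtracting per trial or after averaging
gives identical means; the implementation subtracts after averaging.

The resolution estimate is the bandwidth σ (octaves) of the 2-D Gaussian
kernel that minimizes cross-validated prediction error:

1. Per stimulus, repeats are split without replacement into disjoint
   train (10) and test (5) subsets; each subset is reduced to an FRF with
   its **own** background median, so train and test stay independent.
2. The train FRF is smoothed at each σ on the geometric grid
   {0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.28, 2.56, 5.12} octaves.
3. The prediction error is the mean squared difference (Hz²) over the 55
   valid cells between the smoothed train FRF and the raw test FRF.
4. Steps 1–3 are repeated for 500 bootstrap iterations per σ; a fresh
   split is drawn per (σ, iteration) by default (a `share_splits` flag
   reuses one split pool across σ for variance reduction).
5. A natural cubic spline through (log₂ σ, mean MSE) is evaluated on a
   dense grid (1000 points, augmented with the sample knots so the
   interpolated minimum can never exceed a sampled mean); the argmin is
   the best σ, ties resolved to the smallest σ.

The reported SEM per σ is SD(errors)/√n_boot and is for display only;
the minimum uses means.

## Smoothing on a masked grid

Valid stimuli occupy the upper triangle (F1 < F2) of the 11×11 grid.
Smoothing uses normalized (masked) convolution,

    out(S) = Σ_{S′ valid} w(|S−S′|) f(S′) / Σ_{S′ valid} w(|S−S′|),

with Euclidean distances in (log₂ F1, log₂ F2) octave coordinates and no
kernel truncation (the grid spans one octave; the kernel is evaluated
over all 55×55 cell pairs).  This is the only masked scheme that
preserves constant fields exactly at every σ and whose large-σ limit is
exactly the kernel-weighted grand mean; zero-padding would leak the mask
shape into the estimate.  The inner loop of the estimator batches
bootstrap iterations (permutations as argsorted uniforms, smoothing as a
55×55 matrix product) but is algebraically the split → build-FRF →
smooth → MSE composition, which a test verifies against the explicit
op-by-op path.

## Inclusion criterion

The stimulus plane is partitioned by precedence with strict inequalities:
quadrant 1 if F2 < 13.2 kHz, else 2 if F1 > 13.2 kHz, else 3 if
F1 + F2 > 26.4 kHz, else 4.  (As printed, the quadrant-2 predicate
implies the quadrant-3 one, so precedence is required; this order
reproduces the intended bottom-left / top-right / top-left / central
geometry, and boundary equalities fall through.)  A Kruskal-Wallis test
(tie-corrected) compares onset counts pooled by quadrant — four groups —
against the baseline counts of all trials as a fifth group; the site is
included when p < 0.05.  Counts rather than rates enter the test; the
windows are equal length, so the ranks are identical either way.  No
multiple-testing correction is applied across sites.  Type-I calibration
on null sites is part of the acceptance suite (measured ≈ 4–5%).

## Stimulus synthesis

Click trains (unit impulses at cumulative-rounded multiples of fs/f₀,
f₀ = 151 Hz, fs = 97 656 Hz) pass through two second-order resonators in
series.  Each resonator is all-pole with pole radius exp(−π·BW/fs) and
unity gain at its center; BW defaults to 200 Hz and a matched-zeros
variant (zeros at DC and Nyquist) is available, since the classical
vowel-synthesis literature uses both.  Raised-cosine (cos²) 5 ms ramps
are applied before RMS calibration; all 55 stimuli are scaled to a common
dimensionless RMS target (0.05).  Absolute sound level (dB SPL) is a
hardware property and is recorded in the bank metadata only.

## Spike detection

Traces are bandpassed 200–2000 Hz with a 4th-order Butterworth applied
forward-backward (zero phase, so spike times are unshifted), and spikes
are strict local minima below −3.5 sample SDs of the filtered trace
(per-trace threshold; a MAD-based robust SD is available but off by
default), with a 1 ms dead time and plateau ties resolved to the earliest
sample.  On pure Gaussian noise the false-positive rate matches the
analytic level-crossing (Rice) rate computed from the squared filter
response within ±30%, which the tests check.

## Synthetic data generator

Ground-truth kinds: `flat` (constant evoked rate; 0 Hz gives the null
site), `bump` (Gaussian hill, default width 0.15 oct), `ridge` (elevated
where log₂(F2/F1) ≤ half-width — the diagonal motif of sites preferring
closely spaced formants), `gradient` (linear ramp in F1+F2), and
`smoothed_noise(w)` (seeded white noise over the 55 cells, masked-
smoothed at width w, affinely mapped to [background, background +
amplitude]) — the knob for recovery studies, since w sets the true
spatial scale of the tuning.

Defaults, chosen once as realistic study conditions: 15 repeats per
stimulus; background 12.5 Hz (one expected spike per 80 ms baseline
window, typical sparse late-window activity); evoked amplitude 50 Hz
(onset responses a few times background).  Onset counts are drawn from
the summed evoked + background process; within-window spike timing is
not modeled for trial tables (it matters only for the voltage-trace
fixtures, which superpose biphasic negative-dominant templates on
band-limited Gaussian noise with amplitudes in noise-SD units).

What the generator does **not** emulate: adaptation and bursting,
noise correlations across sites, non-Poisson dispersion, latency
structure within the onset window, and any dependence of background on
the stimulus.  Passing recovery tests therefore demonstrates estimator
correctness under Poisson assumptions, not robustness to every real
cortical noise regime.

## Numerical choices and degenerate inputs

- Spline fit in log₂ σ (the sample grid is geometric); natural boundary
  conditions; argmin ties → smallest σ.
- An all-zero trial table (or an exactly flat MSE curve) returns the
  widest σ with a `flat` flag rather than an arbitrary interior argmin.
- Ragged repeat counts (15–20) are allowed; CV requires at least
  n_train + n_test repeats per stimulus and subsamples the surplus.
- One top-level seed fans out to named `SeedSequence` substreams per
  site, so any site is reproducible in isolation; identical (config,
  seed) runs produce byte-identical results CSVs.

## Known limitations and an honest negative result

For **flat (null) sites**, the expectation that cross-validation should
essentially always select a very wide kernel holds only partially.
Conditional on one finite dataset, train and test splits both estimate
the same pooled empirical FRF, whose per-stimulus Poisson deviations
(variance ∼ λ/15) act as shared structure; the CV curve then has a
genuine shallow minimum at intermediate σ in a sizable minority of
seeds (measured: best σ ≥ 0.64 oct in ~60% of runs at the default
conditions, rising with repeat count and rate but not to ~90%; the dips
are ~1–2 Hz² against a bootstrap SEM of ~0.3 at 500 iterations, i.e.
real, not Monte-Carlo noise).  Practically: a moderate best σ at a
weakly modulated site should be read together with the depth of its MSE
minimum, not as certain evidence of genuine mid-scale tuning.

Problem sizes in the test and acceptance suites — 20 sites per
smoothness level, 100 bootstrap iterations, 50 noise-floor runs, 1000
inclusion-calibration simulations — were chosen as the package's own
statistical design points: large enough that medians and rates are
stable at the asserted tolerances, small enough to keep the suites quick
on a single CPU.
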