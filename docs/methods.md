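# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the known limitations of `seqrec`.

## Synthetic data model

**Sensor epochs.** One synthetic participant is 80 trials (40 per
condition) of 3.5 s at 150 Hz (t = −0.1 … 3.4 s) over 102 sites × 3
channels (two planar gradiometers + one magnetometer per site), the sites
flattened onto a 10 × 11 grid with the four corner pairs empty. Both
conditions receive an N100-like Gaussian transient (σ = 35 ms, latency
100 ms) after each of the five tone onsets (0, 250, 500, 750, 1,000 ms) over
two temporal 3 × 3 site patches; magnetometer gains flip sign across the
helmet midline as a crude dipolar field. The "memorized" condition
additionally receives a sustained difference waveform — a Tukey
(tapered-cosine, taper 0.25) window over `effect_window` on
`effect_sites` — so the injected effect is near-constant across its window
rather than peaked; this is what "sustained difference" means here and it is
what the cluster-overlap recovery checks measure against. Sensor noise is
Gaussian (`noise_sd`, default 30 field units against a default effect
amplitude of 25) optionally mixed with a 1/f-shaped component (fraction 0.3,
slope 1 by default). With `effect_amplitude = 0` the two conditions are
exchangeable by construction, which is the basis of every null-calibration
check. Reaction times are lognormal (median 1,870 ms, σ = 0.15 on the log
scale, matching reported means near 1.9 s) and correctness is Bernoulli
(p = 0.8), so the correct-trial and 20-fastest-trial selection rules are
exercised. Defaults were fixed once so that the demo pipeline reaches
significance at cohort size 8–20; they are synthetic choices, not measured
quantities.

**Parcel time courses.** 90 AAL-style parcels. Hub parcels carry a
phase-locked band-limited oscillation whose amplitude is modulated by
`(1 − r) + r·m(t)` with a common slow modulator `m` and mixing weight
`r = shared_envelope_r`. The carrier is constant-envelope (cosine of the
analytic phase of band-limited noise): with a raw noise carrier the
carrier's own Rayleigh-like envelope fluctuations dominate and hub–hub
envelope correlations plateau near 0.3 regardless of `r`; the
constant-envelope construction puts the analysis-band envelope under the
modulator's control, so `r` behaves as an effective sharing dial (r = 0 →
independent hubs). Non-hub parcels are independent Gaussian noise. The
baseline is pseudo-trials cut at random onsets from a continuous resting
record of pure noise.

**What the generator does not emulate.** No forward model or realistic
field topographies, no source leakage between parcels (the orthogonalization
hook is a no-op), no artifacts (blinks, cardiac), no 1/f structure in the
parcel noise, no learning or fatigue across trials. Passing recovery tests
therefore demonstrates the statistics, not robustness to real-data
confounds.

## Melodic information content

A single-viewpoint (pitch) n-gram model with additive smoothing (default
0.5 per event) and suffix back-off: a context shorter than the model order,
or unseen, falls back to its longest suffix with observed counts, then to
the unigram distribution. Model order defaults to 2 — five-tone excerpts
cannot support deeper contexts. `IC = −log2 p` exactly; entropy uses the
`0·log 0 = 0` convention. With smoothing 0, an unseen event yields `inf`
IC, reported explicitly rather than masked. This is deliberately not a
multiple-viewpoint long-/short-term model mixture; published mean IC/H
values that depend on large training corpora are out of reach by design and
are not targets.

## Decoding

Per timepoint: channel-wise z-scoring fitted on the training folds, then a
linear SVM (C = 1, squared-hinge, liblinear) — linear because activation
patterns require a linear readout. Cross-validation is stratified
leave-one-group-out with N = 8 groups, repeated (default 100×) with random
regrouping; accuracy, the four confusion series, and mean weights are
repetition-averaged. Decision values of exactly 0 go to the first label
(deterministic tie-break). Temporal generalization applies the classifier
and scaler fitted at the training timepoint to every test timepoint; with
the same seed its diagonal reproduces plain decoding bit-for-bit (shared
fold-draw and fit path). Haufe patterns are `Cov·w`, unit-normalized per
timepoint, computed on the z-scored data; an optional ridge
(`ridge · mean(diag) · I`) guards near-singular covariance. Group inference:
sign permutation of participant deviations from chance (one-sided,
empirical p with the +1 correction) and Benjamini–Hochberg FDR across
cells; α is the only configurable level, the FDR-adjusted q cut-off is a
data-dependent output.

## Cluster Monte-Carlo simulation

Paired two-sided t-tests per channel/timepoint across participants (the
t-map sign carries the directionality; separate positive and negative
binarizations at p < 0.01). Clusters are connected components under face
adjacency (4-neighbour in the layout plane, ±1 in time); 8-neighbour
spatial adjacency is available. The null permutes the values of occupied
layout cells uniformly across space and time jointly (a per-timeslice
variant is exposed); every permutation conserves the count of 1s.
Significance: cluster size strictly greater than the 99.9th percentile of
the 1,000 permutation maxima, plus the empirical
`p = (1 + #{null ≥ size}) / (1 + n_perms)` to avoid p = 0 artifacts.
Tone windows are half-open, [0, 250) ms, [250, 500) ms, …: a closed
millisecond-grid reading is not representable at 150 Hz sample spacing and
half-open bins assign every sample to exactly one window. Cluster-forming
thresholds are computed from the t distribution at the requested α rather
than hard-coded; printed single-valued thresholds from any particular study
cannot be matched simultaneously for all αs at one df and are not used.
The magnetometer follow-up reruns the full MCS restricted to the
gradiometer-significant window (magnetometer field signs are ambiguous, so
they are only tested where the combined gradiometers, which are
polarity-free after root-sum-square, established an effect); an empty
window returns an explicit no-follow-up result. The 1D variant for
behavior scans binarizes per-timepoint r/F tests at p < 0.05 and compares
run lengths of 1s against the maximum run under 1,000 random reorderings.

## Envelope connectivity and degree centrality

Band-pass is a zero-phase FFT spectral mask by default. Reason: on 3.5-s
mean trials a forward–backward IIR filter with a 0.1 Hz low edge leaves
startup transients spanning the whole record; these imprint a common
envelope shape on every channel and bias envelope correlations upward by as
much as +0.5 on fully independent signals. The spectral mask is
transient-free (measured bias < 0.03); a forward–backward Butterworth
(order 4) remains available as `filter='butter'`. The gamma band 32–75 Hz
sits exactly at Nyquist for 150 Hz data; the FFT mask includes the Nyquist
bin, the Butterworth option clips the upper edge to 0.99 × Nyquist.

SFC is the Pearson correlation between parcel envelopes of the
condition-pooled mean trial (20 fastest correct trials per condition for
task, all pseudo-trials for baseline), per band and participant; constant
envelopes yield 0 with a logged warning. Group level: one-way ANOVA across
bands on matrix-mean connectivity with Tukey HSD post-hoc (67 participants
× 5 bands gives dfs (4, 330)); edge-wise Wilcoxon signed-rank z
(normal approximation, tie-corrected, zero differences dropped, no
continuity correction — positive z = stronger in task).

Degree test: observed weighted degree per node (off-diagonal row sums of
B); 1,000 permutations shuffle the upper triangle and mirror, conserving
the edge-weight multiset; empirical p per node against the pooled permuted
degrees (node-wise pooling available). Significance defaults to the
occurrence-count rule — the node's degree is matched or exceeded fewer than
two times in the permutation distribution — with the per-band level
α/5 = 2.0e-4 reported alongside; a `rule='pvalue'` variant tests
p < α/5 directly. The count rule is the default because it is the more
conservative of the two and the one whose calibration on uniform-random
matrices approaches zero false positives; by exchangeability of the
observed assignment with its permutations, *any* such rule retains an
irreducible per-matrix flag probability of about 2/(n_perms + 1), so
calibration claims of literally zero false positives hold in expectation
only over small numbers of matrices.

A power note on hub recovery: the signed-rank z saturates at √(3n)/2 for n
participants, so a hub's maximum attainable degree advantage is (hubs − 1) ×
√(3n)/2 against a √89 noise floor. Recovering all 8 hubs among 90 parcels
therefore needs large cohorts (the recovery test uses 100 synthetic
participants) and the node-wise null; the pooled maximum-based threshold
scales with the same saturated z and cannot separate 8 hubs at any cohort
size.

## Problem sizes in tests and scripts

The test suite and the acceptance script run the full statistical machinery
at reduced problem sizes chosen a priori: decoding calibration uses 5–100
repetitions at 17–33 decimated timepoints (under the null, accuracy is
chance at every timepoint, so decimation changes only the averaging);
cluster calibration uses 400 replicate 10 × 10 × 50 maps; degree
calibration 200 replicate 90 × 90 matrices at the full 1,000 permutations.

## Reproducibility

Every generator and permutation test takes an explicit integer seed
(NumPy `default_rng`); the pipeline fans stage seeds out of one master seed
through fixed `SeedSequence` spawn keys, so adding a stage does not shift
the streams of existing stages. Outputs name the config hash and seed.
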