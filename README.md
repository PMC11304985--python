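# seqrec

Statistical machinery for MEG auditory sequence-recognition studies, as a
tested, reusable Python package. It targets the analysis style of old/new
melody-recognition experiments: a listener memorizes a musical piece, then
hears 1,250-ms five-tone excerpts and labels each as *memorized* or *novel*
while MEG is recorded. Everything runs on synthetic data with recorded
ground truth, so every stage can be validated by parameter recovery.

## What it implements

* **`seqrec.synth`** — generators for all inputs: two matched categories of
  five-tone melodies; 306-channel Elekta-like sensor epochs (80 trials,
  3.5 s at 150 Hz, 100 ms prestimulus) with an injectable spatiotemporal
  condition difference; 90-parcel (AAL-style) source time courses with
  shared-envelope hub structure; behavioral scores; pseudo-trial baselines
  cut from resting data.
* **`seqrec.melody_info`** — an n-gram model over pitches giving, per tone,
  the information content `IC_i = log2 1/p(e_i | e_{i-n+1}^{i-1})` (bits
  needed to encode the tone given its context) and the entropy
  `H = Σ_e p(e|ctx) · log2 1/p(e|ctx)` of the continuation distribution
  (0 for a certain continuation, `log2|A|` for a uniform one).
* **`seqrec.decode`** — per-timepoint linear-SVM decoding of the two
  conditions with stratified 8-group cross-validation repeated with random
  regroupings; confusion-series; temporal generalization (train at t, test
  at all t'); Haufe activation patterns (`A = Cov · w`); group-level
  sign-permutation tests against the 50% chance level with
  Benjamini–Hochberg FDR.
* **`seqrec.cluster`** — the Monte-Carlo cluster simulation (MCS):
  correct-trial condition averages, planar-gradiometer root-sum-square
  combination, paired t-maps across participants, binarization at p < 0.01
  split by t-sign onto a 2D layout, connected-cluster identification, and a
  cluster-size null from 1,000 element permutations of the binary matrix
  (99.9% maximum-size criterion); the two-step magnetometer follow-up;
  250-ms tone-window aggregation; behavior–neural scans (per-timepoint
  Pearson r or expertise-group ANOVA) corrected by a 1D MCS.
* **`seqrec.connectivity`** — static functional connectivity of evoked
  responses: five bands (0.1–2, 2–8, 8–12, 12–32, 32–75 Hz), Hilbert
  amplitude envelopes, pairwise Pearson SFC per participant for task and
  pseudo-trial baseline, band ANOVA with Tukey post-hoc, edge-wise Wilcoxon
  signed-rank z-matrix **B**, and the weighted-degree permutation test
  (1,000 shuffles of the upper triangle of **B**, α = 0.001 split across the
  five bands).
* **`seqrec.pipeline` / `seqrec` CLI** — one-command demo over a synthetic
  cohort with deterministic per-stage seeding and a report bundle
  (CSV tables, `stats.json`, markdown report).

## Worked example

```bash
python analysis/01_simulate.py
python analysis/03_decode.py
```

prints (seed 42, 8 synthetic participants, effect injected on 10 temporal
sites between 0.55 and 1.18 s):

```
participant 0: peak accuracy 0.779 at 0.75 s
participant 1: peak accuracy 0.934 at 0.65 s
...
group FDR-significant span: 0.65-1.07 s
TG block mean inside effect window: 0.798 (off-window 0.499)
```

The decoder finds the injected memorized-vs-novel difference where it was
planted: single-participant peak accuracies reach ~0.9 inside the effect
window, the group sign-permutation + FDR mask covers the window, and
temporal generalization shows the sustained (off-diagonal) code
(~0.80 inside the window block vs ~0.50 outside — chance). Running
`analysis/04_sensor_clusters.py` recovers the same effect as one significant
positive gradiometer cluster (window 0.57–1.15 s), and
`analysis/05_connectivity.py` flags the injected 2–8 Hz hub parcels
(Heschl's gyrus, superior temporal gyrus, Rolandic operculum, insula) by
degree centrality.

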