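# Methods

This note documents the models, estimators, defaults and numerical
choices behind `eegtopo`, and what the synthetic-data validation does
and does not establish.

## Signal model of the synthetic generator

A recording is a sum of three parts, per channel, scaled to ~20 µV RMS:

* **1/f background** — independent per channel, amplitude spectrum
  ∝ f^(−β/2) with β = 1 by default, matching the spectral shape of
  resting EEG.
* **Oscillators** — each oscillator is a narrowband Gaussian source
  (Gaussian spectral envelope centred on `freq`, s.d. `bandwidth`/2)
  shared by a set of channels. Channel *k* of the set receives
  `strength · shift(common, φ_k) + sqrt(1 − strength²) · private_k`,
  with per-channel phases φ spread evenly over [0, `phase_lag`]
  (frequency-domain rotation). The expected magnitude-squared coherence
  between two coupled channels at the centre frequency is `strength²`
  with phase equal to their lag difference, so imaginary coherence is
  monotone in `strength` and zero at `strength = 0`. Phase lags are
  restricted to (0, π): a constant rotation is a lag only for narrowband
  signals, and lags of exactly 0 or π carry no imaginary part.
* **Volume conduction** — an optional instantaneous real mixing matrix
  applied sample-wise. Because the mixing is real and instantaneous it
  inflates the real part of coherency but adds no imaginary part; this
  is the confound the estimator must reject, and the generator
  reproduces it exactly rather than approximately.

Default resting coupling places one oscillator per canonical band on a
plausible scalp region (posterior alpha at 10 Hz, frontal delta,
fronto-central theta/beta, temporal gamma) with strengths 0.15–0.4.

**Study designs.** `generate_study` builds a crossover design: per
subject, baseline oscillator strengths are jittered (multiplicative
Gaussian, s.d. 0.15) to create between-subject variance; pre and post
segments share the subject's parameters and differ only in noise
realization; sham post segments are therefore statistically identical to
pre. Active post segments additionally receive the **effect**: one extra
oscillator per module at the band centre. The default effect is four
distributed 4-channel modules at strength 0.6. Several small modules —
rather than one large clique — are used deliberately: a single clique
concentrates degrees, which raises the clustering of degree-preserving
nulls as fast as that of the graph itself and so moves γ and σ *down*
even as Cp rises; distributed modules add triangles without degree
concentration and move Cp, γ and σ together, the signature the analysis
is meant to detect. The human cohort's true resting coupling level is
unknown, so these effect sizes are chosen for testability of the chain,
not biological fidelity.

**Desk-scale profiles.** The full study conditions (19 channels, 500 Hz,
7-min segments, 26 subjects, four arms) are the generator defaults.
Simulation-heavy validation uses `reduced_design` /
`reduced_analysis_params`: 128 Hz sampling (Nyquist above the gamma
band), 24–60 s recordings, 2-s epochs with 2-Hz half-bandwidth
(7 tapers), and small null ensembles. These sizes keep replicate studies
cheap while preserving every structural property of the full analysis;
statistical power at reduced size is compensated by the deliberately
strong injected effect. One trade-off to know about: the 2-Hz multitaper
half-bandwidth of the desk-scale profile smears the injected alpha
oscillator's edges into neighboring theta/beta bins, so adjacent bands
can show weak secondary effects that are leakage, not false positives;
at the full-scale profile (0.5-Hz half-bandwidth) the leakage is
negligible.

## Preprocessing

Fixed stage order: bandpass → transient repair → bad-channel
interpolation → common-average reference → ICA artifact removal. Every
stage preserves channel count, labels, sampling rate and metadata.

* Bandpass: order-4 Butterworth, applied forward–backward (zero phase,
  so the effective order doubles); phase distortion would bias coherency
  phases, which the whole pipeline depends on. Note the chain is only
  *approximately* idempotent: re-filtering re-attenuates 1/f energy near
  the 1-Hz edge by a few percent RMS; the test suite allows 5%.
* Transient repair: spikes are |robust z| > 8 (median/MAD); flat runs
  are moving variance < 1e-3 µV² for ≥ 0.1 s. Flagged segments are
  replaced by the 50/50 mean of the equal-length preceding and
  subsequent windows (one-sided at recording boundaries, noted in the
  report).
* Bad channels: caller-supplied, or automatic when the mean |r| with
  montage neighbors falls below 0.4. Automatic detection refuses to act
  when it flags more than 25% of the montage (on data without shared
  sources the criterion is meaningless, and interpolating a quarter of
  the channels would fabricate data). Neighbors come from flattened
  10–20 positions on the unit disc with a 0.75 distance cutoff, equal
  interpolation weights.
* ICA: FastICA with a fixed seed. Components are removed when their
  source kurtosis z-score exceeds 5, or when their mixing weights
  concentrate on the frontal poles (> 2.5× the mean absolute weight)
  with > 50% of power below 3 Hz (eye-movement signature). On
  near-Gaussian sources FastICA essentially never reaches its tolerance
  (Gaussianity is the ICA degeneracy), while the learned rotation is
  still usable; the iteration cap is therefore recorded in the cleaning
  report rather than raised, unless `strict_convergence` is set.

## Connectivity estimation

10-s non-overlapping epochs (remainder dropped); DPSS tapers with the
2·NW−1 taper rule; cross-spectra averaged over tapers and epochs. The
coherency denominator is sqrt(Sxx·Syy) — the only normalization for
which the magnitude is bounded by 1 (Cauchy–Schwarz; the implementation
also guards the floating-point tail). Default half-bandwidth is 0.5 Hz
for 10-s epochs (NW = 5, 9 tapers). Edge weights are |Im coherency|:
absolute values make the weights thresholdable, and a `signed` flag
preserves the sign when needed. The zero-phase exclusion uses a 0.01-rad
tolerance. Band averaging is bin-wise |Im coherency| then mean, over
half-open intervals [low, high) so shared edges (4, 8, 13, 30 Hz) are
counted once. Zero-power bins yield a zero coherency and a log entry.

The estimator is biased upward for finite data: with K tapers and E
epochs the coherence noise floor scales like 1/√(KE). Validation
therefore compares coupled estimates against the empirical uncoupled
floor rather than against zero.

## Graph analysis

Thresholding keeps the round(s·n(n−1)/2) largest weights (round half
up); ties are broken by lexicographic channel-pair order so results are
reproducible. Graphs are binary: the normalized indices γ, λ, σ are
standard for binary graphs, and binarization makes them well defined
across the whole grid.

Disconnected graphs are handled rather than discarded: Lp averages over
reachable pairs only (the unreachable count is reported), Eg counts
unreachable pairs as zero efficiency, nodes with fewer than two
neighbors contribute zero to Cp and Eloc. γ/λ/σ use 100
degree-preserving double-edge-swap nulls by default (10 swaps per edge);
when a level's null ensemble has zero mean clustering (very sparse
graphs) the indices are recorded as NaN — missing, never fabricated. At
near-complete sparsity few legal swaps exist; the partially rewired null
is still exactly degree-preserving and a warning is emitted. Shortest
paths use an in-package BFS kernel (numba-compiled; the metric sweep
across 19 levels × 5 bands × nulls is the pipeline's hot path);
equivalence with brute-force enumeration and with networkx is asserted
in the test suite to 1e-12.

One reading note: λ is reported alongside γ even though some metric
lists collapse the two path-length symbols; σ = γ/λ requires it.

## Statistics

Normalized change (post − pre)/pre is undefined when the pre-value is 0
or either value is missing; such cells propagate as NaN. Paired
comparisons are dependent-samples two-sided t-tests across subjects with
pairwise deletion; cells with fewer than 3 complete pairs or degenerate
(constant, non-zero) differences are missing, and all-zero differences
give t = 0, p = 1 by definition. No correction is applied across the 19
sparsity levels, 5 bands or 7 metrics — the map reports raw p values,
and users should treat isolated flags accordingly (this is a deliberate
caveat, not an oversight). Side-matched comparisons only: left-active
vs. left-sham and right-active vs. right-sham; shams are never pooled
across sides.

**Calibration testing.** Under a zero-effect study, the flag rate at
p < 0.05 should be 5%. Two subtleties shape the validation test. First,
cells where every within-subject difference is exactly zero — at high
sparsity, any 19-node graph with a fixed edge count and diameter ≤ 2 has
*identical* Lp and Eg regardless of which edges are present — are
deterministic, not Bernoulli(α) draws, and are excluded from the rate.
Second, the ~600 cells within one replicate study are strongly
correlated (shared graphs across sparsity levels, overlapping metric
definitions), so the replicate study, not the cell, is the independent
unit: the acceptance band is the 99% binomial band around α with n =
number of replicate studies.

## Pipeline and reproducibility

Stage order is fixed; every stochastic stage (GTA nulls, ICA) derives
its seed from the master seed by CRC-32 hashing of the stage name and
recording identity, so subjects could be processed in any order or in
parallel without result drift. Identical configuration and seed
reproduce byte-identical output tables; the run manifest records a
configuration hash. EDF is the canonical interchange format (16-bit,
written by a self-contained writer, read via MNE; round-trips are exact
up to the format's quantization step); delimited text with a JSON
sidecar is the lossless alternative.

## What the synthetic validation does and does not show

Passing tests establish that the chain detects phase-lagged band-limited
coupling changes of the injected kind, rejects instantaneous mixing,
keeps its type-I error calibrated, and computes the graph quantities it
claims to compute. They do not establish biological claims: the
generator has no head model, no dipole geometry, no realistic artifact
waveforms, no non-stationarity or drowsiness drift, and its
between-subject variability is a simple strength jitter. Real-data
effect sizes, channel noise and electrode repositioning between sessions
are all outside the model, so quantitative power estimates here do not
transfer to human studies.
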