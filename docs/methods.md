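# Methods

## Signal model and the PAC estimation chain

All analysis operates on epoch-structured EEG (`trials × channels ×
samples`, microvolts) with 1-based class labels, per-trial session ids and
an attended/non-attended flag. Frequency content is always expressed
through the seven canonical bands δ [0.5, 4], θ [4, 8], α1 [8, 10],
α2 [10, 13], β1 [13, 20], β2 [20, 30], γ1 [30, 45] Hz.

Band filtering is a 3rd-order Butterworth bandpass applied forward and
backward (`sosfiltfilt`, odd reflect padding), giving zero effective phase
shift — a precondition for meaningful instantaneous phases. Note that a
narrow low-frequency band has a long transient: a δ filter settles over
roughly a second, so on a 1 s epoch a substantial fraction of every
filtered trace is transient. We deliberately do **not** trim samples
inside the estimators: trimming raises the clean coupled value but
shortens the effective record and widens the null by the same
time–bandwidth argument, with no net gain (verified in design
simulations). Consumers that need transient-free values should supply
longer records, as the comodulogram-recovery tests do (12 s).

The PAC chain per band pair (LF, HF): bandpass in LF and in HF; Hilbert
transform both; take the HF envelope `A_HF(t)`; re-filter the
(mean-removed) envelope inside the LF band; Hilbert transform again for
`φ_LF→HF(t)`. Estimators:

- `plv(φ1, φ2) = |mean e^{i(φ1−φ2)}|`. The textbook definition is
  sometimes written without the modulus; a complex "PLV" is not orderable,
  so the modulus is always taken.
- `iplv = |Im mean e^{i(φ1−φ2)}|`: only the imaginary part, so zero-lag
  phase consistency — what instantaneous volume conduction produces —
  contributes nothing. This makes iPLV blind to couplings whose phase lag
  is 0 or π; the synthetic generator therefore defaults to a quarter-cycle
  coupling lag.
- `mvl = |mean A_HF e^{iφ_LF}|` uses the **raw** HF envelope with the LF
  phase (Canolty's definition), not the re-filtered envelope; it scales
  with signal amplitude, unlike the phase-only estimators.

A comodulogram evaluates one estimator over every ordered pair of an
ordered, non-overlapping band list (21 pairs for the canonical seven);
each band is filtered once and only the envelope re-filtering is
per-pair. `pac_timeseries` computes the phase/envelope vectors once on the
full record — the LF band is unresolvable inside a 100 ms window, so
per-window filtering would be meaningless — then applies the estimator to
sliding windows `[k·step, k·step + window)`; length is
`floor((n − window)/step) + 1`, with an optional centred truncation to a
caller-specified `target_length`.

Band power is `SP = Σ_t x_band(t)²` and relative power
`RSP = SP_band / Σ_bands SP`; RSP sums to 1 by construction over the band
list used.

### Surrogate significance

An optional helper builds a circular time-shift null: the envelope
phase/amplitude series is rolled by ≥ 0.5 s (200 shifts by default) and
the estimator recomputed; the 95th percentile serves as a significance
threshold. Caveat: for *strictly periodic* coupling, shifts near a
multiple of the LF period realign the phases, inflating the threshold;
the null is intended for testing uncoupled signals (as the test suite
uses it), not for sharp inference on deterministic periodic ones.

## Spatial filtering

The LCMV beamformer `W = C⁻¹A (AᵀC⁻¹A)⁻¹` passes the template subspace
`A` with unit gain (`WᵀA = I`) while minimising output variance under the
pooled covariance `C`. The template is the sample-wise mean of a class's
training segments; its leading left singular vector is the default rank-1
spatial basis (a full-rank variant is available). The covariance is shrunk
as `(1−γ)C + γ(trace C/m)I` with γ = 0.05 by default — enough to make
rank-deficient training sets invertible without biasing well-conditioned
ones. The beamformer is used strictly as a denoiser: downstream PAC
consumes the dominant projected component; it never decodes.

## Symbolization and runs-test classification

Sliding windows of a PAC trajectory are quantised by a neural-gas
codebook: rank-based competitive learning where every prototype moves
towards each random sample with step `ε(t)·exp(−rank/λ(t))`, both
schedules decaying exponentially (`ε`: 0.5 → 0.005, `λ`: k/2 → 0.01,
`t_max = 50·n` by default), deterministic given the seed. Unlike k-means,
the rank-based update makes all prototypes move early on, avoiding dead
units on these strongly unimodal window distributions.

Similarity between a test trial's windows and a class's prototypes is the
two-sample Wald–Wolfowitz statistic: pool the two samples, count runs `R`
of sample-origin labels (after sorting, for scalars; via mixed-origin
edges of the Euclidean minimum spanning tree — Friedman–Rafsky — for
vectors, where `R = 1 + #mixed edges`), and standardise with
`μ = 2n₁n₂/(n₁+n₂) + 1` and the classical variance. Samples from the same
distribution intermix (many runs, high z), so classification picks the
class with the largest z; ties go to the lowest class id. The multivariate
mode is the default for window vectors. Because the FR test loses power
under extreme sample-size imbalance, the pipeline decimates test windows
evenly to 64 before testing against the 32-prototype class codebooks.

## Selection, gating and classification (flashing-image design)

The feature table holds one column per (band pair, channel) PAC value
plus per-channel α1 relative power. Unsupervised multi-cluster feature
selection builds a symmetric k-NN trial graph with heat-kernel weights
(width = median pairwise distance), takes the `n_clusters` smallest
nontrivial eigenvectors of the normalised Laplacian and regresses each on
the features by least-angle regression (≤ 20 nonzero coefficients),
scoring features by their maximum |standardised coefficient|. The graph
uses features as given (standardise first if scales are incomparable);
coefficients are standardised internally so scores are comparable. Exactly
duplicated columns are collinear — the L1 path keeps one arbitrarily — so
duplicates share the maximum score within their group, making the
documented lowest-index tie rule honest.

The attention gate is a k-NN majority vote (k = 5, odd by contract) on α1
relative power; attended trials show elevated α1 power (attended
0.09 ± 0.02 vs non-attended 0.06 ± 0.01 relative power — the calibration
the generator reproduces). The multi-class stage is a linear one-vs-rest
SVM (C = 1) with train-fold-only standardisation; prediction aligns
feature columns by name. Cross-validation schemes: session holdout (train
sessions {1,2,3}, test {4}), cross-day transfer (train {3,4}, test {1,2})
and seeded stratified k-fold. Gated accuracy is scored on trials that are
both truly attended and gate-accepted.

## Performance measures

Wolpaw bits per selection and ITR as in the README. Below-chance
accuracies (P < 1/N) are clipped to 0 bits with a warning — the raw
expression rebounds upward below chance, which has no operational
meaning. Selection time is the decision window plus a design-specific
overhead: 0.3 s stimulus for the 6-class flashing-image design, 0.5 s
gaze switch for the 32-target matrix, 5 s for the SSVEP layout. The
decision-window sweep runs 32 → 248 samples in steps of 12 with 256
appended. The decoding search is greedy over channels, exhaustive over
band pairs and ascending over trajectory lengths, stopping at absolute
accuracy 1.0 or a plateau (no gain > 0.005 over 25 length increments).

## The synthetic generator

A coupled trace is

```
x(t) = a_L cos(2π f_L t)
     + a_H [(1−m) + m(1 + cos(2π f_L t + offset))/2] cos(2π f_H t)
     + σ · pink(t)
```

with modulation depth `m ∈ [0,1]`, coupling lag `offset` (default π/2 —
iPLV is blind to zero-lag coupling) and 1/f pink noise with seeded
spectrum phases, σ relative to unit oscillation amplitude. Three dataset
profiles emulate the studied designs on an 8-channel layout whose first
six channels (PZ, OZ, P3, P4, P7, P8) carry the coupling:

- **cvep6** — 6 classes, 1 s at 512 Hz, noise σ = 0.15. Every
  parieto-occipital channel carries a class-invariant δ→θ coupling (the
  headline physiological signature) plus δ-phase coupling onto β1, β2 and
  γ1 carriers whose lags encode the class as a 3-bit code over {0, π/2}
  — one codeword per flashed image, mimicking image-specific response
  latencies. This coding is a deliberate design choice: at 1 s the
  δ-band's time–bandwidth product caps any single δ-pair statistic's
  precision (the uncoupled null is ≈ 0.3 ± 0.2), so no scalar δ→θ level
  code can separate six classes; binary lag codes over three carriers are
  linearly separable with ≈ 3σ per bit per channel. The attended/
  non-attended flag is Bernoulli(0.5); each trial's α1 relative power is
  calibrated by adding a Tukey-tapered 9 Hz burst (tapering keeps the
  tone's energy out of the δ band; an untapered tone leaks ~44 % of its
  filter-bank power into δ through edge transients and destroys the δ
  phase). The tone scale is solved exactly per trial: filtering is
  linear, so each band's power in `x + s·tone` is quadratic in `s` with
  coefficients from the pre-filtered quadrature tone pair. Per-trial
  targets are drawn from the attended/non-attended Gaussians
  (0.09 ± 0.02 / 0.06 ± 0.01).
- **cvep32** — 32 classes, 5.25 s at 250 Hz (1313 samples, round-half-up),
  noise σ = 0.25. All six analysis channels couple δ→θ at depth 0.9 with
  a class-specific lag `2π·2(c−1)/63` — targets lagged by two frames of
  the length-63 m-sequence. iPLV reads the lag out as a `|sin(offset)|`
  level ladder, which is what makes a magnitude estimator sensitive to
  the lag code at all.
- **ssvep5** — 5 classes, 5 s at 250 Hz; each class adds a
  stimulus-locked flicker sinusoid at 6.66/7.50/8.57/10.00/12.00 Hz plus
  the δ→θ coupling.

m-sequences come from a degree-6 LFSR (default polynomial x⁶ + x + 1);
the period must verify as 63 or the taps are rejected, and lagged
variants are cyclic shifts by two frames per class.

What the generator does **not** emulate: volume conduction and realistic
sensor covariance, artifacts (blinks, muscle), non-stationary background
rhythms, inter-subject variability, or any true evoked-response waveform.
Passing end-to-end tests therefore shows the pipeline recovers the coupling
structure it is designed for at realistic noise levels — not that real
recordings carry that structure.

## Problem sizes in the test suite

The suite exercises the six-class pipeline at 20 trials/class (120 trials,
session holdout, 30 of 126 features selected), the matrix pipeline at 8
classes × 12 trials under five-fold CV (PAC window 25 samples / step 4;
symbolization window 25 / step 5; 32 prototypes/class; test windows
decimated to 64), comodulogram recovery on 12 s records over 20 seeds,
and the runs-test calibration at n = 100 over 2000 draws. These sizes give
stable statistics while keeping the full suite to a few minutes on one
core.

## Known limitations

- Phase estimates on records shorter than a few LF cycles are transient-
  dominated; single-trial δ-pair statistics at 1 s are intrinsically
  noisy, which is a physics constraint, not an implementation one.
- iPLV cannot see couplings at lag 0 or π; PLV and MVL cannot see lag at
  all (they are lag-invariant), so lag-coded designs are decodable by
  iPLV only.
- The circular-shift surrogate null is conservative-to-invalid for
  strictly periodic coupling (see above).
- The LCMV template basis defaults to rank 1; sources with genuinely
  higher-rank spatio-temporal structure need `rank > 1`.
- EDF reading requires the optional `mne` dependency and treats the file
  as one continuous record to be epoched downstream.
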