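# Methods

This note documents the models, the numerical choices, and the design
decisions behind `ecgseize`, including what the synthetic cohort does and
does not establish about real wearable data.

## Signal model and preprocessing

Input is single-lead ECG sampled at 256 Hz in millivolt.  Preprocessing
is a zero-phase (forward–backward) order-4 Butterworth band-pass at
0.5–40 Hz followed by decimation to 8 Hz.  Zero-phase filtering was
chosen because causal filtering would shift the waveform relative to the
seizure annotations; the cost is a doubled effective order (the measured
gain is the squared magnitude response, which the tests verify against
the analytic Butterworth curve).  Decimation uses a polyphase anti-alias
filter: although the band-pass nominally passes up to 40 Hz, the 8 Hz
output can only carry content below 4 Hz, so the detectors operate on the
envelope and rhythm of the ECG, not on QRS morphology.  Output length
follows the floor convention `⌊N·8/256⌋`; boundary samples are dropped,
never padded.  Series already at a rate too low to support the 40 Hz
cutoff are rejected rather than silently re-filtered, which makes the
preprocessing effectively idempotent-by-refusal.

Quality control excludes recordings without a resolvable ECG channel and
recordings whose rail fraction is at least 10% ("at least" means the
comparison is `>=`).  Saturation rails are auto-detected as the signal
extrema when at least 0.5% of samples sit exactly there (a plateau
heuristic — isolated extrema of a continuous signal never qualify); the
rails can be supplied explicitly.  The saturation fraction is computed on
the raw signal, before filtering, since exclusion is a dataset-level
decision.

## Matrix-profile detector

For subsequence length `m` (default 80 samples = 10 s at 8 Hz, several
cardiac envelope cycles), the matrix profile holds, at each start index,
the z-normalized Euclidean distance to the nearest neighbor outside a
trivial-match exclusion zone of `⌈m/2⌉`.  The implementation computes
exact distances with blocked matrix products (no approximation); the test
suite checks elementwise agreement with an independent all-pairs
computation at 1e-6.  Zero-variance subsequences cannot be z-normalized;
they are mean-centered with unit fallback scale and their profile value
is forced to 0, so flat rail artifacts never surface as discords.

Candidate selection applies a global per-recording percentile threshold
(default 0.98) and a greedy overlap filter in descending score order
(ties to the earlier index).  The overlap limit defaults to 0.9·m: the
filter only removes near-duplicates, because the subsequent min-run
clustering needs several nearby anomalies to confirm an event — an
aggressive overlap filter (e.g. 0.5·m) would space survivors `m/2`
samples apart, farther than any plausible "short gap", and the two stages
would annihilate each other.  Min-run clustering joins anomalies whose
index gaps are at most `max_gap` seconds (default 2 s), drops runs
shorter than `min_n` (default 2), and reports each surviving run at the
nearest integer to its mean index.

## Multi-length discord detector

Discord profiles are computed exactly for each length of a grid (default
{24, 48, 80, 120} samples, i.e. 3–15 s at 8 Hz) and divided by `√m` so
scores are comparable across lengths (the z-normalized distance scale
grows with `√m`).  The speed-oriented pruning of the original multi-length
algorithm is deliberately omitted: at desk scale exact per-length
computation is affordable and directly oracle-testable.  Selection runs
in three stages — global percentile over all (length, index) cells,
per-length top-k, and a greedy overlap constraint rejecting candidates
that overlap an accepted interval by more than 25% of the *shorter*
interval (the stricter, deterministic reading of "more than 25%
overlap").  Ties break toward higher score, then shorter length, then
earlier index.  The percentile is computed within one recording; pooling
across recordings is a caller-side choice.

## Temporal clustering and gap selection

All detectors share single-pass gap clustering: a sorted anomaly joins
the current cluster iff its gap to the last member is ≤ Δt, and each
cluster is represented by its temporal medoid (minimal mean absolute
time distance, ties to the earliest member).  Candidate Δt values
(default grid 2–900 s) are compared on training recordings with

    score = 0.6·FP_reduction(%) + 0.3·anomaly_reduction(%) − 2.0·sensitivity_loss(%)

where each term is a percentage of the pre-clustering baseline and a term
with zero baseline is defined as 0 (no reduction is possible).
Sensitivity loss is likewise measured relative to baseline sensitivity;
since medoid representation can only lose coverage, the term is
nonnegative.  The Δt with the highest mean score across training
recordings wins, ties to the smaller Δt, and the choice never sees test
events — test data simply is not an argument of the selection function.

## Tokenizer and masked-token prior

The third detector is a deliberately tiny two-stage model that preserves
the tokenize → prior → masked-likelihood mechanism at a scale that trains
in seconds on one CPU.

*Stage 1 (tokenizer).*  The 8 Hz series is mapped to a log-magnitude STFT
with `n_fft = 16`, hop 8, height `H = ⌊n_fft/2⌋ + 1 = 9`.  Each
(bin, frame) cell is encoded from its edge-padded 3×3 spectrogram patch
by a two-layer tanh MLP into a D=8 latent, quantized to the nearest of
K=16 codebook prototypes, and decoded back to the cell magnitude by a
mirror MLP.  Training minimizes reconstruction error plus a commitment
term (β=0.25) with a straight-through gradient; the codebook follows
exponential-moving-average k-means (decay 0.99) seeded from actual
encodings of the training data.  A per-cell MLP stands where a larger
system would use strided convolutions: at this grid size the 3×3 receptive
field carries the same local context at a fraction of the machinery.
Tokens are stored 0-based internally.

*Stage 2 (prior).*  A bidirectional transformer (token + learned position
embeddings, two residual blocks of 2-head self-attention and a tanh MLP,
dimension 32) predicts tokens replaced by a [MASK] symbol, minimizing the
masked-token negative log-likelihood at mask ratio 0.3.  The network is
implemented in numpy with hand-derived gradients (a finite-difference
check guards them) and Adam.  There is no layer normalization: at this
depth and width, scaled initialization plus Adam trains stably, and
omitting it keeps the backward pass short.  The output head is
zero-initialized, so the untrained prior is *exactly* uniform — every
masked cell scores ln K, which doubles as the closed-form anchor for the
whole scoring pipeline (an analytic `UniformPrior` reproduces it to
1e-9).

*Scoring.*  A masking window of half-width α slides along the token
grid's time axis (stride 1 by default).  For each center the masked
columns of a width-16 context window are replaced by [MASK], and each
masked cell receives the NLL of its true token; per cell the
contributions of all passes are averaged (cells near recording edges are
masked fewer times, and averaging keeps their scale comparable), then
summed over α ∈ {1, 2}.  The expectation in the score is thus taken over
the masked cells of one deterministic mask per window position, not over
random mask redraws.  Per-sample scores are the column mean over
frequency bins, expanded by the STFT hop.

*Detection.*  Samples scoring above τ are gap-clustered; a cluster whose
span exceeds half the recording (the coverage limit) is split at its
largest internal gaps — ties resolved nearest the middle so uniform runs
split geometrically — until every part complies, and an explicit
coverage-penalty helper (percentage points proportional to excess span)
is available for Δt scoring.  The published description of this adaptive
penalty is not specific; this split-plus-penalty form is this package's
own concrete choice.  τ defaults to a percentile of the pooled training
scores.

## Evaluation

*Matching.*  Detections are half-open intervals; zero-length detections
are points.  Strict mode matches against `[onset, offset)`.  SDW mode
matches against the union of `[onset − 300 s, onset + 180 s)` and the
ictal interval, so late-ictal alarms in very long seizures still count;
because every SDW window is a superset of its strict window, SDW
sensitivity dominates strict sensitivity and SDW false-positive counts
never exceed strict ones (asserted property).  One detection overlapping
two windows credits both seizures; several detections on one seizure
count it once and are never false positives.

*Metrics.*  Sensitivity = 100·TP/(TP+FN); FAR counts post-clustering
alarm events outside every window, divided by the patient's recorded
hours; HMS = sensitivity − 0.4·FAR, unclipped (negative values are
meaningful: they flag alarm rates that swamp the detections).  Cohort
values are unweighted means over patients; patients without seizures are
excluded from sensitivity and HMS means but keep contributing false
alarms to FAR.  The HMS identity is enforced at construction of every
per-patient record.

*Responders.*  R-peaks come from the two-moving-average QRS enhancement
method: band-pass 8–20 Hz, rectify-and-square, compare a 120 ms moving
average against a 611 ms one offset by 8% of the mean energy, emit one
peak per sufficiently long active block.  RR intervals outside
0.24–3.0 s are treated as artifacts and dropped.  The responder window
starts at the first seizure and grows symmetrically in 15 s steps until
it holds 100 RR intervals or exhausts the recording (flagged when
extension was needed); the patient responds iff max(60/RR) − min(60/RR)
exceeds 50 BPM.  "Maximum heart-rate change" is read as max − min within
the window; a change-from-baseline variant would need a separate
pre-ictal reference and is not implemented.

*Statistics.*  Patient-level bootstrap resamples patients with
replacement (1000 iterations), recomputes the patient-wise mean, and
takes the 2.5th/97.5th percentiles; seeded and deterministic.  Detector
pairs are compared on aligned per-seizure hit vectors with the
Yates-corrected McNemar statistic χ² = (|n10 − n01| − 1)²/(n10 + n01)
against χ²(1); zero discordance is reported as χ²=0, p=1 rather than an
error.

## Synthetic cohort: what it is and is not

The generator renders a PQRST template train (five Gaussian waves at
fixed offsets from the R peak) driven by an RR tachogram whose
instantaneous rate is the baseline profile plus Gaussian beat-to-beat
jitter; white measurement noise of 0.01 mV is added.  Seizures raise the
rate by `hr_delta` with a 10 s linear ramp, an ictal plateau, and
exponential post-ictal decay (τ = 30 s) — the decay is what makes
post-onset detections land inside the SDW, mirroring persistent autonomic
change.  Saturation clips contiguous ~1 s runs to ±rail until exactly
`⌊fraction·N⌋` samples are clipped.  A morphology-perturbation gain
exists for ictal waveform change but defaults to off, since no
quantitative target exists for it.

Default study conditions: 10 patients × one 360 s recording (one hour of
signal), one seizure of 30–60 s per recording, baseline 70 BPM, HRV SD
3 BPM, responder fraction 0.5 with excursions of 70 BPM (responders)
versus 20 BPM (non-responders), seizure types drawn with the benchmark
test set's frequencies.  Everything is deterministic given the cohort
seed.

What passing tests on this cohort shows: the plumbing and the mathematics
are right — detectors localize a genuine rate excursion, responder
classification recovers the injected dichotomy, clustering and matching
behave per contract.  What it does not show: performance on real wearable
ECG, whose non-stationary baselines, movement artifacts, ectopy and
subtle non-motor seizures are all absent here.  Absolute
sensitivity/FAR/HMS numbers from the synthetic benchmark therefore
characterize the pipeline, not the clinical problem.

## Benchmark protocol and problem sizes

The runner splits patients (default 75/25 by sorted id), makes every
data-driven choice — detector operating point per objective
(sensitivity, FAR, HMS) and clustering Δt — on training patients only,
then evaluates test patients under both matching modes, overall and for
responders.  FAR objectives are minimized with ties to higher
sensitivity; the others maximized with ties to lower FAR.  The
tokenizer/prior stages train once on the pooled non-SDW segments of
training recordings.  Desk-scale sizes (250 training steps per stage,
the cohort above, Δt grid {2, 5, 10, 30, 60} s) keep the full benchmark
around half a minute on one CPU while leaving every mechanism exercised;
they are configuration, not constants.

## Known limitations

- The EDF writer covers exactly one channel with int16 samples; physical
  range strings are rounded outward to the 8-character header fields,
  costing up to ~1e-5 relative amplitude.
- The matrix profile is exact but O(n²·m); recordings beyond a few hours
  at 8 Hz would want an FFT-based or pruned formulation.
- The masked-token prior's context window is 16 frames (16 s); anomalies
  slower than that are seen only through their local texture.
- Token grids are scored with one deterministic mask per window; mask
  ensembles would smooth scores at additional cost.
- Responder classification uses the first annotated seizure only, per the
  benchmark's definition, and inherits any R-peak detection failures on
  heavily corrupted signal.
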