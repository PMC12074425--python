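# Methods

This note documents the models and procedures implemented in `seizelect`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Problem setting

Scalp EEG for epilepsy monitoring is recorded from the 21 bipolar
derivations of the international 10–20 system at 256 Hz. The package
addresses two coupled tasks for a single patient:

1. **Channel-pair selection** — find the two derivations that carry the
   most phase-specific information: one representative of the *no-seizure*
   phase (channel A) and one of the *ictal* phase (channel B).
2. **Seizure detection** — train a lightweight convolutional network on
   4-s windows of those two channels and score it at the segment and
   event level under leave-one-record-out (LORO) cross-validation.

## Preprocessing

Each record is cleaned with a 1-Hz-wide second-order Butterworth band-stop
centred on the powerline frequency (60 Hz default, 50 Hz selectable),
z-scored per channel over the whole record, and band-passed into the five
clinical bands δ[0.5,4], θ(4,8], α(8,13], β(13,35], γ(35,80] Hz with
second-order Butterworth filters. All filters are applied
forward–backward (zero phase): offline analysis has no reason to accept
group delay, at the cost of doubling the one-pass attenuation. "1 Hz wide"
is read as the total stop-band width. The step order is fixed: notch →
z-score → band-pass. Z-scoring is per whole record (per-window
normalization would erase the between-window variance differences the
selection method feeds on).

## Channel weight coefficients (CWC)

Each band-filtered record is cut into non-overlapping 1-s windows
(N = 256 samples × C = 21 channels). For each window the sample covariance
(1/(N−1), columns mean-centred per window) is eigen-decomposed into
loadings L (columns = eigenvectors) and eigenvalues s_j. The per-channel
weight is

    CWC_i = Σ_j |l_ij| · s_j ,

the absolute loadings weighted by explained variance and summed over all
components — no component truncation. Numerical choices: eigenvalues are
clipped at zero against floating-point negatives; a window containing a
constant channel is skipped (NaN row); exactly degenerate eigenvalues make
eigenvectors non-unique and the solver's deterministic output is accepted
(a measure-zero event on noisy data). Useful invariances, all asserted in
the tests: scaling data by *a* scales CWC by *a*²; eigenvector sign flips
and channel permutations behave as expected; the channel *ranking* is
independent of the 1/N vs 1/(N−1) convention.

## Pair selection

Per seizure-containing record and band, the CWC rows are averaged within
each phase. The ictal phase is the annotated seizures; the no-seizure
phase excludes a guard interval before onset and after offset (default
600 s for hour-long clinical records; the synthetic study uses 60 s on
its 600-s records). The guard is the reproducible surrogate for the
pre-/post-ictal regimes, which are visible in CWC time courses but have
no detector. Per record, each band's 21-vector is min–max normalized
across channels and the five bands are averaged with equal weight; a
constant band contributes 0.5 everywhere (an uninformative band should
neither promote nor demote channels). Per-record maps are averaged across
records and rescaled to [0, 1].

Both phase maps are digitized at a threshold of 0.9 (strict `>`), and the
XOR of the two bit vectors keeps channels dominant in exactly one phase.
When several candidates survive, the pair with the lowest mean absolute
Pearson correlation ρ̄ — averaged over non-overlapping 1-s windows, the
five bands, and the contributing records — wins; ties break toward lower
channel numbers. Fallbacks: if only one phase has candidates, the two
least-correlated channels within that set are used; if neither has any,
the threshold drops in 0.05 steps until two distinct candidates exist.

The canonical entry point runs this selection once per LORO fold and
majority-votes the per-fold pairs (ties break toward lower mean ρ̄, then
lexicographically), so the classifier-facing pair never depends on any
single held-out record.

Segment ground truth note: a segment (below) is truth-ictal when all
three of its windows are truth-ictal under the ≥50 %-overlap window rule.
Defining segment truth by raw interval overlap instead would make perfect
window predictions unable to score perfectly at seizure boundaries; with
the buffer rule applied to both prediction and truth, the perfect-oracle
identity is exact.

## Detector

The detector is a five-block convolutional network consuming broadband
(notch + z-score only) 4-s windows shaped (1, M, 1024) — channels as
height, time as width. Blocks: Conv2D(4 filters, 1×4) → BN → ReLU →
MaxPool(1×8); Conv2D(16, 1×16) → BN → ReLU → MaxPool(1×4); Conv2D(16,
1×8) → BN → ReLU → MaxPool(1×4); Conv2D(16, 16×1) → BN → ReLU →
MaxPool(M×1); Conv2D(16, 8×1) → BN → ReLU; global average pool; dense
16→2 with softmax. Convolutions are zero-padded to preserve shape
(trailing-side extra padding for even kernels), so no layer's parameter
count depends on M: 9470 trainable parameters (≈9.5k) for both the
two-selected-channel (M=2) and four-temporal-channel (M=4, F7-T7, T7-P7,
F8-T8, T8-P8) configurations. Batch-normalization scale/shift are the
only BN parameters; running statistics are buffers. The network, its
backpropagation and the Adam optimizer are implemented directly in NumPy
(single precision); weights initialize with the uniform fan-in scheme
from a seeded generator, and inference uses running BN statistics, so
forward passes are deterministic for fixed weights.

## Training

LORO: one fold per record, including seizure-free records as test folds.
Validation is one seizure-containing record from the remainder when
possible (the published protocol splits the remainder without stating a
ratio; one record is the smallest leak-free choice), the rest train.
Windows are 4 s; training stride is 2 s on seizure records and 4 s on
seizure-free records to bound dataset size; evaluation always uses 2 s. A
window is labelled ictal when ≥50 % of its span overlaps an annotated
seizure (symmetric, standard; the boundary rule is otherwise unstated).
Batches hold 64 windows with exactly 3 (5 %) minority-class samples when
any exist, drawn with replacement once the minority pool is exhausted;
one epoch covers the majority class once. Adam (lr 10⁻³, β₁ 0.9,
β₂ 0.999), cross-entropy, at most 150 epochs, early stopping after 10
epochs without validation-loss improvement, best-validation weights
restored.

## Evaluation

Window predictions at 2-s stride are folded into *segments* of three
consecutive windows (8-s span, 2-s advance). A segment is predicted ictal
only if all three windows are ictal — deliberately stricter than majority
voting, suppressing isolated false-positive windows. Segment counts give
SN, SP, Acc and bAcc = (SN+SP)/2; undefined ratios (e.g. SN of a
seizure-free record) are NaN, never silent zeros. Maximal runs of ictal
segments merge into events; a seizure is detected when any event overlaps
it, the delay is the earliest overlapping segment start minus the onset
(clipped at 0), and events overlapping no annotation count toward FP/h.
Per-record metrics aggregate to patient level as mean ± sd, with NaNs
excluded and events pooled.

## Synthetic patients

The generator emulates the corpus the method targets: 21 bipolar channels
at 256 Hz, records of minutes (default 4 × 600 s), one annotated seizure
per record of 10–60 whole seconds placed ≥ guard from record edges.
Background: per-channel pink (1/f) noise at ~30 µV plus a rank-8 shared
component (25 % of variance) whose mixing is redrawn per record with
equal per-channel loading norm — realistic cross-channel correlation
without making any channel systematically dominant — and a stable
lognormal per-patient amplitude profile (sd 0.1 in log) that elevates the
same channels in both phases, which is precisely the structure the XOR
step cancels.

Planted signatures: during seizures, channel B (default 9, F8-T8) gains a
broadband 13–80 Hz discharge at a band-power ratio `ictal_gain`, tapered
at the edges, with 0.3 of its amplitude leaking to the two adjacent
montage channels; outside seizures, channel A (default 19, P3-O1)
carries an alpha-centred rhythm with a beta-range first harmonic (0.6
amplitude) and a theta component (0.5) — mimicking a non-sinusoidal
posterior dominant rhythm — at band-power ratio `baseline_gain`.
Narrow single-band signatures were deliberately avoided: the min–max
normalization is scale-free, so a one-band advantage is capped at 1/5 of
the merged map, and the z-score makes a strong narrow-band addition
*suppress* its channel in the remaining bands; spectrally broad
phase-specific activity is both the physiologically realistic case and
the regime the selection method is designed for. Gains are power ratios
relative to the channel's own band-limited background, so gain 1 plants
nothing (the negative control). The default gain is the smallest integer
at which the planted pair is recovered in ≥19 of 20 seeded replicates —
calibrated once against that criterion and frozen.

What passing synthetic tests does **not** show: performance on real
scalp EEG with artifacts (EMG, blinks, electrode pops), non-stationary
backgrounds, seizure morphologies beyond band-limited power increases, or
inter-patient variability of seizure topography. The published corpus
results (bAcc 0.83, 0.10 FP/h, 152/181 events over ~950 h and 24
patients) require the real recordings and multi-hour training; they are
deliberately not recomputed here. The CLI (`seizelect select / train /
evaluate / report`) runs unchanged on a directory of real EDF records
with summary annotations, which is the optional replication route.

## Scaled-down study sizes

The repository's own checks use synthetic patients of 4 × 600-s records
for selection (20 replicates for the recovery rate) and one 3-record
patient for the end-to-end LORO detection check — sizes chosen so the
whole validation runs on a single CPU core in minutes while leaving every
stage of the pipeline exercised at realistic per-second dimensions
(256-sample windows, 21 channels, 1024-sample detector inputs).

## Known limitations

- Index-adjacency (channel number ± 1) is used for the simulated spatial
  leak of the ictal discharge; true scalp adjacency differs for a few
  montage positions.
- The EDF writer emits minimal single-rate 16-bit files (sufficient for
  fixtures; no EDF+ annotations channel).
- With multiple equally frequent pairs and equal ρ̄, majority voting falls
  back to lexicographic order, an arbitrary but deterministic choice.
- The strict three-window unanimity rule trades sensitivity at seizure
  onset/offset for a lower false-positive rate; delays are measured
  against the earliest overlapping segment, so they are bounded below by
  the buffer geometry.
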