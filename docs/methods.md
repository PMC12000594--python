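# Methods

## Model

MSCFormer classifies one epoched EEG trial X ∈ ℝ^(C×T) into M motor-imagery
classes. Three convolutional branches share F₁ = 16 temporal filters but
differ in kernel length K_c ∈ {85, 65, 45} samples (0.18–0.34 s at 250 Hz),
so each branch is tuned to a different temporal scale of the sensorimotor
rhythms. A branch computes:

1. temporal convolution (1×K_c), zero-padded 'same' so all branches emit
   T-length maps (K_c is odd, so padding is exact);
2. depthwise spatial convolution (C×1) with depth multiplier 1 — one spatial
   filter per temporal map, no cross-map mixing;
3. batch normalization (momentum 0.1, ε = 1e-5) and ELU;
4. average pooling (1×P) with stride P, and dropout 0.5.

Both convolutions carry bias terms (the biases before BN are redundant in
expressivity but are part of the size accounting below). The pooled length
is T_p = ⌈T/P⌉ by default (`pool_ceil_mode=True`, a trailing partial window
averaged over the samples it contains); floor mode is available and matters
only for the size accounting of the flatten classifier (below). For T = 1000
this gives the token-length law T_p = 84 at P = 12 down to T_p = 14 at
P = 72.

The three (F₁, T_p) maps are transposed and concatenated along features into
T_p tokens of dimension F₂ = 3F₁ = 48. A learnable class token is prepended
and a learnable positional table of shape (T_p+1, F₂) added (both
initialized N(0, 0.02²)). The encoder is L = 5 post-norm Transformer layers:
multi-head attention with h = 8 heads of dimension d_k = F₂/h = 6,
softmax(QKᵀ/√d_k)V per head, concatenated and projected; then a
feed-forward block Linear(48→192) → GELU → Linear(192→48); each sub-block
adds its residual before LayerNorm (post-norm, not pre-norm). Dropout 0.25
follows the attention projection and the GELU. The classifier applies
dropout 0.25 to the final-layer class-token embedding and one fully
connected softmax layer. MSNet, the no-Transformer ablation, flattens the
T_p·F₂ token map directly into the same classifier; it is a distinct head,
and constructing MSCFormer with depth 0 is rejected.

Training minimizes mean cross-entropy with Adam (lr 1e-3, β₁ = 0.5,
β₂ = 0.999). Weight decay, when enabled (1e-3 for the 3-channel benchmark),
is applied as an L2 gradient term to weights but not to biases, norm
parameters, or the embedding tables. Prediction is the argmax of the softmax
output, ties broken toward the lower class index.

## Size accounting

`count_parameters` defaults to the operator-weight convention: convolutions
(with biases), BN/LN affine parameters, attention and feed-forward
projections, and the classifier — the class token and positional table are
excluded. Under this convention the benchmark configurations measure
145,924 (22 ch / 4 classes) and 144,914 (3 ch / 2 classes) scalars for
MSCFormer, i.e. 145.9 k and 144.9 k; the counts are independent of the
pooling size because neither excluded table is an operator weight.
`include_embeddings=True` gives the complete trainable count (the model does
train both tables). For MSNet the flatten classifier makes the count depend
on T_p; the published 8.6 k / 5.3 k figures correspond to the
floor-division token lengths (T_p = 22 at P = 44, T_p = 19 at P = 52),
reproduced with `pool_ceil_mode=False`. The ceil/floor distinction is
exposed as a real configuration flag precisely because the token-length law
above uses ceil while this accounting uses floor; the default is ceil.

## Data handling

Epoching is index-exact: the sample window is
[round(t_start·fs), round(t_start·fs) + (t_end−t_start)·fs), half-open,
0-based, measured from trial start. The benchmark windows are 2–6 s
(4-class, 22 electrodes after discarding the three EOG channels) and 3–7 s
(2-class, 3 bipolar channels), each 1000 samples at 250 Hz. Where a
recording carries only cue events, trial start is inferred as cue onset
minus the paradigm's fixed cue delay (2 s and 3 s respectively) — the
standard trial timing of these datasets; this fallback is documented rather
than silently assumed. No band-pass filtering or artifact removal is applied
anywhere. Artifact-flagged trials are kept by default (sessions keep their
full 288 trials); `exclude_artifacts=True` drops them. Evaluation-session
labels come from the separate true-label files, passed explicitly.

Standardization (zero-mean): x̃ = (x − μ)/σ with μ, σ computed over the
training data only and applied unchanged to validation and test data. The
default scope is global (one scalar pair over all trials, channels and
samples), the most natural reading of "mean and S.D. of the raw EEG data";
per-channel scope is available. σ = 0 (constant signal) is an error unless
the documented ε-override (1e-8) is enabled.

S&R augmentation partitions [0, T) into N_s contiguous segments (sizes
differ by ≤ 1; the first T mod N_s segments get the extra sample) and builds
each artificial trial by drawing segment k, at position k, from a uniformly
chosen donor trial (with replacement) of the target class. Segments never
change temporal position and classes never mix; an artificial trial may
coincide with an original. N_s defaults to 8. The number of augmented
trials N_A is not fixed by the protocol's description; the default doubles
the training fold (N_A = fold size) and is configurable — this value is a
package choice, not an externally validated one.

## Training protocol

Five-fold subject-specific cross-validation: the original training session
is shuffled and split into five near-equal subsets (288 trials → validation
sizes {58, 58, 58, 57, 57}). Per fold, the standardizer is fitted on the
four original training subsets *before* augmentation — augmented trials are
recombinations of the same samples, so under global scope the statistics
differ from fitting after augmentation only through donor multiplicity; the
order is fixed and documented here. Augmentation donors come exclusively
from the training subsets; provenance tags on every trial let the trainer
reject validation-tagged trials outright (leakage guard). Validation loss is
computed after every epoch without augmentation; the checkpoint with the
lowest validation loss is restored (ties → earlier epoch, the more
regularized model) and scored once on the held-out test session. Batches are
drawn without replacement within an epoch from the original-plus-augmented
pool; a batch size larger than the pool simply yields one full-pool batch.
Fold seeds are seed + fold_index; identical seeds give bit-identical
results. A non-finite loss aborts with fold/epoch/batch diagnostics.

## Metrics

Accuracy is 100·trace/total of the confusion matrix (rows true, columns
predicted). Kappa is (p_o − p_e)/(1 − p_e) with p_e from marginal products
(Cohen); for balanced sessions this coincides with the 1/M accuracy of a
random guess, which is selectable explicitly. The Wilcoxon signed-rank test
is two-sided, exact for ≤ 25 non-zero differences, with zero differences
dropped; tiers are '**' (p < 0.01), '*' (p < 0.05), n.s. otherwise. ROC/AUC
is restricted to binary tasks; the trapezoid AUC equals the Mann–Whitney
pairwise statistic (asserted in tests). Feature export for external
embedding (e.g. t-SNE) is provided at four stages — raw, fused tokens,
after encoder layer k, final class token — the embedding itself is
delegated to the ecosystem.

## Synthetic data

The generator emulates the statistical structure MI decoders exploit:
event-related power differences of a band-limited rhythm. Each trial is a
sinusoid with trial-random frequency in the rhythm band (default 8–12 Hz)
and channel-random phase, plus 1/f-shaped noise (spectrally shaped white
noise, unit S.D., DC removed). Class k multiplies the oscillation amplitude
by (1 + effect_size) on its designated block of ⌊C/M⌋ consecutive channels;
effect_size 0 is an exact null. Defaults: 2 classes, 6 channels, 250
samples at 250 Hz, 30 trials per class, noise S.D. 1 — a deliberately small
geometry on which the full five-fold protocol runs in about a minute on one
CPU. The generator does not model volume conduction, inter-channel
correlation of the noise, artifacts, or non-stationarity; tests passing on
it demonstrate that the pipeline's machinery (epoch handling,
standardization, augmentation, optimization, selection, scoring) is correct
and that the network can learn band-power contrasts, not that benchmark
accuracies transfer.

The worked fixture is an 8-trial, 2-channel, 16-sample set with distinct
integer samples generated by a fixed arithmetic formula (no RNG), hash-
pinned in the tests, so augmentation recombinations and standardization
statistics can be enumerated and checked by hand.

## Numerical choices and limitations

All arithmetic is float64 NumPy. The autodiff engine implements exactly the
primitives the model needs and is gradient-checked against central finite
differences (per-op and whole-model). The attention softmax subtracts the
row max (gradient-invariant shift). BN uses batch statistics in training
and running averages (momentum 0.1) in inference. Initialization is
fan-in-scaled uniform for convolutions and linear layers and N(0, 0.02²)
for the embedding tables, all from a single seeded generator, so model
construction is reproducible.

Known limitations: no GPU path and no mini-batch parallelism beyond BLAS, so
full-benchmark training (5 folds × 1000 epochs × 288 trials) is out of
desk-scale reach — the protocol is implemented and verified on reduced
problems; cross-subject transfer, learning-rate schedules, early stopping,
pre-norm encoders, relative positional encodings, attention masking and
multi-class ROC extensions are out of scope.
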