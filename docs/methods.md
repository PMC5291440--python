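# Methods

## Problem and model

promcnn classifies fixed-length, TSS-anchored DNA windows as promoter or
non-promoter and then asks *where* in the window the trained classifier's
evidence lives.  Windows follow the conventions common for curated
promoter collections: 81 nt spanning −60..+20 around the TSS for
bacteria (TSS at 1-based position 61) and 251 nt spanning −200..+50 for
eukaryotes (TSS at position 201).  The TSS-relative coordinate of
1-based window position *p* is *p − tss_index*.

The classifier is a small 1-D convolutional network over one-hot
sequence (columns A, T, G, C; `N` encodes as the all-zero row, so it is
neutral with respect to every filter dot product `W·x + b`):

* one or more **valid** (unpadded) convolutional layers, stride 1, ReLU,
  each optionally followed by non-overlapping max-pooling whose stride
  equals its size (trailing remainder positions are dropped);
* a fully connected ReLU layer (128 units by default);
* a 2-neuron sigmoid output, promoter encoded (1, 0) and non-promoter
  (0, 1); a window is called promoter iff the promoter neuron strictly
  exceeds the non-promoter neuron (ties break conservatively to
  non-promoter), and the reported score is always the promoter neuron.

Architectures are declared in a compact "F, L, P" dialect — F filters of
length L, pooling size P, layers separated by "/"; P = 0 means no
pooling.  Valid convolution makes the arithmetic exact: length n maps to
n − L + 1, then integer division by P.  A pool size equal to the full
activation-map length (e.g. "300, 21, 231" on a 251-nt input, since
251 − 21 + 1 = 231) is therefore global max pooling.  Padding mode and
pooling stride are this package's own conventions, chosen because they
make that global-pool entry land exactly on one value.

## Training

Stratified 70/10/20 train/validation/test split of the full corpus (the
three fractions apply to the whole set and sum to 1; stratification
keeps the class ratio of each part within one record).  Training uses
Adam (step size 1e-3, β₁ = 0.9, β₂ = 0.999) at batch size 16 on
categorical cross-entropy against the one-hot class targets.  The
validation part selects the epoch: parameters are snapshotted each
epoch and the earliest epoch with the highest validation accuracy is
returned, with a patience rule (default 3 epochs without a new best)
stopping training before `max_epochs` when validation accuracy has
plateaued — the standard guard against over-fitting.

Two numerical points deserve record:

* **Loss head.** The output neurons are independent sigmoids, not a
  softmax, so inside the loss the pair is renormalized
  (pᵢ / Σⱼ pⱼ) before the log.  Without this the cross-class gradient
  vanishes (each neuron would only ever be pushed up by its own class)
  and the head cannot learn.
* **Output initialization.** This head has a flat region: if both
  sigmoids saturate near 1, the normalized probabilities are ~½
  regardless of the inputs and gradients are damped by (1 − pᵢ).  With
  ordinary Glorot output initialization, Adam reliably walked into that
  plateau on our corpora.  The output layer is therefore initialized at
  0.01 × Glorot scale (conv/dense layers use He initialization), keeping
  early logits near zero.  The scheme is recorded in model metadata.

All randomness — initialization, epoch shuffling, batch order — derives
from the config seed, and the numpy implementation is bit-deterministic:
retraining with the same seeds reproduces the selected model exactly.

## Evaluation

With S positive and N negative examples, TP/FP/TN/FN give
Sn = TP/(TP+FN), Sp = TN/(TN+FP), AC = (TP+TN)/(S+N), and the
Matthews-style correlation coefficient
CC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Sp here is the true-negative rate, not precision.  A zero marginal makes
CC undefined; the default is a hard error, with an explicit opt-in that
maps the degenerate case to 0 (used by the CLI for display, so a
one-epoch degenerate model still prints a report).  Metrics are computed
in double precision and rounded only at display (2 decimals).

## Synthetic corpora

The generator emulates the statistical skeleton of curated promoter
corpora: positives are i.i.d. background draws (default uniform base
composition) with one or more PWM-sampled motif instances overwritten at
fixed TSS-relative offsets, optionally jittered uniformly by up to ±j
positions; negatives are background-only.  Shipped motif fixtures —
TATA-box (8 nt, offset −30), Inr-like (4 nt, −1), bacterial −10 (6 nt)
and −35 (6 nt) boxes — are consensus-weighted toys (consensus
probability 0.9 by default), not biological claims.  An optional
"coding-like" negative mode draws from a 3-periodic base composition to
mimic reading-frame structure when a harder negative class is wanted.

What the generator does **not** model: dinucleotide or higher-order
background, CpG islands/isochores, motif presence/absence mixtures,
strand effects, or negatives taken from real genic sequence.  Passing
tests on these corpora therefore demonstrate that the pipeline learns
and localizes positionally planted signals, not that it attains any
particular accuracy on real promoter corpora.

The learnability and element-recovery checks use a separable-by-
construction corpus: 1000 promoters with the **consensus-only** TATA PWM
at offset −30 (no jitter) in 251-nt windows versus 1000 background
negatives — a condition under which a positional string-match oracle is
perfect, so any shortfall is attributable to the learner.  The null
control retrains the same pipeline on label-shuffled data, where
held-out accuracy must stay at chance.

## Random-substitution profiling

For each window start (length 6 by default, stride 1), every promoter's
window content is replaced by freshly drawn random bases (uniform by
default; a background-composition option exists), the set is
re-classified with the fixed model, and sensitivity is averaged over 10
replicates (independent draws per record per replicate), with the
standard error of the replicate mean reported per point.  Windows are
indexed by start position; outputs carry both 1-based and TSS-relative
coordinates.  Dips localize sequence the model depends on;
`profile_minima` thresholds at (1 − drop_fraction) × baseline
sensitivity, groups implicated starts into maximal runs, reports the
union of covered sequence positions as TSS-relative intervals, and
merges overlapping covers so intervals are disjoint.

A caveat this package documents deliberately: a model trained on a
corpus where *every* positive carries two motifs need not rely on both —
either motif alone separates positives from background-only negatives,
and in practice training latches onto one (we observed profiles
completely flat across the second motif).  The two-interval recovery
check therefore drives the profiling machinery with a hand-constructed
conjunctive matcher (`build_positional_motif_model`), a real network
whose filters copy the two consensus strings and whose threshold
requires both — exact ground truth through the ordinary forward path.

Information content per alignment column is the sequence-logo statistic
IC = 2 + Σ_b p_b·log₂ p_b bits (0 = uniform, 2 = invariant), with N
bases excluded from counts.  A Schneider-style small-sample correction
(e(n) = 3/(2n·ln 2), clipped at 0) is available but off by default; at
the corpus sizes used here (hundreds to thousands of sequences) it is
negligible.

## Problem sizes and defaults

The shipped checks and the reproduction script use: corpora of
1000 + 1000 × 251-nt windows; a one-layer "32, 21, 4" network (which at
this input length has 32·21·4 + 32 = 2,720 conv parameters); batch 16;
up to 20 epochs with patience 5; profiles on ~200 held-out promoters at
window 6 × 10 replicates.  These sizes give stable statistics
(binomial SE ≈ 0.015 at n = 200 per class) while keeping a full run in
the minutes range on one CPU core.  Larger corpora and the full
published-scale architectures ("200, 21, 4" etc.) run unchanged through
the same API, just slower.

## Known limitations

* Accuracy figures on real promoter collections (EPD, RegulonDB, DBTSS)
  are out of scope here; the synthetic corpora are deliberately easier
  than real data.  The CLI trains on any pre-windowed FASTA pair, so
  such corpora can be supplied externally.
* The substitution profile attributes importance only to **positionally
  conserved** elements; motifs at variable offsets spread their dip and
  may fall below threshold.
* Only binary classification, stride-1 valid convolution, and
  non-overlapping pooling are supported — matching the modeled method,
  not a general deep-learning toolkit.
* Whole-genome scanning with overlapping-prediction resolution is not
  implemented.
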