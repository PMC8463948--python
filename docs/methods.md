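# Methods

## Problem setting

Smartwatches record one ECG lead at a time; moving the watch between body
positions yields multiple leads that are *asynchronous* — each lead is a
different 2.5 s window of cardiac activity.  Standard 12-lead reports have
the same structure (four slots of three simultaneous leads at offsets
0/2.5/5/7.5 s), so asynchronous lead subsets can be derived from routine
hospital ECGs and used to train a classifier that will accept smartwatch-style
input.  The package implements that derivation, a classifier that tolerates
arbitrary missing leads, the training and evaluation protocol, and a
synthetic generator that stands in for hospital data.

## Lead algebra

The six limb leads are linear functionals of a two-dimensional frontal-plane
source, so they form a rank-2 system: Einthoven's law `II = I + III` plus the
Goldberger definitions of the augmented leads.  `reconstruct_limb_leads`
inverts the 2×2 coefficient matrix of any supplied pair (every pair of the
six is linearly independent) and emits all six leads; supplied leads are
returned verbatim.  In completely asynchronous sets, lead II is computed from
the slot-1 augmented leads as `II = 2(aVF − aVR)/3` and carries the 2.5 s
offset, keeping one lead per slot.

Enumeration of tested lead sets follows three constraints: lead I belongs to
every multi-lead set (it is the lead a watch measures without being moved);
3- and 4-lead sets also contain the derived lead II; members come from
pairwise distinct slots.  This yields 9 four-lead, 6 three-lead, 7 two-lead
and 2 single-lead sets, verified in the tests against a brute-force
enumeration over all subsets.

## Model

Per-lead encoder (weight-shared across the 12 channels):

- 16 residual blocks, every conv with kernel 7 and "same" padding, each conv
  followed by batch normalization and ReLU;
- feature depth 64 doubling every 4 blocks (64/128/256/512);
- stride schedule: block 1 has three convs with strides (1, 2, 1); odd blocks
  3–15 are 3-conv blocks with strides (2, 1, 1); even blocks are 2-conv
  (1, 1) blocks.  Total downsampling 2^8: 625 → 3 samples, then global
  average pooling to a 512-vector.  The exact per-block stride placement is
  one consistent realization of "2 or 3 convs per block, stride 2 every 2–4
  blocks"; it is configurable via `ModelConfig.stride_schedule`;
- block 1's shortcut taps the output of its first ReLU and joins the block
  output through a stride-2 average-pooling layer; later blocks use identity
  shortcuts, realized parameter-free as average-pooling (for length changes)
  plus channel zero-padding (for depth changes).  No activation follows the
  addition.

Fusion: multi-head self-attention (8 heads of 64; the head count is a
standard choice dividing 512) over the 12 embeddings with scaled dot-product
scores.  Masking acts on the attention matrices: unavailable leads get score
−∞ as keys, hence softmax weight exactly 0, and their output rows are zeroed
before flattening.  Both steps matter — without row zeroing a masked lead's
own query row would leak its encoder output into the classifier.  Because
`exp(−∞) = 0` exactly and `0 · v = 0` in IEEE arithmetic, inference output is
bit-identical under any perturbation of masked-lead inputs; the acceptance
suite asserts a change of exactly zero over 100 random (parameters, input,
mask) triples.  No residual connection or layer normalization is used around
the attention module.  Classifier: flatten (6144) → dense 512 → ReLU →
dense 1 → sigmoid.

Masked leads are fed zeros through the encoder to keep a fixed 12-channel
graph; their encoder outputs are discarded by the attention masking.  In
training mode batch-norm statistics pool over all 12 channels of the batch,
including zeroed segments; inference uses running statistics, which preserves
per-lead independence.

The whole network, its backward pass and Adam are implemented in NumPy
(float32; convolutions as im2col matrix products).  Gradients were verified
against central finite differences layer by layer.

## Training

Binary cross-entropy on the sigmoid output (no class reweighting; operating
points are chosen downstream by threshold).  Adam with batch 32, learning
rate 1e−3, weight decay 1e−4 applied to conv/dense weight matrices only.
Per sample per step a fresh lead mask is drawn: each lead dropped with
probability `mask_prob = 0.5`, redrawn if all 12 would vanish.
Augmentations, each applied with independent probability 0.3 to available
leads: additive Gaussian noise (SD 0.05 mV), time scaling by a factor in
[0.9, 1.1] with linear resampling back to 625 samples, and zeroing of a
random contiguous window of up to 10 % of the segment.  Splits are grouped
by patient: 80 % train+validation / 20 % test, then 85/15 within
train+validation.  Early stopping monitors validation AUROC (all leads
available) with patience 10; an optional `stop_auroc` threshold ends
training once validation AUROC is effectively perfect, which the scaled
study uses (0.995) to save compute on its easy task.  All randomness flows
from a single seed; runs are bit-reproducible.

## Evaluation

AUROC is the trapezoidal area over unique-score thresholds (equal to the
Mann–Whitney pair statistic with ties counted half — asserted against a
brute-force pairwise oracle).  AUPRC uses step-wise integration of the
precision–recall curve without interpolation; the recall-0 endpoint is the
first achievable point.  `sensitivity_at_specificity` scans thresholds of
the form "positive iff score ≥ t" and returns the highest-sensitivity point
whose specificity meets the target (achieved specificity may exceed the
target, as on any discrete ROC).  The paired DeLong test uses placement
values (structural components) with sample covariances; it reproduces
`pROC::roc.test` to seven decimals on shared fixtures and attains its
nominal 5 % level in null simulations at 60 positives / 240 negatives per
replicate.  Interpretation-text categorization is case-insensitive substring
matching after whitespace normalization; the second criterion's phrase set
strictly contains the first's, so its positives are always a superset.

## Cohort rules

ECGs within 24 h (closed interval) of an emergency-room visit by patients
aged ≥ 20 are kept.  A visit is AMI-positive when any ICD-10 code starts
with I21 or I22 (prefix match on the dot-stripped code, so subcodes count).
Positive-visit ECGs whose AMI-code registration times are all null or all
beyond 24 h of that ECG are excluded with an itemized reason — never
relabeled — and the registration-time rule never touches negative visits.
The 24 h exclusion window is evaluated per ECG.  Kept + excluded counts
always equal the input count.

## Synthetic data

Records are built from a 3-component cardiac dipole: P/Q/R/S/T Gaussian
bumps along an electrical axis of roughly 55°, heart rate uniform in
55–95 bpm, ±15 % amplitude jitter, 10 s at 500 Hz, FIR-decimated to 250 Hz.
Each lead is a fixed projection of the dipole; the limb-lead projection
vectors are constructed from the (I, II) pair via the Einthoven/Goldberger
relations, so the identities hold to machine precision before noise.
Positives receive an ST-window dipole component aimed at one of three
territories and calibrated so the representative lead (aVF for inferior;
the V1–V4 mean for anterior; the I/aVL/V5/V6 mean for lateral) deviates by
exactly `st_shift` mV; reciprocal depression in opposing limb leads emerges
from the projection geometry (−st/2 in aVL and aVR for inferior events).
Per-lead white noise is added after projection.  This is cartoon
electrophysiology: it guarantees a learnable, spatially localized class
signal and exact lead algebra, but has none of the morphological diversity,
artifacts, comorbid abnormalities or label noise of hospital ECGs — so
passing tests demonstrate the mechanics of the method, not clinical
performance.

## The scaled study

Hospital-scale training (~140k ECGs at 1.8 % prevalence) is far beyond a
desk run, so the lead-count experiment is scaled down as the package's own
study condition: the reduced model (8 blocks, initial depth 16, stages
16/32, embedding 32, downsampling every block: block 1 strides (2, 2, 1),
blocks 2–8 (2, 1)), 2,000 synthetic records per seed at 20 % prevalence,
ST shift 0.25 mV, noise 0.05 mV, 3 seeds, at most 4 epochs with
`stop_auroc = 0.995`.  Prevalence is raised so that a 2,000-record cohort
contains enough positives to train on.  With `--seed 1` the study yields
held-out mean AUROC 1.00 / 0.98 / 0.97 / 0.79 / 0.65 for the 12-/4-/3-/2-/
single-lead sets — the monotone lead-count ordering of the full-scale
protocol, compressed to an easy task.  Absolute values are not comparable
to hospital data; only the ordering and the feasibility of
train-once/evaluate-any-subset are being demonstrated.

## Numerical choices and limitations

- float32 weights and activations; BCE computed in float64 with probability
  clipping at 1e−12.
- Batch-norm eps 1e−5, momentum 0.1; Adam β = (0.9, 0.999), eps 1e−8.
- "Same" padding splits the pad TensorFlow-style (extra sample on the
  right); pooling uses ceil-mode lengths to match strided convs.
- Ties in `sensitivity_at_specificity` resolve toward higher sensitivity
  subject to the specificity constraint.
- The per-block Length/Depth table of the reference architecture is not
  public; the default stride schedule is one consistent realization and is
  fully configurable.
- No WFDB reader is included; records interchange as JSON sidecar + CSV.
- The DeLong normal approximation is slightly anticonservative below ~50
  positives; calibration checks use 60 positives per replicate.
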