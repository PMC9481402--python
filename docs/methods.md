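# Methods

`beatvote` implements an automatic inter-patient arrhythmia classifier
for single-lead ECG: annotated heartbeats are cut into fixed windows of
raw samples, re-sampled to soften the extreme class imbalance, fed to a
small ensemble of residual 1-D convolutional networks trained with a
class-weighted focal loss, and evaluated with the AAMI five-class
conventions. This note records the model, the defaults and their
rationale, the numerical choices, and what the synthetic test bed does
and does not establish.

## Problem setting and evaluation discipline

Beats carry one of five AAMI EC57 superclasses — N (normal, bundle
branch block, escape), S (supraventricular ectopic), V (ventricular
ectopic), F (ventricular/normal fusion), Q (paced or unclassifiable).
The native PhysioNet beat symbols map onto these five classes through a
fifteen-row table shipped as data (`data/beat_symbols.csv`); non-beat
annotations (rhythm changes, signal quality) are skipped, and unknown
symbols are rejected rather than guessed.

Evaluation follows the inter-patient paradigm: the 44 usable MIT-BIH
records are split into fixed, disjoint 22-record sets DS1 (training)
and DS2 (testing), so no patient contributes beats to both sides. The
four paced records (102, 104, 107, 217) are excluded per AAMI practice;
the exclusion set is exposed in the API because the convention, not a
list printed alongside the split, defines it. Only the MLII lead is
used; loading fails loudly if a record lacks it.

## Segmentation

Windows are anchored on the annotated R sample (no detector is run).
Two geometries matter:

* **signal-508** — 250 samples before the R peak, the R sample, 257
  after (508 total ≈ 1.4 s at 360 Hz). At a typical RR interval of
  0.6–1.0 s this window reaches into the neighbouring beats, so the
  network can see *timing context* — a premature supraventricular beat
  drags its predecessor's QRS into the left part of the window —
  without any hand-extracted RR features.
* **signal-256** — the traditional single-beat window. Its pre/post
  split is a convention the window length alone does not fix; we centre
  it (127 before, 128 after), mirroring the R-sample-inclusive layout
  of the 508 window. The split is a config field, so other conventions
  remain expressible.

Windows are verbatim signal slices: no filtering, baseline correction
or amplitude normalisation anywhere in the pipeline. Beats whose
window crosses a record boundary are dropped by default (`pad-edge`
repeats edge values instead); edge beats are a negligible fraction of a
30-minute record, and dropping keeps every emitted window a pure slice.

## Re-sampling

Training pools are severely imbalanced (~90% N). Each ensemble
member's training multiset is rebuilt as:

* N: random subsample **without replacement** to 11188;
* S: duplication-based oversampling to 7544; V: to 4592 — every
  original beat kept, full round-robin copies added while they fit,
  remainder drawn without replacement, so per-beat multiplicities never
  differ by more than one;
* F and Q: passed through unchanged.

S is deliberately the largest abnormal class — the class every
single-beat method struggles with gets the most training mass — and N
ends up just below half the multiset (47.1% with DS1-sized pools). The
oversampling is exact duplication, not interpolation: synthesising new
waveforms would contradict the raw-signal design. Only the N subsample
differs between members; the S/V/F/Q draws are shared. Ensemble
diversity therefore comes entirely from which normal beats each member
sees. Seeds derive from `(base_seed, member_index)` via
`numpy.random.SeedSequence`, making every multiset bit-reproducible
across platforms.

## Loss

For true-class probability `p_t` the per-beat loss is

    L = -a_t (1 - p_t)^γ log p_t ,    γ = 2.35,
    a = {N: 1.6, S: 1.8, V: 0.8, F: 1.0, Q: 1.0}.

`p_t` is the softmax probability of the true class. The modulating
factor suppresses confidently-correct beats, concentrating gradient on
the hard ones; the weights tilt attention toward S and away from the
comparatively easy V. Weights are used raw — only their ratio matters,
a global scale is absorbed by the learning rate. `p_t` is floored at
1e-12 before the log so a degenerate probability produces a large
finite loss, never a non-finite gradient. At γ=0 with unit weights the
loss, and its analytic logit gradient, reduce exactly to softmax
cross-entropy; both facts are tested.

## Base network

Nine 1-D convolutions, kernel 17, stride 1, "same" padding; 20 filters
in layers 1–5, 40 in layers 6–9; batch normalisation after every
convolution; Tanh after layer 1, ReLU elsewhere; 40% dropout after
layers 3–9. Skip connections span consecutive layer pairs (2-3, 4-5,
6-7, 8-9); the one channel-width change (20→40, layers 6-7) uses a 1×1
projection on the skip path. After the last skip a further
batch-norm + ReLU is applied, then global average pooling and a single
fully connected layer to the 5-way softmax. The skip endpoints, the
projection, and the pooling-free body are declared design choices:
standard residual practice consistent with the stated layer plan, with
the topology data-driven from `ArchitectureSpec` so alternatives remain
testable.

The network, its backpropagation and the Adam optimiser are implemented
directly in numpy (float32, channels-last so convolution reduces to
contiguous-memory im2col plus single BLAS matmuls). Correctness is
established by finite-difference gradient checks of the full topology
in float64. Everything — initialisation (He), dropout masks, batch
order — is driven by explicit seeds; two builds from one seed are
bit-identical, and evaluation-mode forward passes are deterministic.

Optimiser, schedule and batch size are not part of the model contract;
defaults are Adam at 1e-3, batch 128, up to 60 epochs with early
stopping on a held-out 10% of the training multiset (patience 8), all
exposed in `TrainingConfig`.

## Ensemble

Six members by default, each trained on its own multiset. Prediction
is a hard plurality vote over member argmaxes. Ties (possible with six
voters) fall back to the largest probability mass summed across
members, then to canonical class order N < S < V < F < Q — a fully
deterministic chain. Soft probability-averaging is available behind
`voting="soft"` but hard voting is the default reading of a "voting"
ensemble.

## Metrics

Per-class Sen/+P/Spe use the one-vs-rest confusion-matrix reduction.
Overall metrics follow the AAMI abnormal-vs-normal reading: Acc is the
five-class trace over the total, while overall TP counts abnormal beats
classified as **their own** abnormal class, FN abnormal beats called
normal, FP normal beats called abnormal, TN normal-as-normal. Abnormal
beats predicted as a *different* abnormal class therefore enter Acc
only — the unique convention under which the published inter-patient
confusion matrix (shipped as `data/reference_confusion.csv`) reproduces
every printed summary number; it is locked in by tests and by an
independent brute-force oracle on random matrices. Ratios with zero
denominators are reported as explicitly undefined (`None`), never
silently zero — the reference matrix itself has no predicted Q beats,
so +P(Q) *is* undefined. Printed-table comparisons round half-up to
two decimals (the published base-classifier accuracy mean is exactly
87.625, printed 87.63).

## Synthetic test bed

The generator writes annotated records in which each beat is a sum of
Gaussian waves (P, QRS deflections, T) on a baseline-wander sinusoid
plus white noise, with beats scheduled by a jittered RR process.  Class
structure mirrors what makes the real task hard: V beats are wide,
high-amplitude and easy; S beats reuse normal morphology but fire at a
configurable fraction (default 0.55) of the nominal RR interval with a
compensatory pause after; class proportions default to the ~90%-N
imbalance of the inter-patient training corpus.  Per-record wave
amplitude/width scatter and per-record prematurity scatter emulate
inter-patient variability, so cues learned on training records
generalise only partially to unseen records.  Generation is
deterministic to the byte under the config seed.

The timing-discrimination corpus makes S and N templates *identical* (a
P-QRS complex without a T wave, since a trailing repolarisation wave
would leak timing information into even a single-beat window): there
the only evidence for S is where the neighbouring beats fall, which is
precisely the quantity the window-length ablation manipulates.

What the synthetic bed does **not** contain: real morphological overlap
between S and N families across patients, non-Gaussian noise and
artefacts, atrial fibrillation and other rhythm context, electrode or
lead variation. Passing the synthetic studies therefore shows the
pipeline's mechanisms work and its claims hold in a controlled regime;
it does not certify the published real-data operating numbers, which
require the real corpus and full-scale training.

## Scaled-down study conditions

The three pipeline-level studies run with a thinner member network of
identical topology (8/16 filters instead of 20/40) and small corpora,
chosen once as single-CPU-friendly study conditions:

* **end-to-end smoke** — 20 easy N/V records of 120 s (~3000 beats),
  508 windows, 2 members, 8 epochs at batch 16, lr 2e-3,
  600+600-segment multisets; expected to reach ≥90% test accuracy.
* **window ablation** — per replicate, 8 timing-corpus records of 90 s
  (5 train / 3 test), one member per window geometry, 14 epochs at
  batch 8, lr 2e-3, N=300/S=120 multisets; compared on S sensitivity.
* **ensemble gain** — 9 imbalanced records of 120 s (6 train / 3 test),
  256 windows, 3 members, 6 epochs at batch 16; ensemble accuracy
  against the mean member accuracy.

Small-sample training of a deep network is inherently noisy, which is
why the two comparative studies are stated over 10 seeded replicates
(≥8 of 10) rather than per-seed.

## Known limitations

* The residual topology details (exact skip endpoints, projection,
  head width) are declared assumptions; alternatives plug into
  `ArchitectureSpec`.
* "Incremental" oversampling is realised as exact duplication; if a
  jittered or interpolating variant is wanted, the operator is
  pluggable.
* The WFDB support is a minimal reader/writer (header, signal formats
  16 and 212, MIT annotation streams including SKIP/AUX escapes) —
  enough for MIT-BIH-style records and round-trip tested at byte
  level, not a general WFDB implementation.
* Full-scale training on real data is out of scope for the test suite;
  the acceptance studies are the scaled-down synthetic ones above plus
  exact metric reproduction from the shipped reference confusion
  matrix.
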