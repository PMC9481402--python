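# beatvote

Inter-patient arrhythmia classification from single-lead ECG, built
around four ideas that target the two things that make the problem
hard — extreme class imbalance and patient-to-patient variability:

1. **Extended-window segmentation.** Each heartbeat is a raw,
   unfiltered 508-sample window (250 before the annotated R peak, 257
   after; ≈1.4 s at 360 Hz) instead of the traditional 256-sample
   single-beat window. The longer window reaches into neighbouring
   beats, so prematurely-timed supraventricular ectopic beats (S) —
   whose morphology is nearly normal — become distinguishable without
   hand-extracted RR features.
2. **Class-targeted re-sampling.** Per ensemble member, the normal
   class N is randomly undersampled to 11188 and the minority classes
   oversampled by near-uniform duplication (S→7544, V→4592, F and Q
   unchanged), making S the largest abnormal class in every training
   multiset.
3. **Weighted focal loss.** `L = -a_t (1-p_t)^γ log p_t` with γ = 2.35
   and weights N:S:V:F:Q = 1.6:1.8:0.8:1.0:1.0, concentrating training
   on hard beats.
4. **A voting ensemble of residual 1-D CNNs.** Six base networks
   (nine conv layers, kernel 17, 20/40 filters, batch norm, 40%
   dropout, pairwise skip connections, global average pooling) that
   differ only in their N subsample; prediction is a hard plurality
   vote with deterministic tie-breaking.

Evaluation follows the AAMI five-class conventions (N, S, V, F, Q) on
the inter-patient DS1/DS2 record split, with per-class one-vs-rest
Sen/+P/Spe and overall metrics in the abnormal-vs-normal reading.

The package reads WFDB-layout records (`.hea`/`.dat`/`.atr`, signal
formats 16 and 212) and a plain CSV dialect, and includes a synthetic
ECG generator with class-conditional morphology and RR structure, so
every stage — including end-to-end training studies — runs without any
dataset download. The CNN and its training loop are implemented
directly in numpy; no deep-learning framework is required.

## Worked example

Evaluate the shipped reference confusion matrix (the published
inter-patient test-set result of the six-member ensemble):

```python
from beatvote.metrics import load_reference_confusion, compute_report

report = compute_report(load_reference_confusion())
print(report.format_table())
```

prints

```
class     Sen%      +P%     Spe%
    N    93.15    98.18    86.00
    S    80.23    49.40    96.85
    V    90.99    83.09    98.72
    F    12.63     4.05    97.65
    Q     0.00    undef   100.00

overall  Acc 91.89  +P 59.51  Sen 85.37  Spe 93.15
```

Row S reads: 80.23% of true supraventricular ectopic beats were
recognised, 49.40% of S calls were correct, and 96.85% of non-S beats
were not called S. The overall row: 91.89% of all beats got their
exact class; among abnormal-vs-normal decisions, 85.37% of abnormal
beats were caught (Sen) and 93.15% of normals were kept normal (Spe).
`+P(Q)` is `undef` because no beat was predicted Q — undefined ratios
are surfaced, never zeroed.

Train a small ensemble end-to-end on synthetic data:

```python
import beatvote as bv
from beatvote.pipeline import RunConfig, run_pipeline
from beatvote.network import TrainingConfig
from beatvote.dataset import AamiClass

corpus = bv.generate_corpus(bv.easy_two_class_config(seed=1), n_records=8)
records = [s.record for s in corpus]
config = RunConfig.from_preset(
    "signal-508+focal+ensemble",
    n_members=2,
    architecture="scaled-down",
    sampling_targets={AamiClass.N: 300, AamiClass.V: 300},
    training=TrainingConfig(epochs=6, batch_size=16),
)
result = run_pipeline(config, records[:6], records[6:])
print(result.report.format_table())
```

The same stages are scriptable from the shell (`beatvote synth`,
`segment`, `sample`, `train`, `predict`, `evaluate`, `ablate`); run
`beatvote --help`.

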