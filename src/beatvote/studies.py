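"""Scaled-down synthetic studies of the pipeline's three design claims.

Full-scale training on the real inter-patient corpus takes hours; these
studies reproduce the qualitative behaviour of the system on synthetic
corpora small enough for a single CPU, using the same pipeline code
end to end.  The scaled-down conditions (corpus sizes, thinner member
networks of identical topology, epoch budgets) are fixed here, in one
place:

* :func:`end_to_end_smoke` — the whole chain (generate → segment →
  re-sample → train members → vote → metrics) on an easy, morphologically
  separable N/V corpus must reach high test accuracy.
* :func:`window_ablation_replicate` — on a corpus where supraventricular
  ectopy is marked **only** by premature timing, the 508-sample window
  should yield higher S sensitivity than the 256-sample window: the
  extended window sees the premature neighbour QRS, the single-beat
  window does not.
* :func:`ensemble_gain_replicate` — majority voting over members that
  differ only in their normal-class subsample should beat the average
  individual member.

Every study derives all randomness from one integer seed.
"""

from __future__ import annotations

import numpy as np

from .dataset import AamiClass
from .ensemble import EnsembleModel, classify_set, train_ensemble
from .losses import FocalLossParams
from .metrics import compute_report
from .network import ArchitectureSpec, TrainingConfig
from .pipeline import pool_by_class
from .segmentation import baseline_256_config, extended_window_config, segment_records
from .synthetic import (
    easy_two_class_config,
    generate_corpus,
    mitbih_like_config,
    timing_discrimination_config,
)

__all__ = [
    "end_to_end_smoke",
    "window_ablation_replicate",
    "ensemble_gain_replicate",
]

#: Thinner member network (same 9-layer residual topology) used by all
#: scaled-down studies.
STUDY_ARCHITECTURE = ArchitectureSpec.scaled_down()


def _split_corpus(synth_records, n_test):
    records = [s.record for s in synth_records]
    return records[:-n_test], records[-n_test:]


def end_to_end_smoke(
    seed: int = 0,
    *,
    n_records: int = 20,
    record_duration_s: float = 120.0,
    epochs: int = 8,
    n_members: int = 2,
) -> dict:
    """Run the full pipeline on an easy synthetic corpus (~3000 beats).

    Two-class N/V records with distinct QRS morphology; 508-sample
    windows, focal loss, a 2-member voting ensemble, ~1200-segment
    training multisets.  Returns the test metrics plus corpus bookkeeping.
    """
    corpus = generate_corpus(
        easy_two_class_config(seed=seed, record_duration_s=record_duration_s),
        n_records,
    )
    n_beats = sum(len(s.record.beats) for s in corpus)
    train_records, test_records = _split_corpus(corpus, n_test=7)
    window = extended_window_config()
    pools = pool_by_class(segment_records(train_records, window))
    ensemble = train_ensemble(
        pools,
        FocalLossParams(),
        TrainingConfig(learning_rate=2e-3, epochs=epochs, batch_size=16,
                       val_fraction=0.0),
        base_seed=seed,
        n_members=n_members,
        architecture=STUDY_ARCHITECTURE,
        sampling_targets={AamiClass.N: 600, AamiClass.V: 600},
    )
    test_segments = segment_records(test_records, window)
    report = compute_report(classify_set(ensemble, test_segments))
    return {
        "accuracy": report.overall.acc,
        "report": report,
        "n_corpus_beats": n_beats,
        "n_test_segments": len(test_segments),
        "n_members": n_members,
        "epochs": epochs,
    }


def _timing_run(seed: int, window_config) -> float | None:
    """One member trained on the premature-timing corpus; returns S Sen%."""
    corpus = generate_corpus(
        timing_discrimination_config(seed=seed, record_duration_s=90.0), 8
    )
    train_records, test_records = _split_corpus(corpus, n_test=3)
    pools = pool_by_class(segment_records(train_records, window_config))
    ensemble = train_ensemble(
        pools,
        FocalLossParams(),
        TrainingConfig(learning_rate=2e-3, epochs=14, batch_size=8,
                       val_fraction=0.0),
        base_seed=seed,
        n_members=1,
        architecture=STUDY_ARCHITECTURE,
        sampling_targets={AamiClass.N: 300, AamiClass.S: 120},
    )
    pairs = classify_set(ensemble, segment_records(test_records, window_config))
    return compute_report(pairs).per_class[AamiClass.S].sen


def window_ablation_replicate(seed: int) -> tuple[float | None, float | None]:
    """(S sensitivity with the 508 window, with the 256 window) for one seed."""
    return (
        _timing_run(seed, extended_window_config()),
        _timing_run(seed, baseline_256_config()),
    )


def ensemble_gain_replicate(
    seed: int, *, n_members: int = 3
) -> tuple[float, float]:
    """(ensemble accuracy, mean member accuracy) on an imbalanced corpus.

    Members share their minority-class draws and differ in the normal
    subsample, as in the full pipeline; 256-sample windows keep the
    replicate cheap.
    """
    corpus = generate_corpus(
        mitbih_like_config(seed=seed, record_duration_s=120.0), 9
    )
    train_records, test_records = _split_corpus(corpus, n_test=3)
    window = baseline_256_config()
    pools = pool_by_class(segment_records(train_records, window))
    targets = {
        AamiClass.N: 200,
        AamiClass.S: 100,
        AamiClass.V: 100,
        AamiClass.F: "unchanged",
        AamiClass.Q: "unchanged",
    }
    ensemble = train_ensemble(
        pools,
        FocalLossParams(),
        TrainingConfig(learning_rate=2e-3, epochs=6, batch_size=16,
                       val_fraction=0.0),
        base_seed=seed,
        n_members=n_members,
        architecture=STUDY_ARCHITECTURE,
        sampling_targets=targets,
    )
    test_segments = segment_records(test_records, window)
    ensemble_acc = compute_report(
        classify_set(ensemble, test_segments)
    ).overall.acc

    member_accs = []
    for member in ensemble.members:
        solo = EnsembleModel(members=[member])
        member_accs.append(
            compute_report(classify_set(solo, test_segments)).overall.acc
        )
    return ensemble_acc, float(np.mean(member_accs))
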