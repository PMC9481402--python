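"""Majority-voting ensemble of focal-loss base classifiers.

Six base networks are trained on six training multisets that share
their S/V/F/Q beats and differ only in which normal beats each member's
random N-subsample contains.  At prediction time each member casts a
hard vote (its argmax class); the plurality wins.  A tie is broken by
the largest summed member probability among the tied classes, and — in
the measure-zero event that even those are equal — by canonical class
order N < S < V < F < Q.  Soft (probability-averaging) voting is
available behind ``voting="soft"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import AAMI_CLASSES, AamiClass
from .losses import FocalLossParams
from .network import (
    ArchitectureSpec,
    TrainedClassifier,
    TrainingConfig,
    build_model,
    predict_proba_batch,
    train,
)
from .sampling import (
    STANDARD_TARGETS,
    SamplingConfig,
    _derive_seed,
    build_training_set,
    standard_sampling_config,
)
from .segmentation import BeatSegment, segments_to_matrix

__all__ = ["EnsembleModel", "train_ensemble", "vote", "classify_set"]

DEFAULT_N_MEMBERS = 6


@dataclass
class EnsembleModel:
    """A fixed roster of trained base classifiers plus the voting policy."""

    members: list[TrainedClassifier]
    voting: str = "hard"
    tie_break: str = "sum-probability"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        lengths = {m.input_length for m in self.members}
        if len(lengths) > 1:
            raise ValueError(f"members disagree on input_length: {sorted(lengths)}")
        if self.voting not in ("hard", "soft"):
            raise ValueError("voting must be 'hard' or 'soft'")

    @property
    def input_length(self) -> int:
        return self.members[0].input_length

    @property
    def n_members(self) -> int:
        return len(self.members)


def train_ensemble(
    ds1_pools: Mapping[AamiClass, Sequence[BeatSegment]],
    loss_params: FocalLossParams | None = None,
    training_config: TrainingConfig | None = None,
    base_seed: int = 0,
    *,
    n_members: int = DEFAULT_N_MEMBERS,
    architecture: ArchitectureSpec | None = None,
    sampling_targets: Mapping[AamiClass, int | str] | None = None,
) -> EnsembleModel:
    """Train ``n_members`` base classifiers on per-member training sets.

    Member ``i`` (1-based) samples with the config derived from
    ``(base_seed, i)``: its own N subsample, the shared S/V/F/Q draw.
    Model initialisation and batch shuffling seeds are derived from the
    same pair, so the whole ensemble is reproducible from ``base_seed``.
    """
    loss_params = loss_params or FocalLossParams()
    training_config = training_config or TrainingConfig()
    architecture = architecture or ArchitectureSpec.default()
    lengths = {len(s.samples) for pool in ds1_pools.values() for s in pool}
    if len(lengths) != 1:
        raise ValueError(f"pools must share one segment length, got {sorted(lengths)}")
    (input_length,) = lengths

    members: list[TrainedClassifier] = []
    for i in range(1, n_members + 1):
        try:
            if sampling_targets is None and n_members == DEFAULT_N_MEMBERS:
                cfg = standard_sampling_config(i, base_seed)
            else:
                cfg = SamplingConfig(
                    target_counts=dict(sampling_targets or STANDARD_TARGETS),
                    n_seed=_derive_seed(base_seed, i),
                    shared_seed=_derive_seed(base_seed, 0),
                )
            training_set = build_training_set(ds1_pools, cfg)
            model = build_model(
                input_length, architecture, seed=_derive_seed(base_seed, 100 + i)
            )
            member_tc = TrainingConfig(
                learning_rate=training_config.learning_rate,
                batch_size=training_config.batch_size,
                epochs=training_config.epochs,
                patience=training_config.patience,
                val_fraction=training_config.val_fraction,
                seed=_derive_seed(base_seed, 200 + i),
            )
            members.append(train(model, training_set, loss_params, member_tc))
        except Exception as exc:
            raise RuntimeError(f"training ensemble member {i} failed: {exc}") from exc
    return EnsembleModel(members=members)


def vote(
    member_predictions: Sequence[Mapping[AamiClass, float]],
    tie_break: str = "sum-probability",
) -> AamiClass:
    """Plurality vote over member argmax labels.

    Ties are resolved by the largest probability mass summed over the
    members (``tie_break="sum-probability"``), falling back to canonical
    class order.
    """
    if not member_predictions:
        raise ValueError("vote needs at least one member prediction")
    tallies = {cls: 0 for cls in AAMI_CLASSES}
    sums = {cls: 0.0 for cls in AAMI_CLASSES}
    for probs in member_predictions:
        best = max(AAMI_CLASSES, key=lambda c: probs[c])
        tallies[best] += 1
        for cls in AAMI_CLASSES:
            sums[cls] += probs[cls]
    top = max(tallies.values())
    tied = [cls for cls in AAMI_CLASSES if tallies[cls] == top]
    if len(tied) == 1 or tie_break != "sum-probability":
        return tied[0]
    return max(tied, key=lambda c: (sums[c], -list(AAMI_CLASSES).index(c)))


def _member_probs(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """(n_members, n_segments, 5) probability stack."""
    return np.stack([predict_proba_batch(m, X) for m in ensemble.members])


def classify_set(
    ensemble: EnsembleModel, segments: Sequence[BeatSegment]
) -> list[tuple[AamiClass, AamiClass]]:
    """Predict every segment, returning ``(true, predicted)`` pairs in order."""
    if not segments:
        return []
    for k, seg in enumerate(segments):
        if len(seg.samples) != ensemble.input_length:
            raise ValueError(
                f"segment {k} (record {seg.source_record}, R at {seg.r_index}) "
                f"has length {len(seg.samples)}, expected {ensemble.input_length}"
            )
    X, labels = segments_to_matrix(list(segments))
    stack = _member_probs(ensemble, X)  # (m, n, 5)
    if ensemble.voting == "soft":
        mean = stack.mean(axis=0)
        pred_idx = mean.argmax(axis=1)
        predictions = [AAMI_CLASSES[j] for j in pred_idx]
    else:
        predictions = []
        for n in range(stack.shape[1]):
            member_maps = [
                {cls: float(p) for cls, p in zip(AAMI_CLASSES, stack[m, n])}
                for m in range(stack.shape[0])
            ]
            predictions.append(vote(member_maps, ensemble.tie_break))
    return list(zip(labels, predictions))
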