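"""Class-targeted re-sampling of the training pool.

The inter-patient training set is heavily dominated by normal beats
(~90%).  Each ensemble member's training multiset is built by

* randomly **undersampling** the normal class N (without replacement) to
  a fixed target, with a different draw per member,
* **incrementally oversampling** the minority ectopic classes S and V to
  fixed targets by near-uniform duplication (every original kept, extra
  slots filled round-robin before a random remainder),
* passing F and Q through unchanged.

The default targets are N=11188, S=7544, V=4592, making S the largest
abnormal class (the hardest class is given the most training mass) and
leaving N at just under half of the training set.  Only the N subsample
differs between ensemble members; the S/V/F/Q multisets are shared, so
member diversity comes exclusively from which normal beats each member
sees.

Seeds are derived with :class:`numpy.random.SeedSequence` so a training
set rebuilt from the same ``(base_seed, member_index)`` is identical on
any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, TypeVar

import numpy as np

from .dataset import AAMI_CLASSES, AamiClass
from .segmentation import BeatSegment

__all__ = [
    "SamplingConfig",
    "TrainingSet",
    "STANDARD_TARGETS",
    "standard_sampling_config",
    "undersample",
    "oversample_incremental",
    "build_training_set",
]

T = TypeVar("T")

#: Default per-class training-set targets; "unchanged" keeps the source pool.
STANDARD_TARGETS: dict[AamiClass, int | str] = {
    AamiClass.N: 11188,
    AamiClass.S: 7544,
    AamiClass.V: 4592,
    AamiClass.F: "unchanged",
    AamiClass.Q: "unchanged",
}


@dataclass(frozen=True)
class SamplingConfig:
    """Re-sampling targets plus the seeds that make the draw reproducible.

    ``n_seed`` drives the undersampling of N and differs per ensemble
    member; ``shared_seed`` drives the oversampling of the remaining
    classes and is common to all members of one ensemble.
    """

    target_counts: Mapping[AamiClass, int | str]
    n_seed: int
    shared_seed: int

    def target_for(self, cls: AamiClass, pool_size: int) -> int:
        t = self.target_counts.get(cls, "unchanged")
        return pool_size if t == "unchanged" else int(t)


@dataclass(frozen=True)
class TrainingSet:
    """A re-sampled multiset of beat segments with its provenance."""

    segments: tuple[BeatSegment, ...]
    class_counts: dict[AamiClass, int]
    provenance: dict = field(default_factory=dict)


def _derive_seed(base_seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([base_seed, stream]).generate_state(1)[0])


def standard_sampling_config(classifier_index: int, base_seed: int) -> SamplingConfig:
    """Sampling config for ensemble member ``classifier_index`` (1..6).

    Every member shares one oversampling stream (identical S/V/F/Q
    multisets) but draws its own N subsample.
    """
    if not 1 <= classifier_index <= 6:
        raise ValueError(f"classifier_index must be in 1..6, got {classifier_index}")
    return SamplingConfig(
        target_counts=dict(STANDARD_TARGETS),
        n_seed=_derive_seed(base_seed, classifier_index),
        shared_seed=_derive_seed(base_seed, 0),
    )


def undersample(pool: Sequence[T], target: int, seed: int) -> list[T]:
    """Uniform random subset of ``pool`` of size ``target``, no replacement."""
    if target > len(pool):
        raise ValueError(
            f"undersample target {target} exceeds pool size {len(pool)}"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.choice(len(pool), size=target, replace=False)
    return [pool[i] for i in np.sort(idx)]


def oversample_incremental(pool: Sequence[T], target: int, seed: int) -> list[T]:
    """Grow ``pool`` to ``target`` items by near-uniform duplication.

    Every original appears at least once; full round-robin copies are
    added while they fit, and the remainder is a seeded random subset —
    so per-item multiplicities never differ by more than one.
    """
    n = len(pool)
    if n == 0:
        raise ValueError("cannot oversample an empty pool")
    if target < n:
        raise ValueError(f"oversample target {target} below pool size {n}")
    copies, remainder = divmod(target, n)
    out = list(pool) * copies
    if remainder:
        rng = np.random.Generator(np.random.PCG64(seed))
        idx = rng.choice(n, size=remainder, replace=False)
        out.extend(pool[i] for i in np.sort(idx))
    return out


def build_training_set(
    pools: Mapping[AamiClass, Sequence[BeatSegment]],
    config: SamplingConfig,
) -> TrainingSet:
    """Apply the per-class re-sampling plan and assemble one training set.

    Classes whose target is below the pool size are undersampled with
    the member-specific seed (N, by default); classes above are
    oversampled with the shared seed; equal targets pass through.
    """
    segments: list[BeatSegment] = []
    counts: dict[AamiClass, int] = {}
    for cls in AAMI_CLASSES:
        pool = list(pools.get(cls, ()))
        target = config.target_for(cls, len(pool))
        if not pool:
            if target:
                raise ValueError(f"class {cls.value}: empty pool with target {target}")
            counts[cls] = 0
            continue
        cls_seed = _derive_seed(
            config.n_seed if target < len(pool) else config.shared_seed,
            list(AAMI_CLASSES).index(cls),
        )
        if target < len(pool):
            chosen = undersample(pool, target, cls_seed)
        elif target > len(pool):
            chosen = oversample_incremental(pool, target, cls_seed)
        else:
            chosen = pool
        segments.extend(chosen)
        counts[cls] = len(chosen)
    return TrainingSet(
        segments=tuple(segments),
        class_counts=counts,
        provenance={
            "n_seed": config.n_seed,
            "shared_seed": config.shared_seed,
            "targets": {
                cls.value: config.target_counts.get(cls, "unchanged")
                for cls in AAMI_CLASSES
            },
            "source_counts": {cls.value: len(pools.get(cls, ())) for cls in AAMI_CLASSES},
        },
    )
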