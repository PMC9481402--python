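"""Fixed-length beat windows cut around annotated R-peaks.

Two window conventions are provided:

* :func:`extended_window_config` — a 508-sample window (250 samples
  before the R-peak, the R sample, 257 after).  At 360 Hz this spans
  about ±0.7 s and therefore usually contains parts of the neighbouring
  beats, so the classifier can see timing context (a supraventricular
  ectopic beat arrives early relative to its predecessor) without any
  hand-extracted RR features.
* :func:`baseline_256_config` — the traditional 256-sample single-beat
  window centred on the R-peak (127 before, 128 after), which mostly
  isolates one QRS-T complex.

Windows are raw signal slices: no filtering, detrending or amplitude
normalisation is applied at any point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import AamiClass, AnnotatedRecord

__all__ = [
    "SegmentationConfig",
    "BeatSegment",
    "extended_window_config",
    "baseline_256_config",
    "segment_record",
    "segment_records",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Window geometry around the annotated R sample.

    The window covers samples ``[r - pre_samples, r + post_samples]``
    inclusive, so its length is ``pre_samples + 1 + post_samples``.
    ``boundary_policy`` decides what happens when a window leaves the
    record: ``"drop"`` discards the beat, ``"pad-edge"`` repeats the
    first/last sample value.
    """

    pre_samples: int
    post_samples: int
    boundary_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.pre_samples < 0 or self.post_samples < 0:
            raise ValueError("pre_samples and post_samples must be >= 0")
        if self.boundary_policy not in ("drop", "pad-edge"):
            raise ValueError("boundary_policy must be 'drop' or 'pad-edge'")

    @property
    def window_length(self) -> int:
        return self.pre_samples + 1 + self.post_samples


@dataclass(frozen=True)
class BeatSegment:
    """One fixed-length window of raw samples with its AAMI label."""

    samples: np.ndarray
    label: AamiClass
    source_record: str
    r_index: int


def extended_window_config(boundary_policy: str = "drop") -> SegmentationConfig:
    """The 508-sample extended window: 250 before the R-peak, 257 after."""
    return SegmentationConfig(
        pre_samples=250, post_samples=257, boundary_policy=boundary_policy
    )


def baseline_256_config(boundary_policy: str = "drop") -> SegmentationConfig:
    """The traditional 256-sample single-beat window, centred on the R-peak.

    The exact pre/post split of the traditional window is a convention;
    here it is symmetric up to the odd sample (127 before, 128 after),
    matching how the 508 window also includes the R sample itself.
    """
    return SegmentationConfig(
        pre_samples=127, post_samples=128, boundary_policy=boundary_policy
    )


def segment_record(
    record: AnnotatedRecord, config: SegmentationConfig
) -> list[BeatSegment]:
    """Cut one window per annotated beat.

    Under ``"drop"`` only beats whose full window lies inside the signal
    are emitted; under ``"pad-edge"`` every beat is emitted, with
    out-of-range samples filled by the signal's edge values.  Emitted
    samples are verbatim copies of the signal (float64), never filtered.
    """
    sig = record.signal
    n = len(sig)
    segments: list[BeatSegment] = []
    for r, label in record.beats:
        lo, hi = r - config.pre_samples, r + config.post_samples + 1
        if lo >= 0 and hi <= n:
            window = sig[lo:hi].copy()
        elif config.boundary_policy == "drop":
            continue
        else:
            window = sig[max(lo, 0) : min(hi, n)]
            window = np.pad(
                window, (max(0, -lo), max(0, hi - n)), mode="edge"
            )
        segments.append(
            BeatSegment(
                samples=window,
                label=label,
                source_record=record.record_id,
                r_index=r,
            )
        )
    return segments


def segment_records(
    records, config: SegmentationConfig
) -> list[BeatSegment]:
    """Concatenate :func:`segment_record` over many records, in order."""
    out: list[BeatSegment] = []
    for record in records:
        out.extend(segment_record(record, config))
    return out


def segments_to_matrix(segments: list[BeatSegment]) -> tuple[np.ndarray, list[AamiClass]]:
    """Stack segments into a (n_beats, window_length) matrix plus labels."""
    if not segments:
        return np.empty((0, 0)), []
    lengths = {len(s.samples) for s in segments}
    if len(lengths) > 1:
        raise ValueError(f"mixed segment lengths: {sorted(lengths)}")
    X = np.stack([s.samples for s in segments])
    return X, [s.label for s in segments]
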