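"""End-to-end orchestration: load → segment → sample → train → vote → report.

Four presets correspond to the ablation grid of the classification
system — the full method and the three single-component removals:

======================================  ========  =============  ========
preset                                  window    loss           members
======================================  ========  =============  ========
``signal-508+focal+ensemble`` (main)    508       focal          6
``signal-256+focal+ensemble``           256       focal          6
``signal-508+ensemble``                 508       cross-entropy  6
``signal-508+focal``                    508       focal          1
======================================  ========  =============  ========

Each run writes a provenance manifest (preset, seeds, targets, training
config) alongside its confusion matrix and metrics report, sufficient
to re-run it exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .dataset import AAMI_CLASSES, AamiClass, AnnotatedRecord
from .ensemble import EnsembleModel, classify_set, train_ensemble
from .losses import FocalLossParams
from .metrics import ConfusionMatrix5, MetricsReport, compute_report
from .network import ArchitectureSpec, TrainingConfig
from .sampling import STANDARD_TARGETS
from .segmentation import (
    SegmentationConfig,
    baseline_256_config,
    extended_window_config,
    segment_records,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "PRESETS",
    "run_pipeline",
    "evaluate_only",
    "pool_by_class",
]

PRESETS: dict[str, dict] = {
    "signal-508+focal+ensemble": {"window": "signal-508", "loss": "focal", "ensemble": True},
    "signal-256+focal+ensemble": {"window": "signal-256", "loss": "focal", "ensemble": True},
    "signal-508+ensemble": {"window": "signal-508", "loss": "cross-entropy", "ensemble": True},
    "signal-508+focal": {"window": "signal-508", "loss": "focal", "ensemble": False},
}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run, fully determined by its fields plus the seeds."""

    window: str = "signal-508"  # "signal-508" | "signal-256"
    loss: str = "focal"  # "focal" | "cross-entropy"
    ensemble: bool = True
    n_members: int | None = None  # default: 6 if ensemble else 1
    architecture: str = "default"  # "default" | "scaled-down"
    sampling_targets: Mapping[AamiClass, int | str] | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    gamma: float = 2.35
    base_seed: int = 0
    preset_name: str | None = None

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides, "preset_name": name})

    def segmentation_config(self) -> SegmentationConfig:
        if self.window == "signal-508":
            return extended_window_config()
        if self.window == "signal-256":
            return baseline_256_config()
        raise ValueError(f"unknown window {self.window!r}")

    def loss_params(self) -> FocalLossParams:
        if self.loss == "focal":
            return FocalLossParams(gamma=self.gamma)
        if self.loss == "cross-entropy":
            return FocalLossParams.cross_entropy_equivalent()
        raise ValueError(f"unknown loss {self.loss!r}")

    def architecture_spec(self) -> ArchitectureSpec:
        if self.architecture == "default":
            return ArchitectureSpec.default()
        if self.architecture == "scaled-down":
            return ArchitectureSpec.scaled_down()
        raise ValueError(f"unknown architecture {self.architecture!r}")

    def member_count(self) -> int:
        if self.n_members is not None:
            return self.n_members
        return 6 if self.ensemble else 1

    def to_manifest(self) -> dict:
        return {
            "preset": self.preset_name,
            "window": self.window,
            "loss": self.loss,
            "ensemble": self.ensemble,
            "n_members": self.member_count(),
            "architecture": self.architecture,
            "gamma": self.gamma if self.loss == "focal" else 0.0,
            "sampling_targets": {
                cls.value: (self.sampling_targets or STANDARD_TARGETS).get(cls, "unchanged")
                for cls in AAMI_CLASSES
            },
            "training": asdict(self.training),
            "base_seed": self.base_seed,
        }


@dataclass
class PipelineResult:
    report: MetricsReport
    ensemble: EnsembleModel
    manifest: dict


def pool_by_class(segments) -> dict[AamiClass, list]:
    pools: dict[AamiClass, list] = {cls: [] for cls in AAMI_CLASSES}
    for seg in segments:
        pools[seg.label].append(seg)
    return {cls: pool for cls, pool in pools.items() if pool}


def run_pipeline(
    config: RunConfig,
    train_records: Sequence[AnnotatedRecord],
    test_records: Sequence[AnnotatedRecord],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute one full run and optionally write its artifacts.

    Stages: segment the training records, build per-member training
    multisets, train the member networks, segment and classify the test
    records, and derive the metrics report.  Stage failures are
    re-raised with the stage name prefixed.
    """

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}': {exc}") from exc

    seg_cfg = config.segmentation_config()
    train_segments = stage(
        "segment-train", lambda: segment_records(train_records, seg_cfg)
    )
    pools = stage("pool", lambda: pool_by_class(train_segments))
    ensemble = stage(
        "train",
        lambda: train_ensemble(
            pools,
            config.loss_params(),
            config.training,
            config.base_seed,
            n_members=config.member_count(),
            architecture=config.architecture_spec(),
            sampling_targets=config.sampling_targets,
        ),
    )
    test_segments = stage(
        "segment-test", lambda: segment_records(test_records, seg_cfg)
    )
    pairs = stage("classify", lambda: classify_set(ensemble, test_segments))
    report = stage("metrics", lambda: compute_report(pairs))

    manifest = config.to_manifest()
    manifest["n_train_segments"] = len(train_segments)
    manifest["n_test_segments"] = len(test_segments)
    manifest["train_records"] = [r.record_id for r in train_records]
    manifest["test_records"] = [r.record_id for r in test_records]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.confusion.to_csv(out_dir / "confusion.csv")
        report.to_json(out_dir / "report.json")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        from .network import save_classifier

        for i, member in enumerate(ensemble.members, start=1):
            save_classifier(member, out_dir / f"member{i}")
    return PipelineResult(report=report, ensemble=ensemble, manifest=manifest)


def evaluate_only(confusion_csv: str | Path) -> MetricsReport:
    """Metrics report straight from a stored 5x5 confusion-matrix CSV."""
    return compute_report(ConfusionMatrix5.from_csv(confusion_csv))
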