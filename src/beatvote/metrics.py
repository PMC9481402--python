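"""AAMI-style evaluation: 5x5 confusion matrix, per-class and overall metrics.

Per-class metrics use the one-vs-rest convention: for class ``c``,
``TP = cm[c, c]``, ``FN`` its row remainder, ``FP`` its column
remainder, ``TN`` everything else, then

    Acc = (TP + TN) / (TP + FP + TN + FN),   Sen = TP / (TP + FN),
    +P  = TP / (TP + FP),                    Spe = TN / (TN + FP).

The **overall** metrics follow the AAMI abnormal-vs-normal reading:
accuracy is the 5-class trace over the total, while Sen/+P/Spe collapse
to abnormal-vs-N — ``TP`` counts abnormal beats classified as *their
own* abnormal class, ``FN`` abnormal beats called normal, ``FP`` normal
beats called abnormal, ``TN`` normal beats called normal.  Abnormal
beats predicted as a *different* abnormal class therefore affect
accuracy only; this is the convention under which the published
inter-patient confusion matrix reproduces its printed summary numbers.

A metric whose denominator is zero (e.g. precision of a class that is
never predicted) is reported as ``None`` — explicitly undefined, never
silently zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import AAMI_CLASSES, AamiClass

__all__ = [
    "ConfusionMatrix5",
    "PerClassMetrics",
    "OverallMetrics",
    "MetricsReport",
    "build_confusion",
    "per_class_metrics",
    "overall_metrics",
    "compute_report",
    "classifier_table",
    "round_half_up",
    "load_reference_confusion",
    "load_reference_base_table",
]

_ORDER = [c.value for c in AAMI_CLASSES]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed tables round 0.005 upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix5:
    """5x5 beat counts; rows = true class, columns = predicted, order N,S,V,F,Q."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (5, 5):
            raise ValueError(f"confusion matrix must be 5x5, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
                raise ValueError("confusion counts must be non-negative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, cls: AamiClass) -> int:
        return int(self.counts[_idx(cls)].sum())

    def col_sum(self, cls: AamiClass) -> int:
        return int(self.counts[:, _idx(cls)].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=_ORDER, columns=_ORDER)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix5":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != _ORDER or list(df.columns) != _ORDER:
            raise ValueError(
                f"{path}: expected rows and columns labelled {_ORDER}, "
                f"got rows {list(df.index)} columns {list(df.columns)}"
            )
        return cls(df.to_numpy())


def _idx(cls: AamiClass) -> int:
    return AAMI_CLASSES.index(cls)


def build_confusion(
    pairs: Iterable[tuple[AamiClass, AamiClass]]
) -> ConfusionMatrix5:
    """Count (true, predicted) pairs into a ConfusionMatrix5."""
    counts = np.zeros((5, 5), dtype=np.int64)
    for true, pred in pairs:
        counts[_idx(true), _idx(pred)] += 1
    return ConfusionMatrix5(counts)


@dataclass(frozen=True)
class PerClassMetrics:
    """One-vs-rest Sen/+P/Spe (percent); None marks an undefined ratio."""

    sen: float | None
    ppv: float | None
    spe: float | None


@dataclass(frozen=True)
class OverallMetrics:
    """Overall Acc (5-class) and abnormal-vs-normal +P/Sen/Spe (percent)."""

    acc: float | None
    ppv: float | None
    sen: float | None
    spe: float | None


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def per_class_metrics(cm: ConfusionMatrix5, cls: AamiClass) -> PerClassMetrics:
    i = _idx(cls)
    tp = int(cm.counts[i, i])
    fn = cm.row_sum(cls) - tp
    fp = cm.col_sum(cls) - tp
    tn = cm.total - tp - fn - fp
    return PerClassMetrics(
        sen=_ratio(tp, tp + fn),
        ppv=_ratio(tp, tp + fp),
        spe=_ratio(tn, tn + fp),
    )


def overall_metrics(cm: ConfusionMatrix5) -> OverallMetrics:
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = _idx(AamiClass.N)
    abnormal = [j for j in range(5) if j != n]
    tp = int(sum(c[j, j] for j in abnormal))
    fn = int(sum(c[j, n] for j in abnormal))
    fp = int(sum(c[n, j] for j in abnormal))
    tn = int(c[n, n])
    return OverallMetrics(
        acc=_ratio(int(np.trace(c)), cm.total),
        ppv=_ratio(tp, tp + fp),
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and overall metrics for one classification run."""

    confusion: ConfusionMatrix5
    per_class: dict[AamiClass, PerClassMetrics]
    overall: OverallMetrics

    def to_dict(self, ndigits: int | None = 2) -> dict:
        def r(v):
            if v is None:
                return None
            return round_half_up(v, ndigits) if ndigits is not None else v

        return {
            "overall": {
                "acc": r(self.overall.acc),
                "ppv": r(self.overall.ppv),
                "sen": r(self.overall.sen),
                "spe": r(self.overall.spe),
            },
            "per_class": {
                cls.value: {
                    "sen": r(m.sen),
                    "ppv": r(m.ppv),
                    "spe": r(m.spe),
                }
                for cls, m in self.per_class.items()
            },
            "confusion": self.confusion.counts.tolist(),
        }

    def to_json(self, path: str | Path | None = None, ndigits: int | None = 2) -> str:
        text = json.dumps(self.to_dict(ndigits), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def format_table(self) -> str:
        """Plain-text layout: confusion counts, per-class rows, overall row."""
        lines = ["Confusion matrix (rows = true, cols = predicted)"]
        lines.append(self.confusion.to_frame().to_string())
        lines.append("")
        lines.append(f"{'class':>5} {'Sen%':>8} {'+P%':>8} {'Spe%':>8}")
        for cls, m in self.per_class.items():
            vals = [
                "undef" if v is None else f"{round_half_up(v):.2f}"
                for v in (m.sen, m.ppv, m.spe)
            ]
            lines.append(f"{cls.value:>5} {vals[0]:>8} {vals[1]:>8} {vals[2]:>8}")
        o = self.overall
        vals = [
            "undef" if v is None else f"{round_half_up(v):.2f}"
            for v in (o.acc, o.ppv, o.sen, o.spe)
        ]
        lines.append("")
        lines.append(
            f"overall  Acc {vals[0]}  +P {vals[1]}  Sen {vals[2]}  Spe {vals[3]}"
        )
        return "\n".join(lines)


def compute_report(
    source: ConfusionMatrix5 | Iterable[tuple[AamiClass, AamiClass]]
) -> MetricsReport:
    """Full report from a confusion matrix or raw (true, predicted) pairs."""
    cm = source if isinstance(source, ConfusionMatrix5) else build_confusion(source)
    return MetricsReport(
        confusion=cm,
        per_class={cls: per_class_metrics(cm, cls) for cls in AAMI_CLASSES},
        overall=overall_metrics(cm),
    )


def classifier_table(
    reports: Sequence[MetricsReport | OverallMetrics | Sequence[float]],
) -> pd.DataFrame:
    """Overall metrics per base classifier plus an unweighted mean row.

    Accepts full reports, ``OverallMetrics`` or plain ``(acc, ppv, sen,
    spe)`` rows; the mean row is the arithmetic mean of each column.
    """
    if not len(reports):
        raise ValueError("classifier_table needs at least one report")
    rows = []
    for rep in reports:
        if isinstance(rep, MetricsReport):
            o = rep.overall
            rows.append([o.acc, o.ppv, o.sen, o.spe])
        elif isinstance(rep, OverallMetrics):
            rows.append([rep.acc, rep.ppv, rep.sen, rep.spe])
        else:
            rows.append(list(rep))
    df = pd.DataFrame(rows, columns=["acc", "ppv", "sen", "spe"])
    df.index = [str(i + 1) for i in range(len(rows))]
    df.loc["mean"] = df.mean(axis=0)
    return df


def load_reference_confusion() -> ConfusionMatrix5:
    """The published inter-patient ensemble confusion matrix (DS2 test set)."""
    with resources.as_file(
        resources.files("beatvote").joinpath("data/reference_confusion.csv")
    ) as path:
        return ConfusionMatrix5.from_csv(path)


def load_reference_base_table() -> pd.DataFrame:
    """Published overall metrics of the six base classifiers (percent)."""
    text = resources.files("beatvote").joinpath(
        "data/reference_base_classifiers.csv"
    ).read_text()
    import io

    return pd.read_csv(io.StringIO(text), index_col="member")
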