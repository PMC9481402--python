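"""Annotated ECG records, AAMI beat classes, and the inter-patient record split.

The MIT-BIH arrhythmia database annotates every heartbeat with a native
PhysioNet beat symbol (``N``, ``L``, ``A``, ``V``, ``/`` ...).  For
arrhythmia-classifier evaluation the AAMI EC57 practice collapses these
into five superclasses:

* **N** — normal, bundle-branch block and escape beats,
* **S** — supraventricular ectopic beats,
* **V** — ventricular ectopic beats,
* **F** — fusion of ventricular and normal beats,
* **Q** — paced, paced-fusion and unclassifiable beats.

This module loads annotated single-lead records (WFDB layout or a plain
CSV dialect), applies the symbol mapping, and provides the standard
inter-patient DS1 (train) / DS2 (test) partition of the 44 non-paced
records, so that training and evaluation never share a patient.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AamiClass",
    "AnnotatedRecord",
    "DatasetSplit",
    "UnknownSymbolError",
    "AAMI_CLASSES",
    "NON_BEAT_SYMBOLS",
    "beat_symbol_table",
    "map_symbol_to_aami",
    "standard_split",
    "load_record",
    "write_record_csv",
    "count_beats_per_class",
]


class AamiClass(enum.Enum):
    """The five AAMI EC57 heartbeat superclasses, in canonical order."""

    N = "N"
    S = "S"
    V = "V"
    F = "F"
    Q = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical class order used by every confusion matrix and report.
AAMI_CLASSES: tuple[AamiClass, ...] = (
    AamiClass.N,
    AamiClass.S,
    AamiClass.V,
    AamiClass.F,
    AamiClass.Q,
)

#: Annotation symbols that mark rhythm changes, signal quality, waveform
#: boundaries etc.  They are not heartbeats and are silently skipped when
#: loading a record.
NON_BEAT_SYMBOLS: frozenset[str] = frozenset(
    '+~|"=pt u`\'^[]!x()sT*@D'.replace(" ", "")
)


class UnknownSymbolError(ValueError):
    """Raised for an annotation symbol outside the AAMI beat mapping."""


def beat_symbol_table() -> dict[str, AamiClass]:
    """Native beat symbol -> AAMI class mapping, loaded from the shipped table.

    The table (``data/beat_symbols.csv``) is data, not code, so the
    fifteen symbol/superclass assignments can be audited in one place.
    """
    table: dict[str, AamiClass] = {}
    text = resources.files("beatvote").joinpath("data/beat_symbols.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        table[row["symbol"]] = AamiClass(row["aami_class"])
    return table


_SYMBOL_TABLE = beat_symbol_table()

#: WFDB annotation-code <-> symbol correspondence for the beat symbols above.
ATR_CODE_TO_SYMBOL: dict[int, str] = {}
_text = resources.files("beatvote").joinpath("data/beat_symbols.csv").read_text()
for _row in csv.DictReader(_text.splitlines()):
    ATR_CODE_TO_SYMBOL[int(_row["atr_code"])] = _row["symbol"]
del _text, _row


def map_symbol_to_aami(symbol: str) -> AamiClass:
    """Map a native beat annotation symbol to its AAMI superclass.

    Raises
    ------
    UnknownSymbolError
        If ``symbol`` is not one of the fifteen beat symbols in the
        mapping table (rhythm/quality markers included) — the caller
        decides whether to skip or abort.
    """
    try:
        return _SYMBOL_TABLE[symbol]
    except KeyError:
        raise UnknownSymbolError(
            f"annotation symbol {symbol!r} is not an AAMI-mapped beat symbol"
        ) from None


@dataclass(frozen=True)
class AnnotatedRecord:
    """One patient's single-lead waveform plus beat annotations.

    ``beats`` holds ``(r_index, label)`` pairs: the sample offset of each
    annotated R-peak and its AAMI class.  Indices are 0-based, strictly
    increasing and within the signal.
    """

    record_id: str
    signal: np.ndarray  # 1-D float array, lead MLII, millivolts
    sampling_rate: float  # samples per second
    beats: tuple[tuple[int, AamiClass], ...]

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        sig = np.asarray(self.signal, dtype=np.float64)
        object.__setattr__(self, "signal", sig)
        if sig.ndim != 1:
            raise ValueError("signal must be one-dimensional (single lead)")
        prev = -1
        for r, label in self.beats:
            if not isinstance(label, AamiClass):
                raise TypeError(f"beat label {label!r} is not an AamiClass")
            if not 0 <= r < len(sig):
                raise ValueError(
                    f"record {self.record_id}: R-index {r} outside signal "
                    f"of length {len(sig)}"
                )
            if r <= prev:
                raise ValueError(
                    f"record {self.record_id}: R-indices not strictly increasing at {r}"
                )
            prev = r

    @property
    def labels(self) -> tuple[AamiClass, ...]:
        return tuple(label for _, label in self.beats)

    @property
    def r_indices(self) -> np.ndarray:
        return np.array([r for r, _ in self.beats], dtype=np.int64)


@dataclass(frozen=True)
class DatasetSplit:
    """The inter-patient DS1/DS2 partition of MIT-BIH record IDs."""

    ds1_records: frozenset[str]
    ds2_records: frozenset[str]
    excluded_records: frozenset[str]


_DS1 = (
    "101 106 108 109 112 114 115 116 118 119 122 124 "
    "201 203 205 207 208 209 215 220 223 230"
).split()
_DS2 = (
    "100 103 105 111 113 117 121 123 200 202 210 212 "
    "213 214 219 221 222 228 231 232 233 234"
).split()
# Paced records excluded per AAMI EC57 practice; not in either set.
_EXCLUDED = ("102", "104", "107", "217")


def standard_split(excluded: Iterable[str] = _EXCLUDED) -> DatasetSplit:
    """The canonical 22/22 inter-patient DS1 (train) / DS2 (test) split.

    The four paced records are excluded entirely, following AAMI
    recommendations; the exclusion set is exposed for audit but the
    DS1/DS2 membership itself is fixed.
    """
    return DatasetSplit(
        ds1_records=frozenset(_DS1),
        ds2_records=frozenset(_DS2),
        excluded_records=frozenset(excluded),
    )


def _read_csv_record(
    signal_path: Path, annotation_path: Path, record_id: str, sampling_rate: float
) -> AnnotatedRecord:
    signal = np.loadtxt(signal_path, dtype=np.float64, ndmin=1)
    beats: list[tuple[int, AamiClass]] = []
    with open(annotation_path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].strip().lower() == "sample_index":
                continue
            try:
                r_index = int(row[0])
                symbol = row[1].strip()
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{annotation_path}:{lineno}: malformed annotation row {row!r}"
                ) from exc
            if symbol in NON_BEAT_SYMBOLS:
                continue
            try:
                label = map_symbol_to_aami(symbol)
            except UnknownSymbolError as exc:
                raise ValueError(f"{annotation_path}:{lineno}: {exc}") from None
            beats.append((r_index, label))
    return AnnotatedRecord(
        record_id=record_id,
        signal=signal,
        sampling_rate=sampling_rate,
        beats=tuple(beats),
    )


def load_record(
    path: str | Path,
    dialect: str = "wfdb",
    *,
    sampling_rate: float = 360.0,
    lead: str = "MLII",
) -> AnnotatedRecord:
    """Load one annotated record.

    Parameters
    ----------
    path
        For ``dialect="wfdb"``: the record path without extension (the
        ``.hea``/``.dat``/``.atr`` triple must exist).  For
        ``dialect="csv"``: the stem ``<path>.signal.csv`` /
        ``<path>.annotations.csv``.
    dialect
        ``"wfdb"`` or ``"csv"``.
    sampling_rate
        CSV dialect only (WFDB headers carry their own rate).
    lead
        Signal channel to select in WFDB records.  Loading fails if the
        named lead is absent rather than silently substituting another.
    """
    path = Path(path)
    if dialect == "csv":
        sig = path.with_suffix(path.suffix + ".signal.csv")
        ann = path.with_suffix(path.suffix + ".annotations.csv")
        if not sig.exists():
            raise FileNotFoundError(sig)
        if not ann.exists():
            raise FileNotFoundError(ann)
        return _read_csv_record(sig, ann, path.name, sampling_rate)
    if dialect == "wfdb":
        from . import wfdb_io

        return wfdb_io.read_record(path, lead=lead)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wfdb' or 'csv'")


def write_record_csv(
    record: AnnotatedRecord,
    path: str | Path,
    *,
    native_symbols: Sequence[str] | None = None,
) -> tuple[Path, Path]:
    """Write a record in the CSV fixture dialect (signal + annotation files).

    ``native_symbols`` optionally supplies per-beat native symbols (e.g.
    ``"A"`` for an atrial premature beat); by default each beat is written
    with a representative symbol of its AAMI class.
    """
    path = Path(path)
    sig_path = path.with_suffix(path.suffix + ".signal.csv")
    ann_path = path.with_suffix(path.suffix + ".annotations.csv")
    representative = {
        AamiClass.N: "N",
        AamiClass.S: "A",
        AamiClass.V: "V",
        AamiClass.F: "F",
        AamiClass.Q: "/",
    }
    np.savetxt(sig_path, record.signal, fmt="%.6f")
    with open(ann_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "label"])
        for i, (r, label) in enumerate(record.beats):
            sym = native_symbols[i] if native_symbols is not None else representative[label]
            writer.writerow([r, sym])
    return sig_path, ann_path


def count_beats_per_class(
    records: Iterable[AnnotatedRecord],
) -> dict[AamiClass, int]:
    """Total beat count per AAMI class over a collection of records."""
    counts = {cls: 0 for cls in AAMI_CLASSES}
    for record in records:
        for _, label in record.beats:
            counts[label] += 1
    return counts
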