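"""Minimal WFDB record support: .hea/.dat signals and MIT .atr annotations.

Implements just enough of the WFDB specification to read the MIT-BIH
arrhythmia records and to write compatible synthetic records:

* header (``.hea``) parsing — record line plus one signal-spec line per
  channel (file name, storage format, gain, baseline, description);
* signal formats **16** (little-endian int16) and **212** (two 12-bit
  samples packed in three bytes), interleaved across channels;
* MIT annotation (``.atr``) decoding — 2-byte words of
  ``(code << 10) | time-increment``, with the ``SKIP`` escape for long
  intervals (PDP-11 long: high word first, each word little-endian) and
  the ``NUM``/``SUB``/``CHN``/``AUX`` modifier codes.

Samples are converted to physical units as ``(adc - baseline) / gain``
(millivolts for MIT-BIH).  Writing uses format 16 with gain 200.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .dataset import (
    ATR_CODE_TO_SYMBOL,
    AnnotatedRecord,
    map_symbol_to_aami,
)

__all__ = ["read_record", "write_record", "read_annotations", "write_annotations"]

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_SYMBOL_TO_CODE = {sym: code for code, sym in ATR_CODE_TO_SYMBOL.items()}
# Non-beat codes that may appear in real annotation streams; skipped on read.
_KNOWN_NON_BEAT_CODES = frozenset(
    [14, 16, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33,
     36, 37, 39, 40, 41]
)


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_id = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt_field = parts[0], parts[1]
        fmt = int("".join(ch for ch in fmt_field.split("x")[0].split(":")[0]
                          if ch.isdigit() or ch == "-") or "16")
        gain, baseline, explicit_baseline = 200.0, 0, False
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
                explicit_baseline = True
            gain = float(g) or 200.0
        if not explicit_baseline:
            # baseline defaults to the ADC zero field when not given
            baseline = int(parts[4]) if len(parts) > 4 else 0
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"ch{len(signals)}"
        signals.append(
            {"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline,
             "description": desc}
        )
    return record_id, n_sig, fs, n_samples, signals


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    triplets = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(triplets) // 3
    triplets = triplets[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = triplets[:, 0] | ((triplets[:, 1] & 0x0F) << 8)
    second = triplets[:, 2] | ((triplets[:, 1] & 0xF0) << 4)
    out = np.empty(n_pairs * 2, dtype=np.int32)
    out[0::2], out[1::2] = first, second
    out[out > 2047] -= 4096  # sign-extend 12-bit
    return out[:n_values]


def read_record(path: str | Path, lead: str = "MLII") -> AnnotatedRecord:
    """Read ``<path>.hea`` / ``.dat`` / ``.atr``, selecting the named lead."""
    path = Path(path)
    record_id, n_sig, fs, n_samples, signals = _parse_header(
        path.with_suffix(".hea")
    )
    descriptions = [s["description"] for s in signals]
    if lead not in descriptions:
        raise ValueError(
            f"record {record_id}: lead {lead!r} not present; "
            f"available leads: {descriptions}"
        )
    channel = descriptions.index(lead)
    spec = signals[channel]
    raw = (path.parent / spec["file"]).read_bytes()
    if spec["fmt"] == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif spec["fmt"] == 212:
        flat = _decode_212(raw, n_samples * n_sig if n_samples else None)
    else:
        raise ValueError(f"unsupported WFDB signal format {spec['fmt']}")
    if n_samples:
        flat = flat[: n_samples * n_sig]
    adc = flat[channel::n_sig]
    physical = (adc - spec["baseline"]) / spec["gain"]

    beats = []
    atr = path.with_suffix(".atr")
    if atr.exists():
        for sample, symbol in read_annotations(atr):
            if symbol is None:
                continue  # non-beat annotation
            beats.append((sample, map_symbol_to_aami(symbol)))
    return AnnotatedRecord(
        record_id=record_id,
        signal=physical,
        sampling_rate=fs,
        beats=tuple(beats),
    )


def read_annotations(path: str | Path) -> list[tuple[int, str | None]]:
    """Decode a MIT .atr stream into ``(sample, beat_symbol)`` pairs.

    Non-beat annotations are returned with symbol ``None`` so callers can
    count or skip them.
    """
    data = Path(path).read_bytes()
    out: list[tuple[int, str | None]] = []
    time = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code, field = word >> 10, word & 0x3FF
        if code == 0 and field == 0:
            break
        if code == _SKIP:
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            pending_skip += (high << 16) | low
        elif code == _AUX:
            i += field + (field & 1)  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            time += field + pending_skip
            pending_skip = 0
            symbol = ATR_CODE_TO_SYMBOL.get(code)
            if symbol is None and code not in _KNOWN_NON_BEAT_CODES:
                raise ValueError(f"{path}: unknown annotation code {code} at byte {i-2}")
            out.append((time, symbol))
    return out


def write_annotations(
    path: str | Path, annotations: list[tuple[int, str]]
) -> None:
    """Write ``(sample, native_symbol)`` pairs as a MIT .atr stream."""
    chunks = []
    prev = 0
    for sample, symbol in annotations:
        code = _SYMBOL_TO_CODE[symbol]
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta > 1023:
            chunks.append(struct.pack("<H", _SKIP << 10))
            chunks.append(struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF))
            delta = 0
        chunks.append(struct.pack("<H", (code << 10) | delta))
        prev = sample
    chunks.append(struct.pack("<H", 0))
    Path(path).write_bytes(b"".join(chunks))


def write_record(
    record: AnnotatedRecord,
    directory: str | Path,
    *,
    lead: str = "MLII",
    gain: float = 200.0,
    native_symbols: list[str] | None = None,
) -> Path:
    """Write a record as ``.hea``/``.dat`` (format 16) plus ``.atr``.

    Returns the record path without extension.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / record.record_id
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    base.with_suffix(".dat").write_bytes(adc.tobytes())
    header = (
        f"{record.record_id} 1 {record.sampling_rate:g} {len(adc)}\n"
        f"{record.record_id}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if len(adc) else 0} 0 0 {lead}\n"
    )
    base.with_suffix(".hea").write_text(header)
    representative = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "/"}
    if native_symbols is None:
        native_symbols = [representative[label.value] for _, label in record.beats]
    write_annotations(
        base.with_suffix(".atr"),
        [(r, sym) for (r, _), sym in zip(record.beats, native_symbols)],
    )
    return base
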