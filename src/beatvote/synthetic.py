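"""Synthetic annotated single-lead ECG records.

Generates records that exercise every pipeline stage without any
external dataset: each heartbeat is a sum of Gaussian waves (P, QRS
deflections, T) placed on a baseline-wander sinusoid plus white noise,
with the annotation stream written at the exact R-peak samples.

The class-conditional structure mirrors what makes the real problem
hard:

* **V** beats have a wide, high-amplitude QRS with an inverted T — they
  are morphologically distinct and easy;
* **S** beats reuse the normal QRS/T shape (their morphology is nearly
  normal) but fire **prematurely**, at a configurable fraction of the
  nominal RR interval, with a compensatory pause after — so the
  evidence that separates S from N lies mostly in the *neighbouring*
  beats' timing, which only an extended segmentation window can see;
* class frequencies default to the severe imbalance of the inter-patient
  training corpus (about 90% N).

Everything is deterministic under the config seed, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .dataset import AAMI_CLASSES, AamiClass, AnnotatedRecord

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "DEFAULT_MORPHOLOGY",
    "make_beat_template",
    "generate_record",
    "generate_corpus",
    "mitbih_like_config",
    "easy_two_class_config",
    "timing_discrimination_config",
]

# Per-class wave lists: (centre seconds relative to R, width s, amplitude mV).
# N and S share QRS and T; S merely lacks the sinus P wave.  V is wide and
# tall with an inverted T.  Amplitudes are in the ~1 mV range of lead MLII.
DEFAULT_MORPHOLOGY: dict[AamiClass, tuple[tuple[float, float, float], ...]] = {
    AamiClass.N: (
        (-0.17, 0.022, 0.15),   # P
        (-0.028, 0.010, -0.12),  # Q
        (0.0, 0.012, 1.10),      # R
        (0.030, 0.010, -0.25),   # S deflection
        (0.19, 0.055, 0.35),     # T
    ),
    AamiClass.S: (
        (-0.028, 0.010, -0.12),
        (0.0, 0.012, 1.10),
        (0.030, 0.010, -0.25),
        (0.19, 0.055, 0.35),
    ),
    AamiClass.V: (
        (0.0, 0.046, 1.35),      # broad R
        (0.085, 0.050, -0.45),
        (0.26, 0.070, -0.35),    # inverted T
    ),
    AamiClass.F: (
        (-0.16, 0.020, 0.08),
        (0.0, 0.028, 0.85),
        (0.045, 0.020, -0.20),
        (0.20, 0.060, 0.25),
    ),
    AamiClass.Q: (
        (0.0, 0.070, 0.75),      # broad paced blob
        (0.22, 0.080, -0.20),
    ),
}

#: Representative native symbol written into annotation streams per class.
NATIVE_SYMBOL: dict[AamiClass, str] = {
    AamiClass.N: "N",
    AamiClass.S: "A",
    AamiClass.V: "V",
    AamiClass.F: "F",
    AamiClass.Q: "/",
}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; defaults emulate a 360 Hz MLII record."""

    sampling_rate: float = 360.0
    record_duration_s: float = 60.0
    class_proportions: Mapping[AamiClass, float] = field(
        default_factory=lambda: {AamiClass.N: 1.0}
    )
    rr_mean_s: float = 0.8
    rr_jitter_s: float = 0.04
    #: S beats fire at this fraction of the nominal RR interval.
    premature_fraction_for_s: float = 0.55
    #: per-record scatter of the premature fraction (patients differ in
    #: how early their ectopic beats fire)
    premature_fraction_jitter: float = 0.0
    morphology: Mapping[AamiClass, tuple] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    #: per-beat multiplicative amplitude jitter (sd of a unit-mean normal)
    amplitude_jitter: float = 0.05
    #: per-record, per-wave amplitude/width scatter (sd of unit-mean normals);
    #: emulates inter-patient morphology differences, so cues learned on one
    #: set of records generalise only partially to unseen records
    record_morph_sd: float = 0.10
    noise_sd: float = 0.03
    baseline_amp: float = 0.05
    baseline_freq_hz: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if min(self.record_duration_s, self.rr_mean_s, self.sampling_rate) <= 0:
            raise ValueError("durations and sampling rate must be positive")
        if not 0.1 <= self.premature_fraction_for_s <= 1.0:
            raise ValueError("premature_fraction_for_s must be in [0.1, 1]")


@dataclass(frozen=True)
class SynthRecord:
    """A generated AnnotatedRecord plus its ground-truth generation log."""

    record: AnnotatedRecord
    log: tuple[dict, ...]  # per beat: class, time, amplitude scale, premature flag
    native_symbols: tuple[str, ...]

    @property
    def class_counts(self) -> dict[AamiClass, int]:
        counts = {cls: 0 for cls in AAMI_CLASSES}
        for entry in self.log:
            counts[entry["class"]] += 1
        return counts


def make_beat_template(
    cls: AamiClass,
    morphology: Mapping[AamiClass, tuple] | None = None,
    *,
    sampling_rate: float = 360.0,
    amplitude_scale: float = 1.0,
    span_s: tuple[float, float] = (-0.30, 0.36),
) -> tuple[np.ndarray, int]:
    """Render one beat as a waveform snippet.

    Returns ``(snippet, r_offset)`` where ``r_offset`` is the sample
    index of the R peak (the snippet's maximum under the default
    shapes).
    """
    waves = (morphology or DEFAULT_MORPHOLOGY)[cls]
    lo = int(round(span_s[0] * sampling_rate))
    hi = int(round(span_s[1] * sampling_rate))
    t = np.arange(lo, hi + 1) / sampling_rate
    snippet = np.zeros_like(t)
    for centre, width, amp in waves:
        snippet += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return amplitude_scale * snippet, -lo


def generate_record(
    config: SynthConfig, record_id: str = "synth-000"
) -> SynthRecord:
    """Generate one annotated record under ``config``.

    Beats are placed by an RR random walk (normal jitter around the
    mean); an S beat steals ``1 - premature_fraction`` of its nominal
    interval and hands it back to the following interval, producing the
    premature-beat/compensatory-pause signature.
    """
    fs = config.sampling_rate
    n_samples = int(round(config.record_duration_s * fs))
    rng = np.random.Generator(np.random.PCG64(config.seed))

    # this record's morphology: per-wave amplitude/width scatter emulating
    # one patient's waveform idiosyncrasies.  Classes that share a wave
    # list (e.g. the timing corpus, where S is a copy of N) are perturbed
    # identically, so no accidental class cue is introduced.
    morphology: dict[AamiClass, tuple] = {}
    if config.record_morph_sd > 0:
        perturbed_cache: dict[tuple, tuple] = {}
        for cls in AAMI_CLASSES:
            waves = tuple(config.morphology.get(cls, ()))
            if not waves:
                continue
            if waves not in perturbed_cache:
                perturbed_cache[waves] = tuple(
                    (
                        centre,
                        width * max(0.5, 1.0 + rng.normal(0, config.record_morph_sd / 2)),
                        amp * max(0.3, 1.0 + rng.normal(0, config.record_morph_sd)),
                    )
                    for centre, width, amp in waves
                )
            morphology[cls] = perturbed_cache[waves]
    else:
        morphology = {
            cls: tuple(config.morphology[cls])
            for cls in AAMI_CLASSES
            if cls in config.morphology
        }

    premature_fraction = float(
        np.clip(
            config.premature_fraction_for_s
            + (rng.normal(0.0, config.premature_fraction_jitter)
               if config.premature_fraction_jitter else 0.0),
            0.30,
            0.90,
        )
    )

    classes = [c for c in AAMI_CLASSES if config.class_proportions.get(c, 0.0) > 0]
    probs = np.array([config.class_proportions[c] for c in classes])

    edge_margin_s = 0.40  # keep whole templates inside the record
    if config.record_duration_s < 2 * edge_margin_s + config.rr_mean_s:
        raise ValueError(
            f"record duration {config.record_duration_s}s too short for one beat"
        )

    # schedule beats
    times: list[float] = []
    beat_classes: list[AamiClass] = []
    premature: list[bool] = []
    t = edge_margin_s + config.rr_mean_s / 2
    carry = 0.0
    while True:
        cls = classes[rng.choice(len(classes), p=probs)]
        nominal = max(0.35, config.rr_mean_s + rng.normal(0.0, config.rr_jitter_s))
        if times:
            if cls is AamiClass.S:
                interval = premature_fraction * nominal
                carry += nominal - interval
            else:
                interval = nominal + carry
                carry = 0.0
            t = times[-1] + interval
        if t > config.record_duration_s - edge_margin_s:
            break
        times.append(t)
        beat_classes.append(cls)
        premature.append(cls is AamiClass.S)

    # render
    signal = rng.normal(0.0, config.noise_sd, size=n_samples) if config.noise_sd else np.zeros(n_samples)
    tt = np.arange(n_samples) / fs
    signal = signal + config.baseline_amp * np.sin(
        2 * np.pi * config.baseline_freq_hz * tt
    )
    log = []
    beats = []
    symbols = []
    for when, cls, early in zip(times, beat_classes, premature):
        scale = max(0.2, 1.0 + rng.normal(0.0, config.amplitude_jitter))
        snippet, r_off = make_beat_template(
            cls, morphology, sampling_rate=fs, amplitude_scale=scale
        )
        r_sample = int(round(when * fs))
        start = r_sample - r_off
        stop = start + len(snippet)
        if start < 0 or stop > n_samples:
            continue
        signal[start:stop] += snippet
        beats.append((r_sample, cls))
        symbols.append(NATIVE_SYMBOL[cls])
        log.append(
            {
                "class": cls,
                "time_s": when,
                "r_sample": r_sample,
                "amplitude_scale": scale,
                "premature": early,
            }
        )
    record = AnnotatedRecord(
        record_id=record_id,
        signal=signal,
        sampling_rate=fs,
        beats=tuple(beats),
    )
    return SynthRecord(record=record, log=tuple(log), native_symbols=tuple(symbols))


def generate_corpus(
    config: SynthConfig, n_records: int, id_prefix: str = "synth"
) -> list[SynthRecord]:
    """Generate ``n_records`` independent records (distinct seeds/IDs).

    Using disjoint record lists for training and testing preserves the
    inter-patient discipline on synthetic data.
    """
    out = []
    for i in range(n_records):
        seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0])
        cfg = replace(config, seed=seed)
        out.append(generate_record(cfg, record_id=f"{id_prefix}-{i:03d}"))
    return out


def mitbih_like_config(seed: int = 0, record_duration_s: float = 120.0) -> SynthConfig:
    """Class mix matching the inter-patient training corpus (~90% N)."""
    return SynthConfig(
        record_duration_s=record_duration_s,
        class_proportions={
            AamiClass.N: 0.899,
            AamiClass.S: 0.0185,
            AamiClass.V: 0.0743,
            AamiClass.F: 0.008,
            AamiClass.Q: 0.0002,
        },
        seed=seed,
    )


def easy_two_class_config(seed: int = 0, record_duration_s: float = 120.0) -> SynthConfig:
    """Morphologically separable N-vs-V mix with low noise (smoke tests)."""
    return SynthConfig(
        record_duration_s=record_duration_s,
        class_proportions={AamiClass.N: 0.65, AamiClass.V: 0.35},
        noise_sd=0.02,
        seed=seed,
    )


def timing_discrimination_config(
    seed: int = 0, record_duration_s: float = 120.0
) -> SynthConfig:
    """N-vs-S mix where S is marked chiefly by premature timing.

    In this corpus the S template is byte-identical to the N template,
    so single-beat morphology carries no class signal: what marks an S
    beat is its timing.  The shared template is a P-QRS complex without
    a T wave — a slow repolarisation wave would trail far enough behind
    the premature beat's predecessor to intrude into even a 256-sample
    window and leak timing information into single-beat morphology.  At
    the default RR of 0.8 s and premature fraction ~0.55 the predecessor
    QRS of an S beat sits ~158 samples before its R peak — outside a
    256-sample window (edge at 127) but well inside the 508-sample one
    (edge at 250) — so this corpus probes exactly what the extended
    window buys.
    """
    shared = (
        (-0.17, 0.022, 0.15),   # P
        (-0.028, 0.010, -0.12),  # Q
        (0.0, 0.012, 1.10),      # R
        (0.030, 0.010, -0.25),   # S deflection
    )
    morphology = dict(DEFAULT_MORPHOLOGY)
    morphology[AamiClass.N] = shared
    morphology[AamiClass.S] = shared
    return SynthConfig(
        record_duration_s=record_duration_s,
        class_proportions={AamiClass.N: 0.75, AamiClass.S: 0.25},
        premature_fraction_for_s=0.55,
        premature_fraction_jitter=0.03,
        morphology=morphology,
        rr_jitter_s=0.04,
        noise_sd=0.02,
        seed=seed,
    )
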