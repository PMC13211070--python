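"""Signal conditioning and dataset partitioning for multi-lead ECG.

The chain applied to every record: quality gate -> zero-phase third-order
Butterworth band-pass (0.05-48 Hz) -> downsample to 250 Hz -> per-lead
z-score -> fixed-length standardization (truncate / zero-pad to the target
window, then right-pad to a multiple of the model's total downsampling
factor of 64).  Splits are assigned at the patient level (7:1:2 by record
count) and training batches are drawn with a class-balanced sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy import signal as sps

from .synth_ecg import ECGRecord

DOWNSAMPLE_FACTOR = 64  # total time reduction of the feature extractor


@dataclass
class PreprocessConfig:
    band_low: float = 0.05        # Hz
    band_high: float = 48.0       # Hz
    filter_order: int = 3
    target_fs: float = 250.0      # Hz
    target_len_s: float = 20.0    # seconds
    pad_mode: Literal["train_random", "eval_end"] = "eval_end"
    amplitude_limit: float = 20.0  # mV, pre-normalization quality gate

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= self.target_fs / 2:
            raise ValueError(
                f"band_high {self.band_high} violates Nyquist at "
                f"target_fs {self.target_fs}")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    @property
    def padded_len(self) -> int:
        """Model input length: target window rounded up to a multiple of 64."""
        base = int(round(self.target_len_s * self.target_fs))
        return -(-base // DOWNSAMPLE_FACTOR) * DOWNSAMPLE_FACTOR


def bandpass_filter(signal: np.ndarray, fs: float,
                    config: PreprocessConfig) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, per lead."""
    if fs <= 2 * config.band_high:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for band edge "
            f"{config.band_high} Hz")
    sos = sps.butter(config.filter_order,
                     [config.band_low, config.band_high],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def zscore_normalize(signal: np.ndarray) -> np.ndarray:
    """Per-lead z-score; constant (zero-variance) leads map to all zeros."""
    mean = signal.mean(axis=-1, keepdims=True)
    std = signal.std(axis=-1, keepdims=True)
    out = np.where(std > 0, (signal - mean) / np.where(std > 0, std, 1.0), 0.0)
    return out


def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase downsampling; output length = round(n * fs_out / fs_in)."""
    if fs_out > fs_in:
        raise ValueError(f"upsampling {fs_in} -> {fs_out} Hz is not supported")
    if fs_out == fs_in:
        return signal.copy()
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    out = sps.resample_poly(signal, frac.numerator, frac.denominator, axis=-1)
    want = int(round(signal.shape[-1] * fs_out / fs_in))
    return out[..., :want]


def fix_length(signal: np.ndarray, fs: float, config: PreprocessConfig,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Truncate/zero-pad to the target window, then pad to a multiple of 64.

    Longer records keep their leading ``target_len_s`` seconds.  The zero
    deficit of shorter records is split uniformly before/after the signal in
    ``train_random`` mode and placed entirely at the end in ``eval_end``
    mode; the final divisibility padding always goes at the end.
    """
    target = int(round(config.target_len_s * fs))
    n = signal.shape[-1]
    if n >= target:
        windowed = signal[..., :target]
        left = 0
    else:
        deficit = target - n
        if config.pad_mode == "train_random":
            if rng is None:
                raise ValueError("train_random padding needs an rng")
            left = int(rng.integers(0, deficit + 1))
        else:
            left = 0
        windowed = np.pad(signal, [(0, 0)] * (signal.ndim - 1)
                          + [(left, deficit - left)])
    extra = -(-target // DOWNSAMPLE_FACTOR) * DOWNSAMPLE_FACTOR - target
    return np.pad(windowed, [(0, 0)] * (signal.ndim - 1) + [(0, extra)])


@dataclass
class ExclusionLog:
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def add(self, record_id: str, reason: str) -> None:
        self.excluded.append((record_id, reason))


def quality_filter(records: list[ECGRecord],
                   config: PreprocessConfig) -> tuple[list[ECGRecord],
                                                      ExclusionLog]:
    """Drop incomplete records (NaN/Inf) and amplitude anomalies."""
    log = ExclusionLog()
    survivors = []
    for rec in records:
        if not np.all(np.isfinite(rec.signal)):
            log.add(rec.record_id, "incomplete")
        elif np.abs(rec.signal).max() > config.amplitude_limit:
            log.add(rec.record_id, "amplitude_anomaly")
        else:
            survivors.append(rec)
    return survivors, log


def split_patients(records: list[ECGRecord],
                   ratios: tuple[float, float, float] = (7, 1, 2),
                   seed: int = 0) -> dict[str, str]:
    """Patient-level train/val/test assignment, greedy-packed to the ratios.

    Patients are shuffled by the seed, then each is assigned to the split
    with the largest remaining record-count deficit, so no patient ever
    spans splits and record fractions approximate the ratios as closely as
    patient granularity allows.
    """
    patients: dict[str, list[str]] = {}
    for rec in records:
        patients.setdefault(rec.patient_id, []).append(rec.record_id)
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients, got {len(patients)}")
    names = ("train", "val", "test")
    total = len(records)
    weights = np.asarray(ratios, dtype=float)
    targets = weights / weights.sum() * total
    counts = np.zeros(3)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(patients))
    assignment: dict[str, str] = {}
    for pid in order:
        deficits = targets - counts
        split = int(np.argmax(deficits))
        counts[split] += len(patients[pid])
        for rid in patients[pid]:
            assignment[rid] = names[split]
    return assignment


def balanced_sampler(labels: np.ndarray,
                     rng: np.random.Generator) -> Iterator[int]:
    """Infinite index stream: pick a class uniformly, then a record uniformly
    within it (with replacement), so minority classes are oversampled."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in by_class.items():
        if len(idx) == 0:  # cannot occur via unique(); guards explicit lists
            raise ValueError(f"class {c} has no records")
    while True:
        c = classes[rng.integers(len(classes))]
        idx = by_class[c]
        yield int(idx[rng.integers(len(idx))])


def preprocess_record(record: ECGRecord, config: PreprocessConfig,
                      rng: np.random.Generator | None = None) -> ECGRecord:
    """Full conditioning chain for one record; returns a new ECGRecord at
    target_fs with exactly ``config.padded_len`` samples."""
    x = bandpass_filter(record.signal, record.fs, config)
    x = resample(x, record.fs, config.target_fs)
    x = zscore_normalize(x)
    x = fix_length(x, config.target_fs, config, rng=rng)
    return ECGRecord(signal=x, fs=config.target_fs, label=record.label,
                     patient_id=record.patient_id, record_id=record.record_id)
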