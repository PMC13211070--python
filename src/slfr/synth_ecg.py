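"""Synthetic class-conditioned 12-lead ECG with a single-lead information deficit.

The 12 leads are linear projections of 8 shared latent sources plus noise,
mimicking the redundancy of a real 12-lead system where any single lead is a
local projection of the same underlying cardiac activity.  Latent sources are
built from Gaussian-bump P/QRS/T/ST templates on a per-class beat grid.  Two
"hidden" sources (indices 6 and 7) carry the distinguishing signatures of
some classes; the designated wearable lead is given near-zero mixing weight
on those sources, so a classifier that only sees that lead is genuinely
information-poor — the premise the feature-reconstruction method targets.

Not a physiological simulator: morphologies are schematic bumps, chosen for
reproducibility and speed, not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_SOURCES = 8
N_LEADS = 12
HIDDEN_SOURCES = (6, 7)

#: Per-class rhythm/morphology parameters. ``hidden_st`` / ``hidden_t`` are
#: injected only into the hidden sources, hence invisible in a lead whose
#: mixing row is near zero there.
CLASS_DEFS = [
    dict(name="normal", rr_mean=0.80, rr_cv=0.04, qrs_width=0.030,
         qrs_amp=1.00, p_amp=0.15, t_amp=0.30, st_offset=0.0,
         hidden_st=0.0, hidden_t=0.0),
    dict(name="irregular_rhythm", rr_mean=0.70, rr_cv=0.28, qrs_width=0.030,
         qrs_amp=1.00, p_amp=0.0, t_amp=0.30, st_offset=0.0,
         hidden_st=0.0, hidden_t=0.0),
    dict(name="wide_qrs", rr_mean=0.85, rr_cv=0.05, qrs_width=0.075,
         qrs_amp=1.30, p_amp=0.15, t_amp=0.30, st_offset=0.0,
         hidden_st=0.0, hidden_t=0.0),
    dict(name="st_shift_hidden", rr_mean=0.80, rr_cv=0.04, qrs_width=0.030,
         qrs_amp=1.00, p_amp=0.15, t_amp=0.30, st_offset=0.0,
         hidden_st=0.45, hidden_t=0.0),
    dict(name="bradycardia", rr_mean=1.25, rr_cv=0.04, qrs_width=0.030,
         qrs_amp=1.00, p_amp=0.15, t_amp=0.30, st_offset=0.0,
         hidden_st=0.0, hidden_t=0.0),
    dict(name="t_inversion_hidden", rr_mean=0.80, rr_cv=0.04, qrs_width=0.030,
         qrs_amp=1.00, p_amp=0.15, t_amp=0.30, st_offset=0.0,
         hidden_st=0.0, hidden_t=-0.55),
]

# Fixed weights of each latent source on the (P, QRS, T, ST, hidden) component
# traces. Sources 0-5 mix the ordinary waves with varied emphasis and carry no
# hidden component; sources 6-7 are dominated by the hidden signature.
SOURCE_COMPONENTS = np.array([
    # P     QRS    T      ST     hidden
    [0.9,  1.00,  0.60,  0.80,  0.0],
    [0.5,  0.85,  0.90,  0.60,  0.0],
    [1.0,  0.60,  0.40,  0.50,  0.0],
    [0.2,  1.10,  0.70,  0.90,  0.0],
    [0.7,  0.40,  1.00,  0.40,  0.0],
    [0.3,  0.95,  0.25,  0.70,  0.0],
    [0.1,  0.15,  0.10,  0.05,  1.00],
    [0.05, 0.10,  0.20,  0.05,  0.80],
])


def default_lead_mixing(wearable_lead_index: int = 0,
                        hidden_weight: float = 0.05) -> np.ndarray:
    """Fixed full-column-rank 12 x 8 mixing matrix.

    All leads get substantial weights on the common sources; the wearable
    lead's weights on the hidden sources are scaled down to `hidden_weight`
    (attenuated, not exactly zero — the signature is recoverable in
    principle but weak).
    """
    rng = np.random.default_rng(20260924)
    m = rng.uniform(0.3, 1.0, size=(N_LEADS, N_SOURCES))
    m *= rng.choice([-1.0, 1.0], size=m.shape, p=[0.25, 0.75])
    m[:, list(HIDDEN_SOURCES)] = rng.uniform(0.5, 1.0, size=(N_LEADS, 2))
    m[wearable_lead_index, list(HIDDEN_SOURCES)] *= hidden_weight
    assert np.linalg.matrix_rank(m) == N_SOURCES
    return m


@dataclass
class SimSpec:
    """Conditions for one synthetic dataset draw."""

    n_patients: int
    records_per_patient: int
    fs: float = 500.0
    duration_s: tuple[float, float] = (10.0, 20.0)
    n_classes: int = 6
    snr_db: float = 20.0
    lead_mixing: np.ndarray | None = None
    wearable_lead_index: int = 0
    class_priors: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_classes > len(CLASS_DEFS):
            raise ValueError(
                f"at most {len(CLASS_DEFS)} classes are defined, "
                f"got {self.n_classes}")
        # templates have appreciable content up to ~1/(2*min QRS width) Hz
        f_max = 1.0 / (2 * min(c["qrs_width"] for c in CLASS_DEFS))
        if self.fs <= 2 * f_max:
            raise ValueError(f"fs={self.fs} must exceed twice the highest "
                             f"template frequency ({f_max:.0f} Hz)")
        if self.lead_mixing is None:
            self.lead_mixing = default_lead_mixing(self.wearable_lead_index)
        self.lead_mixing = np.asarray(self.lead_mixing, dtype=float)
        if np.linalg.matrix_rank(self.lead_mixing) < self.lead_mixing.shape[1]:
            raise ValueError("lead_mixing must have full column rank")
        if self.class_priors is None:
            p = 0.82 ** np.arange(self.n_classes)
            self.class_priors = p / p.sum()
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if len(self.class_priors) != self.n_classes:
            raise ValueError("class_priors length must equal n_classes")


@dataclass
class ECGRecord:
    """One labeled multi-lead recording."""

    signal: np.ndarray  # (leads, samples), millivolt scale
    fs: float
    label: int
    patient_id: str
    record_id: str

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (leads, samples)")
        if self.signal.shape[0] not in (1, 3, 12):
            raise ValueError(f"leads must be 1, 3 or 12, got {self.signal.shape[0]}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN/Inf")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_beat_train(class_id: int, fs: float, duration_s: float,
                        rng: np.random.Generator, rr_scale: float = 1.0,
                        amp_scale: float = 1.0) -> np.ndarray:
    """Latent source traces for one record: (N_SOURCES, round(fs*duration_s)).

    The class controls RR regularity (`rr_cv`), QRS width/amplitude, P-wave
    presence and any hidden-source-only signature.
    """
    if not 0 <= class_id < len(CLASS_DEFS):
        raise ValueError(f"unknown class_id {class_id}; "
                         f"defined classes are 0..{len(CLASS_DEFS) - 1}")
    c = CLASS_DEFS[class_id]
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs

    rr_mean = c["rr_mean"] * rr_scale
    # beat grid with class-dependent RR variability
    centers = []
    pos = float(rng.uniform(0.1, 0.4))
    while pos < duration_s + rr_mean:
        centers.append(pos)
        rr = rng.normal(rr_mean, c["rr_cv"] * rr_mean)
        pos += float(np.clip(rr, 0.3, 2.5))

    p_tr = np.zeros(n)
    qrs_tr = np.zeros(n)
    t_tr = np.zeros(n)
    st_tr = np.zeros(n)
    hid_tr = np.zeros(n)
    qw = c["qrs_width"]
    for ctr in centers:
        if c["p_amp"] > 0:
            p_tr += c["p_amp"] * _gauss(t, ctr - 0.20, 0.025)
        qrs_tr += c["qrs_amp"] * (_gauss(t, ctr, qw)
                                  - 0.30 * _gauss(t, ctr - 2.2 * qw, qw * 0.8)
                                  - 0.20 * _gauss(t, ctr + 2.2 * qw, qw * 0.8))
        t_tr += c["t_amp"] * _gauss(t, ctr + 0.32, 0.055)
        st_pos = ctr + 0.14
        if c["st_offset"]:
            st_tr += c["st_offset"] * _gauss(t, st_pos, 0.045)
        if c["hidden_st"]:
            hid_tr += c["hidden_st"] * _gauss(t, st_pos, 0.045)
        if c["hidden_t"]:
            hid_tr += c["hidden_t"] * _gauss(t, ctr + 0.32, 0.055)

    components = np.stack([p_tr, qrs_tr, t_tr, st_tr, hid_tr])
    return amp_scale * (SOURCE_COMPONENTS @ components)


def project_to_leads(source_matrix: np.ndarray, lead_mixing: np.ndarray,
                     snr_db: float, rng: np.random.Generator,
                     fs: float = 500.0,
                     wander_freq_hz: float = 0.33) -> np.ndarray:
    """Project latent sources to leads and add noise at a prescribed SNR.

    The noise term is white Gaussian plus a low-frequency baseline-wander
    sinusoid (random phase per lead); the combined disturbance is scaled so
    the empirical SNR equals `snr_db`.  ``snr_db=inf`` returns the noiseless
    projection exactly.
    """
    source_matrix = np.asarray(source_matrix, dtype=float)
    lead_mixing = np.asarray(lead_mixing, dtype=float)
    if lead_mixing.shape[1] != source_matrix.shape[0]:
        raise ValueError(
            f"lead_mixing has {lead_mixing.shape[1]} columns but "
            f"{source_matrix.shape[0]} sources were provided")
    clean = lead_mixing @ source_matrix
    if np.isinf(snr_db):
        return clean
    n = clean.shape[1]
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=(clean.shape[0], 1))
    wander = np.sin(2 * np.pi * wander_freq_hz * t[None, :] + phases)
    disturbance = rng.standard_normal(clean.shape) + wander
    p_signal = np.mean(clean ** 2)
    p_target = p_signal / 10.0 ** (snr_db / 10.0)
    disturbance *= np.sqrt(p_target / np.mean(disturbance ** 2))
    return clean + disturbance


def simulate_dataset(spec: SimSpec) -> list[ECGRecord]:
    """Draw the full dataset: patients x records, class-conditioned.

    Patients carry a random heart-rate and amplitude effect shared by their
    records. Same spec (incl. seed) reproduces the dataset byte-identically.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ECGRecord] = []
    lo, hi = spec.duration_s
    for p in range(spec.n_patients):
        patient_id = f"P{p:04d}"
        rr_scale = float(rng.uniform(0.92, 1.08))
        amp_scale = float(rng.uniform(0.85, 1.15))
        for r in range(spec.records_per_patient):
            label = int(rng.choice(spec.n_classes, p=spec.class_priors))
            duration = float(rng.uniform(lo, hi))
            sources = simulate_beat_train(label, spec.fs, duration, rng,
                                          rr_scale=rr_scale,
                                          amp_scale=amp_scale)
            signal = project_to_leads(sources, spec.lead_mixing, spec.snr_db,
                                      rng, fs=spec.fs)
            records.append(ECGRecord(signal=signal, fs=spec.fs, label=label,
                                     patient_id=patient_id,
                                     record_id=f"{patient_id}_R{r:02d}"))
    return records


def build_manifest(records: list[ECGRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "patient_id": [r.patient_id for r in records],
        "label": [r.label for r in records],
        "fs": [r.fs for r in records],
        "n_samples": [r.n_samples for r in records],
    })


def save_dataset(records: list[ECGRecord], out_dir) -> None:
    """One directory per dataset: per-record .npy arrays + CSV manifest."""
    from pathlib import Path
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    for rec in records:
        np.save(out / "signals" / f"{rec.record_id}.npy", rec.signal)
    build_manifest(records).to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir) -> list[ECGRecord]:
    from pathlib import Path
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        signal = np.load(src / "signals" / f"{row.record_id}.npy")
        records.append(ECGRecord(signal=signal, fs=float(row.fs),
                                 label=int(row.label),
                                 patient_id=str(row.patient_id),
                                 record_id=str(row.record_id)))
    return records


def select_leads(record: ECGRecord, lead_indices: list[int]) -> ECGRecord:
    """A copy of the record restricted to the given leads (student input)."""
    return ECGRecord(signal=record.signal[lead_indices, :], fs=record.fs,
                     label=record.label, patient_id=record.patient_id,
                     record_id=record.record_id)
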