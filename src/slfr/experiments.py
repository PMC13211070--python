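"""Desk-scale end-to-end experiments on the synthetic generator.

These runs exercise the complete two-phase protocol — simulate, condition,
split by patient, pretrain and freeze the 12-lead teacher, train the
single-lead variants, evaluate held-out macro metrics — at sizes a single
CPU handles in minutes.  Widths use the small architecture profile,
records are 5 s long, and the optimizer runs fewer, larger steps than a
full-scale training would, with a correspondingly larger Adam step size.
Arithmetic runs in float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess as pp
from .evaluation import compute_metrics
from .extractor import ExtractorSpec
from .nn.tensor import default_dtype
from .synth_ecg import SimSpec, simulate_dataset
from .training import TrainConfig, pretrain_teacher, predict_probs, train_slfr

ABLATION_VARIANTS = ("baseline_single", "supervise_only", "full")


@dataclass
class DeskConfig:
    """Problem sizes for the desk-scale ablation replicate."""

    n_patients: int = 60
    records_per_patient: int = 4
    duration_s: tuple[float, float] = (5.0, 5.0)
    snr_db: float = 20.0
    target_len_s: float = 5.0
    teacher_epochs: int = 24
    student_epochs: int = 24
    batch_size: int = 8
    steps_per_epoch: int = 8
    lr_init: float = 1e-3
    alpha: float = 1.0
    dropout: float = 0.0
    tiny_widths: bool = False  # even narrower profile for smoke tests

    def extractor_spec(self, in_leads: int) -> ExtractorSpec:
        if self.tiny_widths:
            return ExtractorSpec.small(
                in_leads=in_leads, oscnn_out_channels=12,
                block_channels=(8, 8, 16, 16, 24), d_model=24, n_heads=2,
                se_reduction=4, dropout=self.dropout)
        return ExtractorSpec.small(in_leads=in_leads, dropout=self.dropout)


def desk_dataset(seed: int, cfg: DeskConfig | None = None):
    """Simulate, quality-filter, patient-split and condition one dataset.

    Returns (train, val, test) lists of preprocessed 12-lead records plus
    the class count.  Training records use the randomized padding mode.
    """
    cfg = cfg or DeskConfig()
    sim = SimSpec(n_patients=cfg.n_patients,
                  records_per_patient=cfg.records_per_patient,
                  duration_s=cfg.duration_s, snr_db=cfg.snr_db, seed=seed)
    records = simulate_dataset(sim)
    base = pp.PreprocessConfig(target_len_s=cfg.target_len_s)
    survivors, _ = pp.quality_filter(records, base)
    assignment = pp.split_patients(survivors, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    train_cfg = pp.PreprocessConfig(target_len_s=cfg.target_len_s,
                                    pad_mode="train_random")
    out = {"train": [], "val": [], "test": []}
    for rec in survivors:
        split = assignment[rec.record_id]
        cfg_rec = train_cfg if split == "train" else base
        out[split].append(pp.preprocess_record(rec, cfg_rec, rng=rng))
    return out["train"], out["val"], out["test"], sim.n_classes


@dataclass
class AblationResult:
    seed: int
    teacher_val_f1: float
    teacher_test_f1: float = float("nan")
    test_f1: dict[str, float] = field(default_factory=dict)
    test_acc: dict[str, float] = field(default_factory=dict)
    val_l1_first: float = float("nan")
    val_l1_last: float = float("nan")
    teacher_hash_stable: bool = True


def run_ablation(seed: int, cfg: DeskConfig | None = None,
                 variants: tuple[str, ...] = ABLATION_VARIANTS,
                 ) -> AblationResult:
    """One replicate: teacher pretraining plus every requested variant,
    evaluated on the held-out patient-level test split."""
    cfg = cfg or DeskConfig()
    with default_dtype(np.float32):
        train, val, test, k = desk_dataset(seed, cfg)
        teacher_cfg = TrainConfig(
            epochs=cfg.teacher_epochs, batch_size=cfg.batch_size,
            lr_init=cfg.lr_init, seed=seed,
            steps_per_epoch=cfg.steps_per_epoch)
        teacher, tlog = pretrain_teacher(
            train, val, teacher_cfg,
            extractor_spec=cfg.extractor_spec(12), n_classes=k)
        hash_before = teacher.weight_hash()
        y_test = np.array([r.label for r in test])
        teacher_rep = compute_metrics(y_test, teacher.predict_probs(test),
                                      n_classes=k)
        result = AblationResult(seed=seed,
                                teacher_val_f1=float(tlog.val_macro_f1.max()),
                                teacher_test_f1=teacher_rep.macro_f1)
        for variant in variants:
            student_cfg = TrainConfig(
                epochs=cfg.student_epochs, batch_size=cfg.batch_size,
                lr_init=cfg.lr_init, alpha=cfg.alpha, seed=seed + 100,
                variant=variant, steps_per_epoch=cfg.steps_per_epoch)
            model, log = train_slfr(
                train, val,
                None if variant == "baseline_single" else teacher,
                student_cfg, extractor_spec=cfg.extractor_spec(1),
                n_classes=k)
            probs = predict_probs(model, test, lead_indices=(0,))
            rep = compute_metrics(y_test, probs, n_classes=k)
            result.test_f1[variant] = rep.macro_f1
            result.test_acc[variant] = rep.accuracy
            if variant == "full":
                result.val_l1_first = float(log.val_l1.iloc[0])
                result.val_l1_last = float(log.val_l1.iloc[-1])
        result.teacher_hash_stable = teacher.weight_hash() == hash_before
        return result


def run_replicates(seeds: tuple[int, ...], cfg: DeskConfig | None = None,
                   ) -> dict:
    """Mean held-out macro-F1 per variant over replicate seeds."""
    results = [run_ablation(s, cfg) for s in seeds]
    mean_f1 = {v: float(np.mean([r.test_f1[v] for r in results]))
               for v in ABLATION_VARIANTS}
    return {
        "seeds": list(seeds),
        "mean_test_macro_f1": mean_f1,
        "mean_teacher_test_f1": float(np.mean(
            [r.teacher_test_f1 for r in results])),
        "per_seed": results,
        "val_l1_first": float(np.mean([r.val_l1_first for r in results])),
        "val_l1_last": float(np.mean([r.val_l1_last for r in results])),
        "teacher_hash_stable": all(r.teacher_hash_stable for r in results),
    }
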