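"""Two-phase training: pretrain and freeze a 12-lead teacher, then train the
single-lead network under the joint loss  L_total = L_rec + alpha * L_CE.

Phase 1 trains the 12-lead extractor + classifier with cross-entropy and the
class-balanced sampler, selects the best validation-macro-F1 checkpoint,
freezes the weights and records their content hash.  Phase 2 trains the
single-lead pathway; per batch the frozen teacher maps the full 12-lead
input to target features F_full with no gradient, the student maps its
configured lead(s) to F_single, and the variant wiring decides the rest:

    full            F_rec = recon(F_single); classify fuse(F_rec, F_single);
                    alignment loss between F_rec and F_full
    supervise_only  no reconstruction module; alignment loss directly
                    between F_single and F_full; classify F_single
    no_fusion       reconstruction present, classify F_rec directly
    baseline_single cross-entropy only, no teacher involvement
    logit_kd        experimental distillation hook: cross-entropy plus
                    KL(teacher probabilities || student probabilities)

The teacher's hash is re-checked every epoch: Phase 2 must never move it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .extractor import ExtractorSpec, FeatureExtractor
from .fusion_head import Classifier, FusionModule, FusionSpec
from .preprocess import balanced_sampler
from .reconstruction import ReconSpec, ReconstructionModule, recon_loss
from .evaluation import compute_metrics
from .synth_ecg import ECGRecord

VARIANTS = ("full", "supervise_only", "no_fusion", "baseline_single",
            "logit_kd")


@dataclass
class TrainConfig:
    epochs: int = 120
    batch_size: int = 128
    lr_init: float = 1e-4
    lr_min: float = 1e-7
    plateau_patience: int = 5
    lr_factor: float = 0.5
    alpha: float = 1.0           # weight of the cross-entropy term
    seed: int = 0
    variant: str = "full"
    lead_indices: tuple[int, ...] = (0,)
    steps_per_epoch: int | None = None
    loss_kind: str = "L1"

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, "
                             f"got {self.variant!r}")


@dataclass
class TeacherBundle:
    """Frozen 12-lead extractor + classifier supervising Phase 2."""

    extractor: FeatureExtractor
    classifier: Classifier
    frozen: bool = False
    hash_at_freeze: str = ""

    def freeze(self) -> "TeacherBundle":
        self.extractor.eval()
        self.classifier.eval()
        self.frozen = True
        self.hash_at_freeze = self.weight_hash()
        return self

    def weight_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(self.extractor.weight_hash().encode())
        h.update(self.classifier.weight_hash().encode())
        return h.hexdigest()

    def check_frozen(self) -> None:
        if not self.frozen:
            raise RuntimeError("teacher must be frozen before Phase 2")
        # keep eval mode pinned: a train-mode forward would update BatchNorm
        # running statistics even under no_grad
        self.extractor.eval()
        self.classifier.eval()
        if self.weight_hash() != self.hash_at_freeze:
            raise RuntimeError("teacher weights changed after freezing")

    def predict_probs(self, records) -> np.ndarray:
        """Eval-mode class probabilities on preprocessed 12-lead records."""
        if self.frozen:
            self.check_frozen()
        net = _TeacherNet(self.extractor, self.classifier).eval()
        return _eval_probs(net, _stack(records))


def cross_entropy(p_pred: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the true labels.

    `p_pred` is a (batch, K) matrix of class probabilities.
    """
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    k = p_pred.shape[-1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    picked = p_pred[np.arange(len(labels)), labels]
    return -((picked + 1e-12).log().mean())


def total_loss(l1_value, ce_value, alpha: float):
    """Joint objective: alignment term plus alpha times cross-entropy."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return l1_value + alpha * ce_value


class SLFRModel(nn.Module):
    """Single-lead student: extractor, optional reconstruction, optional
    fusion, pooling classifier — wired according to the training variant."""

    def __init__(self, extractor_spec: ExtractorSpec, n_classes: int,
                 variant: str = "full", recon_layers: int = 2,
                 seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.variant = variant
        d_model = extractor_spec.d_model
        self.extractor = FeatureExtractor(extractor_spec, seed=seed)
        needs_recon = variant in ("full", "no_fusion")
        self.recon = ReconstructionModule(
            ReconSpec(d_model=d_model, n_layers=recon_layers,
                      n_heads=extractor_spec.n_heads,
                      dropout=extractor_spec.dropout),
            seed=seed + 1) if needs_recon else None
        self.fusion = FusionModule(
            FusionSpec(d_model=d_model, n_heads=extractor_spec.n_heads,
                       dropout=extractor_spec.dropout),
            seed=seed + 2) if variant == "full" else None
        self.classifier = Classifier(d_model, n_classes, seed=seed + 3)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """Returns (class probabilities, reconstructed features or None)."""
        f_single = self.extractor(x)
        if self.variant == "full":
            f_rec = self.recon(f_single)
            return self.classifier(self.fusion(f_rec, f_single)), f_rec
        if self.variant == "no_fusion":
            f_rec = self.recon(f_single)
            return self.classifier(f_rec), f_rec
        # supervise_only / baseline_single / logit_kd classify F_single;
        # supervise_only aligns F_single itself with the teacher features
        return self.classifier(f_single), f_single


def _stack(records: list[ECGRecord],
           lead_indices: tuple[int, ...] | None = None) -> np.ndarray:
    sig = np.stack([r.signal for r in records])
    if lead_indices is not None:
        n_leads = sig.shape[1]
        if max(lead_indices) >= n_leads or min(lead_indices) < 0:
            raise ValueError(f"lead index out of range for {n_leads} leads: "
                             f"{lead_indices}")
        sig = sig[:, list(lead_indices), :]
    return sig


def _labels(records: list[ECGRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=int)


def _eval_probs(model: nn.Module, x: np.ndarray,
                batch_size: int = 32) -> np.ndarray:
    """Batched eval-mode forward returning class probabilities."""
    was_training = model.training
    model.eval()
    outs = []
    try:
        with nn.no_grad():
            for i in range(0, len(x), batch_size):
                out = model(Tensor(x[i:i + batch_size]))
                probs = out[0] if isinstance(out, tuple) else out
                outs.append(probs.numpy())
    finally:
        model.train(was_training)
    return np.concatenate(outs)


class _TeacherNet(nn.Module):
    """Extractor + classifier viewed as one network (Phase 1 training)."""

    def __init__(self, extractor: FeatureExtractor, classifier: Classifier):
        super().__init__()
        self.extractor = extractor
        self.classifier = classifier

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.extractor(x))


def pretrain_teacher(train_records: list[ECGRecord],
                     val_records: list[ECGRecord],
                     config: TrainConfig,
                     extractor_spec: ExtractorSpec | None = None,
                     n_classes: int | None = None,
                     ) -> tuple[TeacherBundle, pd.DataFrame]:
    """Phase 1: train the 12-lead model with cross-entropy, select the best
    validation-macro-F1 checkpoint, freeze and hash it."""
    if any(r.n_leads != 12 for r in train_records + val_records):
        raise ValueError("teacher pretraining requires 12-lead records")
    spec = extractor_spec or ExtractorSpec.small(in_leads=12)
    if spec.in_leads != 12:
        raise ValueError("teacher extractor must take 12 leads")
    y_train = _labels(train_records)
    k = n_classes or int(y_train.max()) + 1
    net = _TeacherNet(FeatureExtractor(spec, seed=config.seed),
                      Classifier(spec.d_model, k, seed=config.seed + 10))
    log = _fit_classifier(net, train_records, val_records, config,
                          lead_indices=None, n_classes=k)
    bundle = TeacherBundle(net.extractor, net.classifier).freeze()
    return bundle, log


def _fit_classifier(net: nn.Module, train_records, val_records,
                    config: TrainConfig, lead_indices, n_classes: int,
                    ) -> pd.DataFrame:
    """Cross-entropy training loop shared by Phase 1 and the CE-only
    variants; restores the best validation-macro-F1 weights at the end."""
    x_train = _stack(train_records, lead_indices)
    y_train = _labels(train_records)
    x_val = _stack(val_records, lead_indices)
    y_val = _labels(val_records)
    rng = np.random.default_rng(config.seed + 1)
    sampler = balanced_sampler(y_train, rng)
    steps = config.steps_per_epoch or -(-len(y_train) // config.batch_size)
    opt = nn.Adam(net.parameters(), lr=config.lr_init)
    sched = nn.ReduceLROnPlateau(opt, factor=config.lr_factor,
                                 patience=config.plateau_patience,
                                 min_lr=config.lr_min)
    rows = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        net.train()
        ce_sum = 0.0
        for _ in range(steps):
            idx = [next(sampler) for _ in range(config.batch_size)]
            opt.zero_grad()
            out = net(Tensor(x_train[idx]))
            probs = out[0] if isinstance(out, tuple) else out
            loss = cross_entropy(probs, y_train[idx])
            loss.backward()
            opt.step()
            ce_sum += loss.item()
        val_probs = _eval_probs(net, x_val)
        rep = compute_metrics(y_val, val_probs, n_classes=n_classes)
        val_ce = -np.mean(np.log(
            val_probs[np.arange(len(y_val)), y_val] + 1e-12))
        lr = sched.step(val_ce)
        rows.append(dict(epoch=epoch, train_ce=ce_sum / steps, val_ce=val_ce,
                         val_acc=rep.accuracy, val_macro_f1=rep.macro_f1,
                         lr=lr))
        if rep.macro_f1 > best[0]:
            best = (rep.macro_f1, net.state_dict())
    if best[1] is not None:
        net.load_state_dict(best[1])
    return pd.DataFrame(rows)


def train_slfr(train_records: list[ECGRecord],
               val_records: list[ECGRecord],
               teacher: TeacherBundle | None,
               config: TrainConfig,
               extractor_spec: ExtractorSpec | None = None,
               n_classes: int | None = None,
               ) -> tuple[SLFRModel, pd.DataFrame]:
    """Phase 2: train the single-lead network under the variant's wiring.

    Records must carry all 12 leads — the teacher consumes the full signal
    while the student sees only ``config.lead_indices``.  Returns the model
    (best-validation-macro-F1 weights restored) and the epoch log.
    """
    uses_teacher = config.variant not in ("baseline_single",)
    if uses_teacher:
        if teacher is None:
            raise ValueError(f"variant {config.variant!r} needs a teacher")
        teacher.check_frozen()
    if any(r.n_leads != 12 for r in train_records + val_records):
        raise ValueError("training records must carry 12 leads")
    y_train = _labels(train_records)
    k = n_classes or int(y_train.max()) + 1
    spec = extractor_spec or ExtractorSpec.small(
        in_leads=len(config.lead_indices))
    if spec.in_leads != len(config.lead_indices):
        raise ValueError("extractor in_leads must match len(lead_indices)")
    model = SLFRModel(spec, k, variant=config.variant, seed=config.seed)

    x12_train = _stack(train_records)
    x_train = _stack(train_records, config.lead_indices)
    x12_val = _stack(val_records)
    x_val = _stack(val_records, config.lead_indices)
    y_val = _labels(val_records)

    rng = np.random.default_rng(config.seed + 1)
    sampler = balanced_sampler(y_train, rng)
    steps = config.steps_per_epoch or -(-len(y_train) // config.batch_size)
    opt = nn.Adam(model.parameters(), lr=config.lr_init)
    sched = nn.ReduceLROnPlateau(opt, factor=config.lr_factor,
                                 patience=config.plateau_patience,
                                 min_lr=config.lr_min)

    def teacher_features(x12: np.ndarray) -> np.ndarray:
        # the teacher is frozen and in eval mode, so its features per record
        # are constant across epochs: compute in batches, once
        with nn.no_grad():
            outs = [teacher.extractor(Tensor(x12[i:i + 32])).numpy()
                    for i in range(0, len(x12), 32)]
        return np.concatenate(outs)

    f_full_train = teacher_features(x12_train) if uses_teacher else None
    f_full_val = teacher_features(x12_val) if uses_teacher else None

    def alignment_loss(model_out, f_full: np.ndarray | None):
        probs, f_student = model_out
        if config.variant == "baseline_single":
            return Tensor(0.0), probs
        if config.variant == "logit_kd":
            with nn.no_grad():
                p_pre = teacher.classifier(Tensor(f_full)).numpy()
            # KL(teacher || student) on the class distributions
            const = float(np.mean(np.sum(
                p_pre * np.log(p_pre + 1e-12), axis=-1)))
            kd = const - (Tensor(p_pre) * (probs + 1e-12).log()) \
                .sum(axis=-1).mean()
            return kd, probs
        return recon_loss(f_student, Tensor(f_full), config.loss_kind), probs

    rows = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        if uses_teacher:
            teacher.check_frozen()
        model.train()
        l1_sum = ce_sum = tot_sum = 0.0
        for _ in range(steps):
            idx = [next(sampler) for _ in range(config.batch_size)]
            f_full = f_full_train[idx] if uses_teacher else None
            opt.zero_grad()
            out = model(Tensor(x_train[idx]))
            l1, probs = alignment_loss(out, f_full)
            ce = cross_entropy(probs, y_train[idx])
            # every variant optimizes l1 + alpha*ce; baseline has l1 == 0
            loss = total_loss(l1, ce, config.alpha)
            loss.backward()
            opt.step()
            l1_sum += l1.item()
            ce_sum += ce.item()
            tot_sum += loss.item()

        # validation pass
        model.eval()
        with nn.no_grad():
            val_out = []
            val_l1 = []
            for i in range(0, len(x_val), 32):
                out = model(Tensor(x_val[i:i + 32]))
                f_full = f_full_val[i:i + 32] if uses_teacher else None
                l1_v, probs_v = alignment_loss(out, f_full)
                val_out.append(probs_v.numpy())
                val_l1.append(l1_v.item())
        val_probs = np.concatenate(val_out)
        rep = compute_metrics(y_val, val_probs, n_classes=k)
        val_ce = -np.mean(np.log(
            val_probs[np.arange(len(y_val)), y_val] + 1e-12))
        val_l1_mean = float(np.mean(val_l1))
        val_total = total_loss(val_l1_mean, val_ce, config.alpha)
        lr = sched.step(val_total)
        rows.append(dict(epoch=epoch, l1=l1_sum / steps, ce=ce_sum / steps,
                         total=tot_sum / steps, val_l1=val_l1_mean,
                         val_ce=val_ce, val_total=val_total,
                         val_acc=rep.accuracy, val_macro_f1=rep.macro_f1,
                         lr=lr))
        if rep.macro_f1 > best[0]:
            best = (rep.macro_f1, model.state_dict())
    if uses_teacher:
        teacher.check_frozen()
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, pd.DataFrame(rows)


def predict_probs(model: nn.Module, records: list[ECGRecord],
                  lead_indices: tuple[int, ...] | None = None) -> np.ndarray:
    """Eval-mode class probabilities for a list of preprocessed records."""
    return _eval_probs(model, _stack(records, lead_indices))


def save_slfr(model: SLFRModel, path) -> None:
    """Weights (.npz) plus a JSON sidecar describing the wiring."""
    from pathlib import Path
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    meta = dict(variant=model.variant,
                n_classes=model.classifier.n_classes,
                recon_layers=(model.recon.spec.n_layers
                              if model.recon is not None else 0),
                extractor_spec=model.extractor.spec.to_json())
    path.with_suffix(".json").write_text(__import__("json").dumps(meta,
                                                                  indent=2))


def load_slfr(path) -> SLFRModel:
    import json
    from pathlib import Path
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ExtractorSpec.from_json(meta["extractor_spec"])
    model = SLFRModel(spec, meta["n_classes"], variant=meta["variant"],
                      recon_layers=meta["recon_layers"] or 2)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
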