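"""Training-protocol checks: loss arithmetic, scheduler contract, variant
wiring, teacher freeze contract, and descent on a tiny separable toy."""

import numpy as np
import pytest

from slfr import nn
from slfr.extractor import ExtractorSpec
from slfr.nn import Tensor, plateau_schedule
from slfr.synth_ecg import ECGRecord
from slfr.training import (SLFRModel, TrainConfig, cross_entropy,
                           pretrain_teacher, predict_probs, total_loss,
                           train_slfr)

TINY = dict(oscnn_out_channels=12, block_channels=(8, 8, 16, 16, 24),
            d_model=24, n_heads=2, se_reduction=4, dropout=0.0)


def tiny_spec(in_leads=1):
    return ExtractorSpec.small(in_leads=in_leads, **TINY)


def toy_records(n_per_class=8, n=128, seed=0, k=2):
    """Linearly separable toy: class c has template amplitude (c+1)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    recs = []
    for c in range(k):
        for i in range(n_per_class):
            base = (c + 1.0) * np.sin(2 * np.pi * t / 32.0)
            sig = base[None, :] * rng.uniform(0.8, 1.2, size=(12, 1)) \
                + 0.05 * rng.normal(size=(12, n))
            recs.append(ECGRecord(signal=sig, fs=250.0, label=c,
                                  patient_id=f"P{c}_{i}",
                                  record_id=f"P{c}_{i}_R0"))
    rng.shuffle(recs)
    return recs


class TestCrossEntropy:
    def test_one_hot_is_zero(self):
        p = Tensor(np.array([[0.0, 1.0, 0.0]]))
        assert cross_entropy(p, [1]).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_nine_classes_is_ln9(self):
        p = Tensor(np.full((4, 9), 1 / 9))
        assert cross_entropy(p, [0, 3, 5, 8]).item() == \
            pytest.approx(np.log(9), rel=1e-9)

    def test_monotone_in_true_class_probability(self):
        losses = [cross_entropy(Tensor(np.array([[q, 1 - q]])), [0]).item()
                  for q in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert losses == sorted(losses, reverse=True)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="labels"):
            cross_entropy(Tensor(np.full((1, 3), 1 / 3)), [3])


def test_total_loss_arithmetic():
    assert total_loss(0.5, 2.0, 0.0) == 0.5
    assert total_loss(0.5, 2.0, 1.0) == 2.5
    assert total_loss(0.5, 2.0, 2.0) == 4.5
    with pytest.raises(ValueError, match="alpha"):
        total_loss(0.5, 2.0, -1.0)


class TestPlateauScheduler:
    def test_halves_at_fifth_nonimproving_epoch(self):
        history = [1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99]
        # four non-improving epochs: unchanged
        assert plateau_schedule(history[:-1], 1e-4) == 1e-4
        # the fifth triggers the halving
        assert plateau_schedule(history, 1e-4) == 5e-5

    def test_floor_respected(self):
        lr = plateau_schedule([1.0] + [2.0] * 100, 1e-7, min_lr=1e-7)
        assert lr == 1e-7

    def test_improving_history_keeps_lr(self):
        assert plateau_schedule(list(np.linspace(1, 0.1, 30)), 1e-4) == 1e-4

    def test_counter_resets_on_improvement(self):
        history = [1.0, 1.1, 1.1, 1.1, 1.1, 0.5, 1.0, 1.0, 1.0, 1.0]
        assert plateau_schedule(history, 1e-4) == 1e-4


class TestVariantWiring:
    def test_baseline_has_no_recon_or_fusion(self):
        m = SLFRModel(tiny_spec(), 2, variant="baseline_single")
        assert m.recon is None and m.fusion is None

    def test_supervise_only_aligns_raw_features(self):
        m = SLFRModel(tiny_spec(), 2, variant="supervise_only")
        assert m.recon is None and m.fusion is None
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 128)))
        m.eval()
        with nn.no_grad():
            probs, f_student = m(x)
        np.testing.assert_array_equal(f_student.numpy(),
                                      m.extractor(x).numpy())

    def test_no_fusion_classifies_reconstruction(self):
        m = SLFRModel(tiny_spec(), 2, variant="no_fusion")
        assert m.recon is not None and m.fusion is None

    def test_full_has_all_modules(self):
        m = SLFRModel(tiny_spec(), 2, variant="full")
        assert m.recon is not None and m.fusion is not None


def test_alpha_zero_silences_classifier_gradients():
    """With alpha = 0 the cross-entropy path contributes no gradient: only
    the reconstruction branch learns."""
    from slfr.reconstruction import recon_loss
    m = SLFRModel(tiny_spec(), 2, variant="full", seed=0).train()
    x = Tensor(np.random.default_rng(0).normal(size=(2, 1, 128)))
    f_full = np.random.default_rng(1).normal(size=(2, 2, 24))
    probs, f_rec = m(x)
    l1 = recon_loss(f_rec, Tensor(f_full))
    ce = cross_entropy(probs, [0, 1])
    total_loss(l1, ce, 0.0).backward()
    clf_grads = [p.grad for _, p in m.classifier.named_parameters()]
    assert all(g is None or not np.any(g) for g in clf_grads)
    recon_grads = [p.grad for _, p in m.recon.named_parameters()]
    assert any(g is not None and np.any(g) for g in recon_grads)


@pytest.fixture(scope="module")
def trained_teacher():
    recs = toy_records(n_per_class=8, seed=0)
    cfg = TrainConfig(epochs=3, batch_size=8, lr_init=3e-3, seed=0)
    bundle, log = pretrain_teacher(recs[:12], recs[12:],
                                   config=cfg, extractor_spec=tiny_spec(12))
    return bundle, log, recs


class TestPretrainTeacher:
    def test_ce_descends_on_separable_toy(self, trained_teacher):
        _, log, _ = trained_teacher
        assert log.train_ce.iloc[-1] < log.train_ce.iloc[0]

    def test_freeze_hash_recorded(self, trained_teacher):
        bundle, _, _ = trained_teacher
        assert bundle.frozen and bundle.weight_hash() == bundle.hash_at_freeze

    def test_same_seed_reproduces_weights(self):
        recs = toy_records(n_per_class=4, seed=1)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=5)
        h = [pretrain_teacher(recs[:6], recs[6:], config=cfg,
                              extractor_spec=tiny_spec(12))[0].weight_hash()
             for _ in range(2)]
        assert h[0] == h[1]

    def test_rejects_non_12_lead(self):
        recs = toy_records(n_per_class=2)
        bad = [ECGRecord(signal=r.signal[:1], fs=r.fs, label=r.label,
                         patient_id=r.patient_id, record_id=r.record_id)
               for r in recs]
        with pytest.raises(ValueError, match="12-lead"):
            pretrain_teacher(bad[:2], bad[2:], config=TrainConfig(epochs=1))


class TestTrainSLFR:
    def test_recon_loss_descends_and_teacher_untouched(self, trained_teacher):
        bundle, _, recs = trained_teacher
        hash_before = bundle.weight_hash()
        cfg = TrainConfig(epochs=4, batch_size=8, lr_init=3e-3, seed=2,
                          variant="full", steps_per_epoch=2)
        model, log = train_slfr(recs[:12], recs[12:], bundle, cfg,
                                extractor_spec=tiny_spec(1))
        assert log.val_l1.iloc[-1] < log.val_l1.iloc[0]
        assert bundle.weight_hash() == hash_before
        # loss bookkeeping: total = l1 + alpha * ce each epoch
        np.testing.assert_allclose(log.total, log.l1 + cfg.alpha * log.ce,
                                   atol=1e-6)
        probs = predict_probs(model, recs[12:], lead_indices=(0,))
        assert probs.shape == (len(recs) - 12, 2)

    def test_unfrozen_teacher_rejected(self, trained_teacher):
        bundle, _, recs = trained_teacher
        import copy
        loose = copy.copy(bundle)
        loose.frozen = False
        with pytest.raises(RuntimeError, match="frozen"):
            train_slfr(recs[:12], recs[12:], loose,
                       TrainConfig(epochs=1, variant="full"))

    def test_lead_index_out_of_range(self, trained_teacher):
        bundle, _, recs = trained_teacher
        cfg = TrainConfig(epochs=1, variant="full", lead_indices=(12,))
        with pytest.raises(ValueError, match="lead index"):
            train_slfr(recs[:12], recs[12:], bundle, cfg,
                       extractor_spec=tiny_spec(1))

    def test_baseline_needs_no_teacher(self, trained_teacher):
        _, _, recs = trained_teacher
        cfg = TrainConfig(epochs=1, batch_size=8, variant="baseline_single",
                          steps_per_epoch=1, seed=3)
        model, log = train_slfr(recs[:12], recs[12:], None, cfg,
                                extractor_spec=tiny_spec(1))
        assert (log.l1 == 0).all()
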