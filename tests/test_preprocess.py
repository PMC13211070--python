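"""Conditioning-chain checks, with an independent frequency-response oracle
for the band-pass stage and counting/leakage checks for the partitioning."""

import numpy as np
import pytest
from scipy import signal as sps

from slfr import preprocess as pp
from slfr.synth_ecg import ECGRecord


CFG = pp.PreprocessConfig()


def filter_magnitude_oracle(freq_hz: float, fs: float,
                            config=CFG) -> float:
    """|H(f)| of the zero-phase filter = squared magnitude of the one-pass
    Butterworth response, evaluated independently via sosfreqz."""
    sos = sps.butter(config.filter_order, [config.band_low, config.band_high],
                     btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def central(x, frac=0.5):
    n = x.shape[-1]
    lo = int(n * (1 - frac) / 2)
    return x[..., lo:n - lo]


class TestBandpass:
    def test_dc_suppressed(self):
        x = np.full((2, 5000), 3.0)
        y = pp.bandpass_filter(x, 500.0, CFG)
        assert np.abs(central(y)).max() < 1e-3 * 3.0

    def test_passband_sinusoid_preserved(self):
        fs, f0 = 500.0, 10.0
        t = np.arange(int(fs * 30)) / fs
        x = np.sin(2 * np.pi * f0 * t)[None]
        y = pp.bandpass_filter(x, fs, CFG)
        ratio = np.sqrt(np.mean(central(y) ** 2) / np.mean(central(x) ** 2))
        assert abs(ratio - 1.0) < 0.05
        assert abs(ratio - filter_magnitude_oracle(f0, fs)) < 0.05

    def test_stopband_attenuation_matches_oracle(self):
        fs, f0 = 500.0, 120.0
        t = np.arange(int(fs * 30)) / fs
        x = np.sin(2 * np.pi * f0 * t)[None]
        y = central(pp.bandpass_filter(x, fs, CFG))[0]
        tc = central(t[None])[0]
        # lock-in projection isolates the 120 Hz component from the slow
        # edge transients the zero-phase filter leaves at the borders
        amp = 2 * np.hypot(np.mean(y * np.sin(2 * np.pi * f0 * tc)),
                           np.mean(y * np.cos(2 * np.pi * f0 * tc)))
        oracle = filter_magnitude_oracle(f0, fs)
        assert amp == pytest.approx(oracle, rel=0.10)

    def test_nyquist_violation_named(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_filter(np.zeros((1, 100)), 80.0, CFG)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 1, 2000))
        lhs = pp.bandpass_filter(2.0 * x + 3.0 * y, 500.0, CFG)
        rhs = 2.0 * pp.bandpass_filter(x, 500.0, CFG) \
            + 3.0 * pp.bandpass_filter(y, 500.0, CFG)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-6, atol=1e-9)


class TestZscore:
    def test_standardizes_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 3.0, size=(3, 1000))
        z = pp.zscore_normalize(x)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(pp.zscore_normalize(5.0 * x - 7.0), z,
                                   atol=1e-9)

    def test_constant_lead_guard(self):
        x = np.vstack([np.full(100, 4.2), np.arange(100.0)])
        z = pp.zscore_normalize(x)
        np.testing.assert_array_equal(z[0], 0.0)
        assert z[1].std() == pytest.approx(1.0)


class TestResample:
    def test_length_and_identity(self):
        x = np.zeros((1, 5000))
        assert pp.resample(x, 500.0, 250.0).shape == (1, 2500)
        np.testing.assert_array_equal(pp.resample(x, 250.0, 250.0), x)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            pp.resample(np.zeros((1, 10)), 250.0, 500.0)

    def test_sinusoid_against_analytic_oracle(self):
        fs_in, fs_out, f0 = 500.0, 250.0, 5.0
        t_in = np.arange(int(fs_in * 10)) / fs_in
        x = np.sin(2 * np.pi * f0 * t_in)[None]
        y = pp.resample(x, fs_in, fs_out)[0]
        t_out = np.arange(len(y)) / fs_out
        ref = np.sin(2 * np.pi * f0 * t_out)
        core = slice(50, len(y) - 50)  # polyphase edges excluded
        corr = np.corrcoef(y[core], ref[core])[0, 1]
        assert corr > 0.999


class TestFixLength:
    def test_truncation_then_divisibility_padding(self):
        x = np.ones((1, 7500))  # 30 s at 250 Hz
        out = pp.fix_length(x, 250.0, CFG)
        assert out.shape == (1, 5056)
        np.testing.assert_array_equal(out[0, :5000], 1.0)
        np.testing.assert_array_equal(out[0, 5000:], 0.0)

    def test_eval_end_padding(self):
        x = np.ones((1, 2500))  # 10 s at 250 Hz
        out = pp.fix_length(x, 250.0, CFG)
        assert out.shape == (1, 5056)
        np.testing.assert_array_equal(out[0, :2500], 1.0)
        np.testing.assert_array_equal(out[0, 2500:], 0.0)

    def test_train_random_padding_deterministic_and_bounded(self):
        cfg = pp.PreprocessConfig(pad_mode="train_random")
        x = np.ones((1, 2500))
        out1 = pp.fix_length(x, 250.0, cfg, rng=np.random.default_rng(3))
        out2 = pp.fix_length(x, 250.0, cfg, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(out1, out2)
        left = int(np.argmax(out1[0] != 0))
        assert 0 <= left <= 2500
        assert out1.shape == (1, 5056)
        assert out1.sum() == 2500

    def test_output_length_divisible_by_64(self):
        for secs in (3.3, 10.0, 20.0, 33.0):
            x = np.ones((1, int(250 * secs)))
            assert pp.fix_length(x, 250.0, CFG).shape[-1] % 64 == 0


def _toy_records(n_patients, rpp=1, n=100, label=0):
    recs = []
    for p in range(n_patients):
        for r in range(rpp):
            recs.append(ECGRecord(signal=np.zeros((12, n)), fs=250.0,
                                  label=label, patient_id=f"P{p}",
                                  record_id=f"P{p}_R{r}"))
    return recs


class TestQualityFilter:
    def test_nan_excluded_as_incomplete(self):
        recs = _toy_records(3)
        recs[1].signal[0, 0] = np.nan
        survivors, log = pp.quality_filter(recs, CFG)
        assert len(survivors) == 2
        assert log.excluded == [("P1_R0", "incomplete")]

    def test_amplitude_spike_excluded(self):
        recs = _toy_records(5)
        recs[2].signal[3, 10] = 10 * CFG.amplitude_limit
        survivors, log = pp.quality_filter(recs, CFG)
        assert len(survivors) == 4
        assert log.excluded == [("P2_R0", "amplitude_anomaly")]

    def test_clean_batch_identity(self):
        recs = _toy_records(4)
        survivors, log = pp.quality_filter(recs, CFG)
        assert survivors == recs and log.excluded == []


class TestSplit:
    def test_ten_singleton_patients_split_7_1_2(self):
        assignment = pp.split_patients(_toy_records(10), seed=5)
        sizes = {s: sum(v == s for v in assignment.values())
                 for s in ("train", "val", "test")}
        assert sizes == {"train": 7, "val": 1, "test": 2}

    def test_no_patient_spans_splits(self):
        recs = _toy_records(9, rpp=3)
        assignment = pp.split_patients(recs, seed=1)
        per_patient = {}
        for rec in recs:
            per_patient.setdefault(rec.patient_id, set()).add(
                assignment[rec.record_id])
        assert all(len(s) == 1 for s in per_patient.values())
        assert set(assignment) == {r.record_id for r in recs}

    def test_deterministic_and_min_patients(self):
        recs = _toy_records(10)
        assert pp.split_patients(recs, seed=2) == pp.split_patients(recs, seed=2)
        with pytest.raises(ValueError, match="3 patients"):
            pp.split_patients(_toy_records(2))


class TestBalancedSampler:
    def test_uniform_class_frequency_binomial_bound(self):
        labels = np.array([0] * 100 + [1])
        stream = pp.balanced_sampler(labels, np.random.default_rng(0))
        n = 10_000
        draws = np.array([next(stream) for _ in range(n)])
        freq1 = np.mean(labels[draws] == 1)
        sigma = np.sqrt(0.25 / n)
        assert abs(freq1 - 0.5) < 3 * sigma

    def test_single_class_and_determinism(self):
        labels = np.array([2, 2, 2])
        stream = pp.balanced_sampler(labels, np.random.default_rng(1))
        assert {labels[next(stream)] for _ in range(20)} == {2}
        s1 = pp.balanced_sampler(np.arange(10) % 3, np.random.default_rng(9))
        s2 = pp.balanced_sampler(np.arange(10) % 3, np.random.default_rng(9))
        assert [next(s1) for _ in range(100)] == [next(s2) for _ in range(100)]


def test_full_chain_contract():
    """500 Hz record in, 250 Hz fixed-length standardized record out."""
    rng = np.random.default_rng(0)
    rec = ECGRecord(signal=rng.normal(size=(12, 5000)), fs=500.0, label=0,
                    patient_id="P0", record_id="P0_R0")
    out = pp.preprocess_record(rec, CFG)
    assert out.fs == 250.0
    assert out.n_samples == CFG.padded_len == 5056
    assert out.n_samples % 64 == 0
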