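import numpy as np
import pytest

from polysorter.recording_io import (MAD_TO_SIGMA, ProbeGeometry, VoltageRecord,
                                     estimate_noise, read_recording,
                                     remove_common_mean, sample_hold_correct,
                                     sample_hold_delays, spatial_smooth,
                                     temporal_smooth, write_recording)


def make_record(V, probe=None, masked=()):
    V = np.asarray(V, dtype=float)
    if probe is None:
        pos = np.column_stack([np.zeros(V.shape[0]),
                               np.arange(V.shape[0]) * 50.0])
        probe = ProbeGeometry(positions=pos, masked=frozenset(masked))
    return VoltageRecord(V, 40.0, probe)


class TestGeometry:
    def test_neighbor_symmetry_and_irreflexivity(self):
        rng = np.random.default_rng(0)
        probe = ProbeGeometry(positions=rng.uniform(0, 300, (12, 2)),
                              neighbor_radius_um=120.0)
        for n in range(12):
            assert n not in probe.neighbors(n)
            for m in probe.neighbors(n):
                assert n in probe.neighbors(m)

    def test_masked_must_be_valid(self):
        with pytest.raises(ValueError):
            ProbeGeometry(positions=np.zeros((2, 2)), masked=frozenset({5}))

    def test_masked_excluded_from_neighbors(self):
        pos = np.array([[0.0, 0.0], [0.0, 50.0], [0.0, 100.0]])
        probe = ProbeGeometry(positions=pos, masked=frozenset({1}))
        assert 1 not in probe.neighbors(0)


class TestIO:
    def test_zero_roundtrip(self, tmp_path):
        rec = make_record(np.zeros((2, 4)))
        write_recording(rec, tmp_path / "z.bin")
        back = read_recording(tmp_path / "z.bin")
        assert back.V.shape == (2, 4)
        assert np.all(back.V == 0)

    def test_roundtrip_bit_exact(self, tmp_path, noise_record):
        # gain 0.25 uV/LSB: quantize first so the round trip is exact
        q = make_record(np.round(noise_record.V / 0.25) * 0.25,
                        probe=noise_record.geometry)
        write_recording(q, tmp_path / "r.bin", gain_uV=0.25)
        back = read_recording(tmp_path / "r.bin")
        np.testing.assert_array_equal(back.V, q.V)
        assert back.dt_us == q.dt_us
        np.testing.assert_array_equal(back.geometry.positions,
                                      q.geometry.positions)

    def test_gain_scaling(self, tmp_path):
        samples = np.array([[1, -2, 3, 30000], [0, 7, -7, -30000]], dtype="<i2")
        samples.T.tofile(tmp_path / "g.bin")
        import yaml
        meta = {"n_channels": 2, "dtype": "int16", "gain_uV": 0.5,
                "dt_us": 40.0, "positions": [[0, 0], [0, 50]], "masked": []}
        (tmp_path / "g.yaml").write_text(yaml.safe_dump(meta))
        rec = read_recording(tmp_path / "g.bin")
        np.testing.assert_allclose(rec.V, samples.astype(float) * 0.5)

    def test_size_mismatch_rejected(self, tmp_path):
        np.zeros(7, dtype="<i2").tofile(tmp_path / "bad.bin")
        import yaml
        meta = {"n_channels": 2, "dtype": "int16", "gain_uV": 1.0,
                "dt_us": 40.0, "positions": [[0, 0], [0, 50]]}
        (tmp_path / "bad.yaml").write_text(yaml.safe_dump(meta))
        with pytest.raises(ValueError, match="not divisible"):
            read_recording(tmp_path / "bad.bin")


class TestCommonMean:
    def test_common_signal_cancels(self):
        t = np.arange(200)
        sine = 30 * np.sin(2 * np.pi * t / 40)
        rec = make_record(np.tile(sine, (4, 1)))
        out = remove_common_mean(rec)
        np.testing.assert_allclose(out.V, 0, atol=1e-10)

    def test_impulse_redistribution(self):
        V = np.zeros((5, 10))
        V[2, 3] = 10.0
        out = remove_common_mean(make_record(V))
        assert out.V[2, 3] == pytest.approx(10 * (1 - 1 / 5))
        assert out.V[0, 3] == pytest.approx(-10 / 5)

    def test_mean_zero_and_idempotent(self, noise_record):
        out = remove_common_mean(noise_record)
        np.testing.assert_allclose(out.V.mean(axis=0), 0, atol=1e-10)
        again = remove_common_mean(out)
        np.testing.assert_allclose(again.V, out.V, atol=1e-10)

    def test_masked_excluded(self):
        V = np.ones((3, 4)) * 6.0
        rec = make_record(V, masked={2})
        out = remove_common_mean(rec)
        np.testing.assert_allclose(out.V[:2], 0, atol=1e-12)
        np.testing.assert_allclose(out.V[2], 0)  # masked stays zero

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            remove_common_mean(make_record(np.ones((2, 4)), masked={1}))


class TestTemporalSmooth:
    def test_constant_unchanged(self):
        rec = make_record(np.full((2, 50), 7.0))
        out = temporal_smooth(rec, passes=5)
        np.testing.assert_allclose(out.V, 7.0)

    def test_impulse_kernel(self):
        V = np.zeros((1, 11))
        V[0, 5] = 1.0
        out = temporal_smooth(make_record(V), passes=1)
        np.testing.assert_allclose(out.V[0, 4:7], [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("passes", [1, 2, 4])
    def test_matches_repeated_convolution(self, passes, noise_record):
        out = temporal_smooth(noise_record, passes=passes)
        expect = noise_record.V.copy()
        for _ in range(passes):
            padded = np.pad(expect, ((0, 0), (1, 1)), mode="edge")
            expect = np.convolve(np.ones(1), [1])[0] * (
                0.5 * padded[:, 1:-1] + 0.25 * padded[:, 2:] + 0.25 * padded[:, :-2])
        np.testing.assert_allclose(out.V, expect, atol=1e-12)

    def test_never_amplifies(self, noise_record):
        out = temporal_smooth(noise_record, passes=3)
        assert np.abs(out.V).max() <= np.abs(noise_record.V).max() + 1e-12


class TestSpatialSmooth:
    def test_uniform_signal_preserved(self, noise_record):
        V = np.tile(noise_record.V[0], (8, 1))
        rec = VoltageRecord(V, 40.0, noise_record.geometry)
        out = spatial_smooth(rec, 60.0)
        np.testing.assert_allclose(out.V, V, atol=1e-9)

    def test_tiny_sigma_is_identity(self, noise_record):
        out = spatial_smooth(noise_record, 1.0)
        np.testing.assert_allclose(out.V, noise_record.V, atol=1e-6)

    def test_two_site_weights_by_hand(self, two_site_probe):
        V = np.array([[10.0, 0.0], [0.0, 20.0]])
        rec = VoltageRecord(V.copy(), 40.0, two_site_probe)
        out = spatial_smooth(rec, 50.0)
        w = np.exp(-50.0**2 / (2 * 50.0**2))  # neighbor weight before norm
        expect00 = (10.0 * 1 + 0.0 * w) / (1 + w)
        expect10 = (10.0 * w + 0.0 * 1) / (1 + w)
        assert out.V[0, 0] == pytest.approx(expect00)
        assert out.V[1, 0] == pytest.approx(expect10)

    def test_rejects_bad_sigma(self, noise_record):
        with pytest.raises(ValueError):
            spatial_smooth(noise_record, 0.0)


class TestSampleHold:
    def test_zero_delay_identity(self, noise_record):
        out = sample_hold_correct(noise_record, np.zeros(8))
        np.testing.assert_allclose(out.V, noise_record.V)

    def test_sinusoid_phase_shift(self):
        t = np.arange(2000)
        f = 1.0 / 25.0  # 1 kHz at 25 kHz
        V = np.vstack([np.sin(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
        rec = make_record(V)
        delays = np.array([0.0, 31.0])
        out = sample_hold_correct(rec, delays)
        expect = np.sin(2 * np.pi * f * (t + 31.0 / 40.0))
        err = np.abs(out.V[1, 50:-50] - expect[50:-50]).max()
        assert err < 0.01  # within 1% of unit amplitude away from edges

    def test_max_delay_two_boards(self):
        delays = sample_hold_delays(n_boards=2, channels_per_board=32,
                                    hold_us=1.0)
        assert len(delays) == 64
        assert delays.max() - delays.min() == 31.0

    def test_rejects_delay_at_dt(self, noise_record):
        with pytest.raises(ValueError):
            sample_hold_correct(noise_record, np.full(8, 40.0))


class TestNoiseEstimate:
    def test_constant_magnitude(self):
        rec = make_record(np.full((2, 500), 3.0))
        est = estimate_noise(rec)
        np.testing.assert_allclose(est.sigma_uV, 3.0 / MAD_TO_SIGMA)

    def test_gaussian_consistency(self):
        rng = np.random.default_rng(7)
        rec = make_record(rng.normal(0, 10.0, (2, 1_000_000)))
        est = estimate_noise(rec)
        np.testing.assert_allclose(est.sigma_uV, 10.0, atol=0.1)

    def test_robust_to_sparse_spikes(self):
        rng = np.random.default_rng(8)
        V = rng.normal(0, 10.0, (1, 200_000))
        idx = rng.choice(V.shape[1], 1500, replace=False)  # <1% of samples
        V[0, idx] += -300.0
        rec = make_record(V)
        est = estimate_noise(rec)
        rms = float(np.sqrt(np.mean(V**2)))
        assert abs(est.sigma_uV[0] - 10.0) / 10.0 < 0.10
        assert rms > 1.5 * 10.0  # RMS blows up where the MAD does not

    def test_masked_channels_zero(self):
        rec = make_record(np.random.default_rng(0).normal(0, 5, (3, 1000)),
                          masked={1})
        est = estimate_noise(rec)
        assert est.sigma_uV[1] == 0.0
        assert np.all(est.sigma_uV[[0, 2]] > 0)
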