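"""Forward model: patterned projection and beat-signal synthesis."""

import warnings

import numpy as np
import pytest

from spholo import (
    AcquisitionConfig,
    ComplexImage,
    HadamardPlan,
    InvalidArgumentError,
    SamplingPlan,
    acquire,
    basis_pattern,
    project_and_sum,
    synthesize_beat,
)
from tests.conftest import random_object


class TestAcquisitionConfig:
    def test_defaults_give_60_samples_and_3_cycles(self):
        cfg = AcquisitionConfig()
        assert cfg.samples_per_record == 60
        assert cfg.cycles_per_pattern == pytest.approx(3.0)
        assert cfg.integer_cycles

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AcquisitionConfig(beat_freq=7e5, sample_rate=1.25e6)

    def test_non_integer_cycles_warns_but_accepts(self):
        with pytest.warns(UserWarning, match="integer"):
            cfg = AcquisitionConfig(refresh_time=1 / 22_000)
        assert not cfg.integer_cycles


class TestProjectAndSum:
    def test_uniform_object_dc_binary_pattern(self):
        plan = HadamardPlan(4)
        obj = ComplexImage(np.ones((4, 4)), np.zeros((4, 4)))
        val = project_and_sum(obj, basis_pattern(plan, 1, "binary"))
        assert val == pytest.approx(4.0)  # sqrt(N) * A

    @pytest.mark.parametrize("n", [2, 7, 16])
    def test_uniform_object_balanced_binary_pattern_gives_half_dc(self, n):
        plan = HadamardPlan(4)
        obj = ComplexImage(np.ones((4, 4)), np.zeros((4, 4)))
        val = project_and_sum(obj, basis_pattern(plan, n, "binary"))
        assert val == pytest.approx(2.0)

    def test_bipolar_equals_two_binary_minus_dc(self, plan8, rng):
        obj = random_object(8, rng)
        dc = project_and_sum(obj, basis_pattern(plan8, 1, "binary"))
        for n in (2, 17, 40, 64):
            bi = project_and_sum(obj, basis_pattern(plan8, n, "bipolar"))
            b = project_and_sum(obj, basis_pattern(plan8, n, "binary"))
            assert bi == pytest.approx(2 * b - dc, abs=1e-12)

    def test_size_mismatch_rejected(self, plan8, rng):
        with pytest.raises(InvalidArgumentError):
            project_and_sum(random_object(16, rng), basis_pattern(plan8, 1))


class TestSynthesizeBeat:
    def test_zero_coefficient_gives_constant_dc_record(self, noise_free):
        rec = synthesize_beat(0.0, 1, noise_free, dc_signal=0.25)
        assert np.allclose(rec.samples, noise_free.dc_reference + 0.25)

    def test_unit_coefficient_waveform_and_count(self):
        cfg = AcquisitionConfig(noise_rel=0.0, dc_reference=5.0)
        rec = synthesize_beat(1.0, 1, cfg, dc_signal=0.0)
        t = rec.times(cfg)
        assert len(rec.samples) == 60
        assert np.allclose(rec.samples, 5.0 + 2.0 * np.cos(2 * np.pi * 62_500.0 * t))
        # exactly three full beat cycles span the record
        assert cfg.refresh_time * cfg.beat_freq == pytest.approx(3.0)

    def test_carrier_phase_identical_at_every_record_start(self, noise_free):
        recs = [
            synthesize_beat(1.0, k + 1, noise_free, t_start=k * noise_free.refresh_time)
            for k in range(5)
        ]
        first_samples = np.array([r.samples[0] for r in recs])
        assert np.allclose(first_samples, first_samples[0])

    def test_noise_magnitude_matches_relative_std(self):
        cfg = AcquisitionConfig(noise_rel=0.001, dc_reference=10.0)
        clean = synthesize_beat(0.0, 1, AcquisitionConfig(noise_rel=0.0, dc_reference=10.0))
        rng = np.random.default_rng(0)
        devs = []
        for _ in range(200):  # 200 x 60 = 12,000 samples
            rec = synthesize_beat(0.0, 1, cfg, rng=rng)
            devs.append(rec.samples - clean.samples)
        emp = np.std(np.concatenate(devs))
        assert emp == pytest.approx(0.001 * 10.0, rel=0.2)

    def test_noise_free_record_fit_exactly_by_single_tone(self, noise_free, rng):
        c = 0.8 * np.exp(1j * 1.1)
        rec = synthesize_beat(c, 3, noise_free, t_start=0.0, dc_signal=0.4)
        t = rec.times(noise_free)
        design = np.column_stack(
            [np.ones_like(t), np.cos(2 * np.pi * noise_free.beat_freq * t),
             np.sin(2 * np.pi * noise_free.beat_freq * t)]
        )
        sol, res, *_ = np.linalg.lstsq(design, rec.samples, rcond=None)
        residual = np.linalg.norm(design @ sol - rec.samples)
        assert residual < 1e-9

    def test_non_finite_coefficient_rejected(self, noise_free):
        with pytest.raises(InvalidArgumentError):
            synthesize_beat(complex(np.nan, 0.0), 1, noise_free)


class TestAcquire:
    def test_record_count_and_timing(self, plan16, noise_free, rng):
        obj = random_object(16, rng)
        recs = acquire(obj, plan16, SamplingPlan(plan16, 1.0), noise_free)
        assert len(recs) == 256
        assert all(len(r.samples) == 60 for r in recs)
        starts = np.array([r.t_start for r in recs])
        assert np.allclose(starts, np.arange(256) * noise_free.refresh_time)
        assert len(recs) * noise_free.refresh_time == pytest.approx(256 * 48e-6)

    def test_fast_path_matches_per_pattern_projection(self, plan8, noise_free, rng):
        obj = random_object(8, rng)
        fast = acquire(obj, plan8, None, noise_free, method="fast")
        direct = acquire(obj, plan8, None, noise_free, method="direct")
        for a, b in zip(fast, direct):
            assert a.order == b.order
            assert np.max(np.abs(a.samples - b.samples)) < 1e-10

    def test_sampling_without_dc_rejected(self, plan8, noise_free, rng):
        obj = random_object(8, rng)
        sampling = SamplingPlan(plan8, 0.5)
        sampling.orders = sampling.orders[1:]  # drop the DC order
        with pytest.raises(InvalidArgumentError):
            acquire(obj, plan8, sampling, noise_free)

    def test_seed_controls_noise_stream(self, plan8, rng):
        obj = random_object(8, rng)
        cfg = AcquisitionConfig(noise_rel=0.001)
        a = acquire(obj, plan8, None, cfg, seed=5)
        b = acquire(obj, plan8, None, cfg, seed=5)
        c = acquire(obj, plan8, None, cfg, seed=6)
        assert np.array_equal(a[3].samples, b[3].samples)
        assert not np.array_equal(a[3].samples, c[3].samples)
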