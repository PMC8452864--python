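"""Harmonic-model fits, HNR, voicing, TV extension, jitter/shimmer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmvoice import harmonic_model as hm
from hmvoice import synthvoice as sv

FS = 16000.0
T = np.arange(400) / FS


class TestDesignMatrix:
    def test_first_row_identity(self):
        X = hm.design_matrix(200.0, 1, T)
        assert np.allclose(X[0], [1.0, 1.0, 0.0])

    def test_column_count(self):
        assert hm.design_matrix(200.0, 10, T).shape[1] == 21

    def test_orthogonality_for_integer_cycles(self):
        # 5 cycles of 200 Hz in 400 samples at 16 kHz
        X = hm.design_matrix(200.0, 5, T)
        G = X.T @ X
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * len(T)
        assert np.allclose(np.diag(G)[1:], len(T) / 2)

    def test_aliasing_error_names_harmonic(self):
        with pytest.raises(ValueError, match="harmonic"):
            hm.design_matrix(900.0, 10, T)


class TestFitHarmonicMap:
    def test_exact_recovery_in_model_span(self):
        y = 2 * np.cos(2 * np.pi * 200 * T) + 1 * np.sin(2 * np.pi * 400 * T)
        fit = hm.fit_harmonic_map(y, 200.0, 5, FS, ridge_lambda=0.0)
        assert fit.alpha == pytest.approx([2, 0, 0, 0, 0], abs=1e-9)
        assert fit.beta == pytest.approx([0, 1, 0, 0, 0], abs=1e-9)
        assert fit.residual_energy < 1e-18

    def test_lambda_zero_equals_least_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=400)
            fit = hm.fit_harmonic_map(y, 220.0, 8, FS, ridge_lambda=0.0)
            X = hm.design_matrix(220.0, 8, T)
            ref, *_ = np.linalg.lstsq(X, y, rcond=None)
            got = np.concatenate([[fit.a0], np.ravel(np.column_stack([fit.alpha, fit.beta]))])
            assert np.allclose(got, ref, atol=1e-8)

    def test_residual_non_increasing_in_H(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=400)
        res = [
            hm.fit_harmonic_map(y, 200.0, H, FS, ridge_lambda=0.0).residual_energy
            for H in range(1, 11)
        ]
        assert np.all(np.diff(res) <= 1e-9)

    def test_large_ridge_shrinks_to_mean(self):
        y = 3.0 + np.cos(2 * np.pi * 200 * T)
        fit = hm.fit_harmonic_map(y, 200.0, 3, FS, ridge_lambda=1e12)
        assert np.max(np.abs(fit.alpha)) < 1e-4
        assert fit.a0 == pytest.approx(np.mean(y), abs=1e-4)

    def test_white_noise_has_negative_hnr(self):
        rng = np.random.default_rng(2)
        hnrs = [
            hm.hnr_db(hm.fit_harmonic_map(rng.normal(size=400), 200.0, 10, FS))
            for _ in range(20)
        ]
        assert np.mean(hnrs) < 0.0
        assert np.mean(np.array(hnrs) < 0) >= 0.9


class TestHnr:
    def test_log_identity(self):
        fit = hm.fit_harmonic_map(np.cos(2 * np.pi * 200 * T), 200.0, 1, FS)
        fit.harmonic_energy, fit.residual_energy = 0.5, 0.05
        assert hm.hnr_db(fit) == pytest.approx(10.0)
        fit.residual_energy = 0.5
        assert hm.hnr_db(fit) == pytest.approx(0.0)

    def test_zero_residual_capped(self):
        fit = hm.fit_harmonic_map(np.cos(2 * np.pi * 200 * T), 200.0, 1, FS, 0.0)
        assert hm.hnr_db(fit) <= 60.0

    def test_recovery_at_known_hnr(self):
        spec = sv.VoicedSpec(duration_s=1.0, f0_contour=200.0, n_harmonics=5,
                             hnr_db=15.0, seed=5)
        wave, _ = sv.synth_voiced(spec)
        frames = wave[: 400 * 40].reshape(-1, 400)
        est = np.mean(
            [hm.hnr_db(hm.fit_harmonic_map(f, 200.0, 10, FS)) for f in frames]
        )
        assert est == pytest.approx(15.0, abs=1.0)

    def test_monotone_in_true_hnr(self):
        means = []
        for h in (0.0, 5.0, 10.0, 20.0):
            spec = sv.VoicedSpec(duration_s=0.5, f0_contour=200.0, n_harmonics=5,
                                 hnr_db=h, seed=6)
            wave, _ = sv.synth_voiced(spec)
            frames = wave[: 400 * 19].reshape(-1, 400)
            means.append(np.mean(
                [hm.hnr_db(hm.fit_harmonic_map(f, 200.0, 10, FS)) for f in frames]
            ))
        assert np.all(np.diff(means) > 0)


class TestVoicing:
    def test_harmonic_frames_voiced_noise_unvoiced(self, rich_voiced):
        wave, _ = rich_voiced
        frames = wave[: 400 * 20].reshape(-1, 400)
        hnrs = np.array(
            [hm.hnr_db(hm.fit_harmonic_map(f, 200.0, 10, FS)) for f in frames]
        )
        assert hm.classify_voicing(hnrs).all()
        rng = np.random.default_rng(3)
        noise_hnrs = np.array(
            [
                hm.hnr_db(hm.fit_harmonic_map(rng.normal(size=400), 200.0, 10, FS))
                for _ in range(30)
            ]
        )
        assert np.mean(~hm.classify_voicing(noise_hnrs)) >= 0.9


class TestTVHarmonic:
    def test_b1_reproduces_fixed_fit(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=400)
        fixed = hm.fit_harmonic_map(y, 200.0, 5, FS, ridge_lambda=0.0)
        tv = hm.fit_tv_harmonic(y, 200.0, 5, FS, basis_order=1)
        assert tv.a0 == pytest.approx(fixed.a0, abs=1e-9)
        assert np.allclose(tv.alpha_traj[:, 0], fixed.alpha, atol=1e-9)
        assert np.allclose(tv.beta_traj[:, 0], fixed.beta, atol=1e-9)
        assert tv.residual_energy == pytest.approx(fixed.residual_energy, rel=1e-9)

    def test_stationary_input_constant_trajectories(self):
        y = np.cos(2 * np.pi * 200 * T)
        tv = hm.fit_tv_harmonic(y, 200.0, 3, FS, basis_order=3)
        assert np.ptp(tv.alpha_traj[0]) < 1e-6
        assert np.allclose(tv.envelope, 1.0, atol=1e-6)

    def test_nested_residual_not_worse_than_fixed(self, rich_voiced):
        wave, _ = rich_voiced
        y = wave[:400]
        fixed = hm.fit_harmonic_map(y, 200.0, 5, FS, ridge_lambda=0.0)
        tv = hm.fit_tv_harmonic(y, 200.0, 5, FS, basis_order=3)
        assert tv.residual_energy <= fixed.residual_energy + 1e-9

    def test_linear_amplitude_ramp_recovered(self):
        ramp = np.linspace(1.0, 2.0, 400)
        y = ramp * np.cos(2 * np.pi * 200 * T)
        tv = hm.fit_tv_harmonic(y, 200.0, 1, FS, basis_order=3)
        slope_true = (2.0 - 1.0) / (400 / FS)
        interior = slice(40, 360)
        slope_est = np.polyfit(T[interior], tv.envelope[interior], 1)[0]
        assert slope_est == pytest.approx(slope_true, rel=0.05)

    def test_cycle_count_matches_frame(self):
        spec = sv.VoicedSpec(duration_s=0.025, f0_contour=200.0, n_harmonics=3)
        wave, _ = sv.synth_voiced(spec)
        tv = hm.fit_tv_harmonic(wave, 200.0, 3, FS, basis_order=3)
        # 25 ms at 200 Hz holds 5 cycles -> 5 +- 1 marks
        n_marks = len(tv.cycle_periods_s) + 1
        assert abs(n_marks - 5) <= 1

    def test_basis_too_large_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            hm.fit_tv_harmonic(np.zeros(50), 200.0, 10, FS, basis_order=3)


class TestJitterShimmerFormulas:
    def test_constant_periods_zero(self):
        assert hm.estimate_jitter([0.005] * 10) == 0.0
        assert hm.estimate_shimmer([1.0] * 10) == 0.0

    def test_adopted_formula_values(self):
        periods = np.array([10.0, 10.2, 10.0, 10.2]) * 1e-3
        assert hm.estimate_jitter(periods) == pytest.approx(0.2 / 10.1 * 100, rel=1e-6)
        amps = [1.0, 1.1, 1.0]
        assert hm.estimate_shimmer(amps) == pytest.approx(0.1 / (3.1 / 3) * 100, rel=1e-6)

    def test_too_few_cycles_missing(self):
        assert np.isnan(hm.estimate_jitter([0.005, 0.005]))
        assert np.isnan(hm.estimate_shimmer([1.0, 1.0]))

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        periods = np.array([5.0, 5.1, 4.9, 5.2, 5.0])
        assert hm.estimate_jitter(k * periods) == pytest.approx(
            hm.estimate_jitter(periods), rel=1e-9
        )
        assert hm.estimate_shimmer(k * periods) == pytest.approx(
            hm.estimate_shimmer(periods), rel=1e-9
        )


class TestSegmentCycleMarks:
    def test_jitter_recovery_from_marks(self):
        spec = sv.VoicedSpec(duration_s=1.0, f0_contour=200.0, n_harmonics=5,
                             jitter_pct=2.0, hnr_db=25.0, seed=7)
        wave, truth = sv.synth_voiced(spec)
        _, periods, _ = hm.segment_cycle_marks(wave, FS, 200.0)
        est = hm.estimate_jitter(periods)
        ref = hm.estimate_jitter(truth.cycle_periods_s)
        assert est == pytest.approx(ref, rel=0.2)

    def test_shimmer_recovery_from_marks(self):
        spec = sv.VoicedSpec(duration_s=1.0, f0_contour=200.0, n_harmonics=5,
                             jitter_pct=1.0, shimmer_pct=3.0, hnr_db=25.0, seed=7)
        wave, truth = sv.synth_voiced(spec)
        _, _, amps = hm.segment_cycle_marks(wave, FS, 200.0)
        est = hm.estimate_shimmer(amps[~np.isnan(amps)])
        ref = hm.estimate_shimmer(truth.cycle_amplitudes)
        assert est == pytest.approx(ref, rel=0.2)

    def test_too_short_input_returns_empty(self):
        t, p, a = hm.segment_cycle_marks(np.zeros(50), FS, 200.0)
        assert len(t) == len(p) == len(a) == 0
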