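"""Ground-truth generator: model construction, stability, simulation."""

import numpy as np
import pytest

from conftest import random_stable_model
from vigilnet.mvar_pdc import StabilityError, VARModel, spectral_radius
from vigilnet.synth import (
    ENHANCEMENT_BLOCK_SCALES,
    CouplingSpec,
    default_coupling_spec,
    make_var_model,
    simulate_behavior,
    simulate_session,
    simulate_var,
)


class TestMakeVarModel:
    def test_decoupled_channels_diagonal(self):
        spec = CouplingSpec(n_channels=2, edges=(), self_coef=0.5, block_scale=(1.0,))
        model = make_var_model(spec, 0)
        assert np.array_equal(model.coeffs[0], 0.5 * np.eye(2))
        assert model.spectral_radius() == pytest.approx(0.5)

    def test_edge_placed_at_target_source(self):
        spec = CouplingSpec(
            n_channels=2, edges=((0, 1, 0.7),), self_coef=np.array([0.5, 0.2]),
            block_scale=(1.0,),
        )
        model = make_var_model(spec, 0)
        assert np.allclose(model.coeffs[0], [[0.5, 0.0], [0.7, 0.2]])

    def test_block_scale_multiplies_strengths(self):
        spec = CouplingSpec(
            n_channels=3, edges=((0, 1, 0.6),), self_coef=0.3,
            block_scale=(1.0, 0.7, 0.4),
        )
        for b, scale in enumerate(spec.block_scale):
            assert make_var_model(spec, b).coeffs[0][1, 0] == pytest.approx(0.6 * scale)

    def test_unstable_construction_is_shrunk(self):
        # 10 strong edges into few nodes plus self_coef 0.99 is unstable raw
        edges = tuple((s, (s + 1) % 6, 0.9) for s in range(6)) + tuple(
            (s, (s + 2) % 6, 0.9) for s in range(4)
        )
        spec = CouplingSpec(n_channels=6, edges=edges, self_coef=0.99, block_scale=(1.0,))
        model = make_var_model(spec, 0)
        # verified independently on the companion matrix
        assert spectral_radius(model.coeffs) <= 0.95 + 1e-9

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            CouplingSpec(n_channels=2, edges=((0, 1, np.nan),), block_scale=(1.0,))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            CouplingSpec(n_channels=2, edges=((1, 1, 0.5),), block_scale=(1.0,))


class TestSimulateVar:
    def test_white_noise_unit_variance(self):
        model = VARModel(coeffs=np.zeros((1, 1, 1)), noise_cov=np.eye(1), order=1)
        x = simulate_var(model, 100_000, seed=0)
        # closed form: white noise variance = 1
        assert x.var() == pytest.approx(1.0, rel=0.05)

    def test_ar1_stationary_variance(self):
        model = VARModel(coeffs=np.full((1, 1, 1), 0.5), noise_cov=np.eye(1), order=1)
        x = simulate_var(model, 100_000, seed=1)
        # closed form: 1 / (1 - a^2) = 4/3
        assert x.var() == pytest.approx(1.0 / 0.75, rel=0.05)

    def test_seed_determinism(self):
        model = VARModel(
            coeffs=np.array([[[0.4, 0.2], [0.0, 0.3]]]), noise_cov=np.eye(2), order=1
        )
        a = simulate_var(model, 500, seed=42)
        b = simulate_var(model, 500, seed=42)
        assert np.array_equal(a, b)

    def test_unstable_model_raises(self):
        bad = VARModel(coeffs=np.full((1, 1, 1), 1.05), noise_cov=np.eye(1), order=1)
        with pytest.raises(StabilityError):
            simulate_var(bad, 100)

    def test_lag1_cross_covariance_recovers_coefficients(self, rng):
        """For a VAR(1), A = Cov(x_t, x_{t-1}) Cov(x)^-1."""
        model = random_stable_model(rng, m=3, p=1, radius=0.7)
        x = simulate_var(model, 200_000, seed=9)
        x0, x1 = x[:, 1:], x[:, :-1]
        n = x0.shape[1]
        c0 = x1 @ x1.T / n
        c1 = x0 @ x1.T / n
        A_hat = c1 @ np.linalg.inv(c0)
        assert np.allclose(A_hat, model.coeffs[0], atol=0.05)


class TestSimulateSession:
    def test_block_length_and_event_layout(self):
        sess = simulate_session(
            vigilance=True, fs=500.0, seed=0, block_minutes=0.2,
            spec=default_coupling_spec(n_channels=4),
        )
        samples = int(0.2 * 60 * 500)
        assert sess.block_bounds == ((0, samples), (samples, 2 * samples), (2 * samples, 3 * samples))
        assert np.all(np.diff(sess.events) > 0)
        ep_len = int(1.2 * 500)
        assert sess.events[-1] + ep_len <= sess.n_samples

    def test_default_block_samples_at_study_scale(self):
        # 20 min at 500 Hz = 600,000 samples; check arithmetic only
        assert int(round(20 * 60 * 500)) == 600_000

    def test_enhancement_truth_nonincreasing(self):
        sess = simulate_session(
            vigilance=False, fs=250.0, seed=3, block_minutes=0.2,
            spec=default_coupling_spec(vigilance=False, n_channels=4),
        )
        scales = sess.truth.block_scale
        assert scales == ENHANCEMENT_BLOCK_SCALES
        assert all(s2 <= s1 and s2 >= 0.95 * s1 for s1, s2 in zip(scales, scales[1:]))

    def test_vigilance_truth_block3_is_40_percent(self):
        sess = simulate_session(
            vigilance=True, fs=250.0, seed=3, block_minutes=0.2,
            spec=default_coupling_spec(n_channels=4),
        )
        assert sess.truth.block_scale[2] == pytest.approx(0.4 * sess.truth.block_scale[0])

    def test_events_fit_at_least_400_epochs_per_study_block(self):
        # default spacing is one event per 3 s: 400 per 20-min block
        assert (20 * 60) // 3 == 400

    def test_bad_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            simulate_session(fs=0.0, spec=default_coupling_spec(n_channels=4))

    def test_seed_determinism(self):
        spec = default_coupling_spec(n_channels=4)
        kw = dict(fs=250.0, block_minutes=0.1, spec=spec)
        a = simulate_session(seed=5, **kw)
        b = simulate_session(seed=5, **kw)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.events, b.events)


class TestSimulateBehavior:
    def test_vigilance_rt_increases_noiseless(self):
        beh = simulate_behavior("vigilance", n_bins=20, seed=0, rt_noise=0.0, acc_noise=0.0)
        assert np.all(np.diff(beh.reaction_time) > 0)
        assert np.all(np.diff(beh.accuracy) < 0)

    def test_enhancement_rt_decreases_noiseless(self):
        beh = simulate_behavior("enhancement", n_bins=20, seed=0, rt_noise=0.0)
        assert np.all(np.diff(beh.reaction_time) < 0)

    def test_twenty_bins_span_60_minutes_at_3min_spacing(self):
        beh = simulate_behavior("vigilance", n_bins=20, seed=1, session_minutes=60.0)
        assert np.allclose(np.diff(beh.bin_times), 3.0)

    def test_fractions_bounded(self):
        beh = simulate_behavior("vigilance", n_bins=20, seed=2)
        for v in (beh.accuracy, beh.omission_rate, beh.commission_rate):
            assert np.all((v >= 0) & (v <= 1))
        assert np.all(beh.reaction_time > 0)
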