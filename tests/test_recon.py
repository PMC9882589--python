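"""ADMM subproblem solvers, stopping statistic, and the joint solver."""

import numpy as np
import pytest

from jkte import (
    AcquisitionConfig,
    ImageSeries,
    PhaseMap,
    ReconConfig,
    T2Map,
    decay_signal,
    encode,
    joint_reconstruct,
    make_vial_phantom,
    mrc,
    roi_stats,
    simulate_acquisition,
)
from jkte.forward import fft2c
from jkte.recon import (
    ADMMState,
    fit_t2_wls,
    update_f_0,
    update_f_i,
    update_multipliers,
    update_v,
)

TE3 = np.array([10.0, 30.0, 60.0])


def _truth_state(n=16, t2_val=40.0, seed=0):
    """Consistent noiseless ground-truth state on an n x n grid."""
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(1.0, 2.0, size=(n, n))
    t2 = np.full((n, n), t2_val)
    f = decay_signal(f0, t2, TE3)
    A = PhaseMap(data=np.ones((3, n, n), dtype=complex))
    g = encode(f, A, np.ones(n, dtype=bool))
    zeros = np.zeros_like(f.data)
    state = ADMMState(
        f=ImageSeries(data=f.data.copy(), te=TE3),
        t2=T2Map(data=t2),
        v=ImageSeries(data=f.data.copy(), te=TE3),
        y=zeros.copy(),
        z=zeros.copy(),
    )
    return state, g, A, f


def _echo_objective(x, state, g, A, i, rho):
    """Independent evaluation of the echo-i quadratic objective."""
    te = g.te
    d = state.f.data[0] * np.exp(-(te[i] - te[0]) / state.t2.data)
    resid = g.mask.astype(float)[:, None] * fft2c(A.data[i] * x) - g.data[i]
    J = 0.5 * np.sum(np.abs(resid) ** 2)
    J += np.sum(state.y[i] * (x - d)) + 0.5 * rho * np.sum((x - d) ** 2)
    J += np.sum(state.z[i] * (state.v.data[i] - x))
    J += 0.5 * rho * np.sum((state.v.data[i] - x) ** 2)
    return J


def _first_echo_objective(x, state, g, A, rho):
    te = g.te
    resid = g.mask.astype(float)[:, None] * fft2c(A.data[0] * x) - g.data[0]
    J = 0.5 * np.sum(np.abs(resid) ** 2)
    for i in range(1, g.n_echo):
        e = np.exp(-(te[i] - te[0]) / state.t2.data)
        r = state.f.data[i] - x * e
        J += np.sum(state.y[i] * r) + 0.5 * rho * np.sum(r**2)
    J += np.sum(state.z[0] * (state.v.data[0] - x))
    J += 0.5 * rho * np.sum((state.v.data[0] - x) ** 2)
    return J


class TestImageUpdates:
    def test_truth_is_fixed_point_of_echo_update(self):
        state, g, A, f = _truth_state()
        cfg = ReconConfig(denoiser="identity")
        for i in (1, 2):
            out = update_f_i(state, g, A, i, cfg)
            rel = np.max(np.abs(out - f.data[i])) / f.data[i].max()
            assert rel <= 1e-8

    def test_truth_is_fixed_point_of_first_echo_update(self):
        state, g, A, f = _truth_state()
        out = update_f_0(state, g, A, ReconConfig(denoiser="identity"))
        assert np.max(np.abs(out - f.data[0])) / f.data[0].max() <= 1e-8

    def test_large_rho_pulls_echo_update_to_auxiliary_target(self):
        state, g, A, f = _truth_state()
        target = state.v.data[1] * 1.3
        state.v.data[1] = target
        out = update_f_i(state, g, A, 1, ReconConfig(rho=1e8))
        # with dominant penalty the update averages the decay prediction d
        # and the target v; both pulls have weight rho
        d = state.f.data[0] * np.exp(-(TE3[1] - TE3[0]) / state.t2.data)
        assert np.allclose(out, 0.5 * (target + d), rtol=1e-6)

    @pytest.mark.parametrize("which", ["echo_i", "echo_0"])
    def test_minimality_probe_8x8(self, which):
        state, g, A, f = _truth_state(n=8, seed=3)
        rng = np.random.default_rng(4)
        # perturb the state off the fixed point so the subproblem is generic
        state.y += rng.normal(scale=0.02, size=state.y.shape)
        state.z += rng.normal(scale=0.02, size=state.z.shape)
        state.v = ImageSeries(
            data=np.clip(state.v.data + rng.normal(scale=0.02, size=state.v.data.shape), 0, None),
            te=TE3,
        )
        cfg = ReconConfig(rho=0.5)
        if which == "echo_i":
            out = update_f_i(state, g, A, 1, cfg)
            J0 = _echo_objective(out, state, g, A, 1, cfg.rho)
            Jp = [
                _echo_objective(out + rng.normal(scale=s, size=out.shape), state, g, A, 1, cfg.rho)
                for s in np.geomspace(1e-4, 1e-1, 1000)
            ]
        else:
            out = update_f_0(state, g, A, cfg)
            J0 = _first_echo_objective(out, state, g, A, cfg.rho)
            Jp = [
                _first_echo_objective(out + rng.normal(scale=s, size=out.shape), state, g, A, cfg.rho)
                for s in np.geomspace(1e-4, 1e-1, 1000)
            ]
        assert J0 <= min(Jp) + 1e-12 * abs(J0)

    def test_single_echo_first_update_matches_decay_free_form(self):
        # with no later echoes the first-echo subproblem loses all decay
        # terms and must match the plain quadratic solve
        rng = np.random.default_rng(5)
        n = 16
        f0 = rng.uniform(1.0, 2.0, size=(n, n))
        te1 = np.array([10.0])
        A = PhaseMap(data=np.ones((1, n, n), dtype=complex))
        f = ImageSeries(data=f0[None], te=te1)
        g = encode(f, A, np.ones(n, dtype=bool))
        zeros = np.zeros((1, n, n))
        state = ADMMState(
            f=ImageSeries(data=f0[None].copy(), te=te1),
            t2=T2Map(data=np.full((n, n), 50.0)),
            v=ImageSeries(data=f0[None] * 1.1, te=te1),
            y=zeros.copy(),
            z=zeros.copy(),
        )
        cfg = ReconConfig(rho=0.5)
        out = update_f_0(state, g, A, cfg)
        # decay-free closed form: (E^H E + rho) f = E^H g + z0 + rho v0
        expected = (f0 + 0.5 * 1.1 * f0) / 1.5
        assert np.allclose(out, expected, atol=1e-10)


class TestAuxiliaryUpdates:
    def test_identity_denoiser_returns_input(self):
        state, g, A, f = _truth_state()
        v = update_v(state, sigma=3.0, cfg=ReconConfig(denoiser="identity"))
        assert np.array_equal(v.data, state.f.data)

    def test_pnp_shift_moves_denoiser_input(self):
        state, g, A, f = _truth_state()
        state.z += 0.3
        cfg = ReconConfig(denoiser="identity", pnp_shift=True, rho=0.5)
        v = update_v(state, sigma=0.0, cfg=cfg)
        assert np.allclose(v.data, state.f.data + 0.3 / 0.5)

    def test_zero_residuals_leave_multipliers_unchanged(self):
        state, g, A, f = _truth_state()
        y, z = update_multipliers(state, ReconConfig(rho=0.5))
        assert np.allclose(y, 0.0, atol=1e-12)
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_multiplier_increment_is_rho_times_residual(self):
        state, g, A, f = _truth_state()
        state.v = ImageSeries(data=state.f.data + 1.0, te=state.f.te)
        y1, z1 = update_multipliers(state, ReconConfig(rho=0.5))
        assert np.allclose(z1, 0.5, atol=1e-12)
        state.y, state.z = y1, z1
        y2, z2 = update_multipliers(state, ReconConfig(rho=0.5))
        assert np.allclose(z2, 1.0, atol=1e-12)  # constant residual adds up


class TestMRC:
    def test_identical_series_give_zero(self):
        f = ImageSeries(data=np.ones((2, 8, 8)), te=np.array([1.0, 2.0]))
        assert mrc(f, f) == 0.0

    def test_uniform_one_percent_change(self):
        old = ImageSeries(data=np.full((2, 8, 8), 100.0), te=np.array([1.0, 2.0]))
        new = ImageSeries(data=np.full((2, 8, 8), 101.0), te=np.array([1.0, 2.0]))
        assert mrc(new, old) == pytest.approx(0.01, rel=1e-2)

    def test_matches_naive_loop_recomputation(self):
        rng = np.random.default_rng(8)
        old = ImageSeries(data=rng.random((3, 6, 6)) + 0.1, te=TE3)
        new = ImageSeries(data=rng.random((3, 6, 6)) + 0.1, te=TE3)
        floor = 1e-3 * old.data.max()
        acc = 0.0
        for i in range(3):
            for a in range(6):
                for b in range(6):
                    acc += abs(new.data[i, a, b] - old.data[i, a, b]) / (
                        old.data[i, a, b] + floor
                    )
        assert mrc(new, old) == pytest.approx(acc / (3 * 36), rel=1e-12)


class TestJointReconstruct:
    def test_max_iter_zero_returns_initialization(self, noisy_kspace):
        f, t2, log = joint_reconstruct(noisy_kspace, ReconConfig(max_iter=0))
        init = np.abs(
            np.fft.fftshift(
                np.fft.ifft2(
                    np.fft.ifftshift(noisy_kspace.data, axes=(-2, -1)), norm="ortho"
                ),
                axes=(-2, -1),
            )
        )
        assert np.allclose(f.data, init)
        assert log["mrc"] == []

    def test_noiseless_recovery_images_and_t2(self):
        ph = make_vial_phantom((64, 64), vial_radius=5.5)
        g = simulate_acquisition(ph, AcquisitionConfig(noise_sd=0.0, seed=0))
        f, t2, log = joint_reconstruct(g, ReconConfig())
        truth = decay_signal(ph.pd, ph.t2_truth, np.asarray(g.te))
        sup = ph.support
        assert np.max(np.abs(f.data[:, sup] - truth.data[:, sup])) / 100.0 <= 0.01
        rep = roi_stats(t2, ph.roi_masks, truth=T2Map(data=ph.t2_truth))
        for entry in rep.stats.values():
            assert entry["rel_error"] <= 0.02

    def test_determinism_bit_identical(self):
        ph = make_vial_phantom((64, 64), vial_radius=5.5)
        g = simulate_acquisition(ph, AcquisitionConfig(noise_sd=2.0, seed=3))
        cfg = ReconConfig(max_iter=3, check_from_iter=1)
        f1, t21, log1 = joint_reconstruct(g, cfg)
        f2, t22, log2 = joint_reconstruct(g, cfg)
        assert np.array_equal(f1.data, f2.data)
        assert np.array_equal(t21.data, t22.data)
        assert log1["mrc"] == log2["mrc"]

    def test_full_admm_sweep_fixes_ground_truth(self):
        """Noiseless data + identity denoiser: truth is a one-sweep fixed point."""
        ph = make_vial_phantom((64, 64), vial_radius=5.5)
        te = np.asarray(AcquisitionConfig().te)
        g = simulate_acquisition(ph, AcquisitionConfig(noise_sd=0.0, seed=0))
        truth = decay_signal(ph.pd, ph.t2_truth, te)
        A = PhaseMap(data=np.ones_like(g.data))
        zeros = np.zeros_like(truth.data)
        state = ADMMState(
            f=ImageSeries(data=truth.data.copy(), te=te),
            t2=T2Map(data=ph.t2_truth.copy()),
            v=ImageSeries(data=truth.data.copy(), te=te),
            y=zeros.copy(),
            z=zeros.copy(),
        )
        cfg = ReconConfig(denoiser="identity")
        scale = truth.data.max()
        new_f = state.f.data.copy()
        for i in range(1, g.n_echo):
            new_f[i] = update_f_i(state, g, A, i, cfg)
        state.f = ImageSeries(data=new_f, te=te)
        new_f[0] = update_f_0(state, g, A, cfg)
        state.f = ImageSeries(data=new_f, te=te)
        assert np.max(np.abs(state.f.data - truth.data)) / scale <= 1e-8
        state.t2 = fit_t2_wls(state.f, 0.0, cfg.t2_clamp)
        sup = ph.support
        assert np.max(np.abs(state.t2.data[sup] - ph.t2_truth[sup])) <= 1e-6 * 853
        state.v = update_v(state, 0.0, cfg)
        assert np.max(np.abs(state.v.data - truth.data)) / scale <= 1e-8
        y, z = update_multipliers(state, cfg)
        assert np.max(np.abs(y)) / scale <= 1e-8
        assert np.max(np.abs(z)) / scale <= 1e-8
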