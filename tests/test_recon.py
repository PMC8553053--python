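"""Reconstruction: IFFT baseline and the constrained-smoothness solver.

The constrained solver is checked against an independent dense oracle: the
same convex program assembled as an explicit least-squares system (explicit
difference matrices, explicit DFT matrix for the weighted path) and solved
with ``numpy.linalg.lstsq``.
"""

import numpy as np
import pytest

import ecamri.scanner as scanner_mod
from ecamri.phantom import build_phantom
from ecamri.recon import (EcaConfig, ImageSeries, build_normal_operator,
                          eca_reconstruct, ifft_reconstruct, measured_kspace,
                          smoothness_penalty)
from ecamri.scanner import KSampleSeries, _fft_volume, _ifft_volume, acquire
from ecamri.trajectory import Partition, partition_trajectory, unwrap_trajectory

from conftest import small_config


# ---------------------------------------------------------------- oracle ---

def random_instance(seed, grid_shape=(4, 4, 2), T=16, frac=0.3, dt=0.25):
    """Random measured pattern and data as a KSampleSeries + Partition."""
    rng = np.random.default_rng(seed)
    V = int(np.prod(grid_shape))
    mask = rng.random((V, T)) < frac
    ks, ts = np.nonzero(mask)
    order = np.lexsort((ks, ts))  # time-major acquisition order
    ks, ts = ks[order], ts[order]
    times = np.empty(ks.size)
    for t in range(T):
        sel = ts == t
        m = int(sel.sum())
        times[sel] = t * dt + (np.arange(m) + 0.5) * dt / max(m, 1)
    vals = rng.standard_normal(ks.size) + 1j * rng.standard_normal(ks.size)
    series = KSampleSeries(indices=np.stack(np.unravel_index(ks, grid_shape), axis=1),
                           times=times, values=vals, grid_shape=grid_shape,
                           sweep_time=T * dt)
    partition = Partition(dt=dt, n_intervals=T, interval_of_sample=ts)
    return series, partition


def dense_solve(series, partition, cfg):
    """Independent dense solution of the constrained smoothness program.

    Assembles the penalty as explicit matrices over the full (V, T) k-space
    variable vector, substitutes the measured entries, and solves the
    eliminated least-squares problem directly.  Returns the full (V, T)
    k-space solution.
    """
    grid_shape = tuple(series.grid_shape)
    mask, data = measured_kspace(series, partition)
    V, T = mask.shape
    D_T = np.diff(np.eye(T), n=cfg.diff_order, axis=0)
    if cfg.weights is None or np.ptp(cfg.weights) == 0:
        w0 = 1.0 if cfg.weights is None else float(cfg.weights.reshape(-1)[0])
        pen = np.sqrt(w0) * np.kron(np.eye(V), D_T)
        mean_w = w0 if cfg.weights is not None else 1.0
    else:
        w = cfg.weights.reshape(-1)
        finv = np.stack([_ifft_volume(e.reshape(grid_shape)).reshape(-1)
                         for e in np.eye(V)], axis=1)  # image <- kspace
        pen = (np.diag(np.repeat(np.sqrt(w), T - cfg.diff_order))
               @ np.kron(np.eye(V), D_T) @ np.kron(finv, np.eye(T)))
        mean_w = float(w.mean())
    lam = cfg.lam_abs(mean_w)

    flat_mask = mask.reshape(-1)
    free = ~flat_mask
    fixed_vec = np.where(flat_mask, data.reshape(-1), 0.0)
    n_free = int(free.sum())
    rows = [pen[:, free]]
    rhs = [-pen @ fixed_vec]
    if lam > 0:
        rows.append(np.sqrt(lam) * np.eye(n_free))
        rhs.append(np.zeros(n_free, dtype=complex))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    z, *_ = np.linalg.lstsq(A, b, rcond=None)
    full = fixed_vec.copy()
    full[free] = z
    return full.reshape(V, T)


def impl_kspace(series_out: ImageSeries) -> np.ndarray:
    """(V, T) k-space of a reconstructed series."""
    k = series_out.kspace()
    return np.moveaxis(k.reshape(k.shape[0], -1), 0, -1)


# ----------------------------------------------------------------- tests ---

class TestIfftReconstruct:
    def test_static_noiseless_exact(self, static_phantom):
        traj = unwrap_trajectory(static_phantom.grid_shape, 3.5, 4, n_sweeps=3)
        out = ifft_reconstruct(acquire(static_phantom, traj))
        assert out.n_times == 3
        for vol in out.data:
            np.testing.assert_allclose(vol.real, static_phantom.background, atol=1e-12)
            np.testing.assert_allclose(vol.imag, 0.0, atol=1e-12)

    def test_volume_count_and_midpoints(self, small_phantom):
        traj = unwrap_trajectory(small_phantom.grid_shape, 3.5, 4, n_sweeps=16)
        out = ifft_reconstruct(acquire(small_phantom, traj))
        assert out.n_times == 16
        np.testing.assert_allclose(out.t_mid, 1.75 + 3.5 * np.arange(16))

    def test_entries_match_acquisition_times(self, static_phantom, monkeypatch):
        # on a linear-in-time phantom every reconstructed k-entry equals the
        # phantom's Fourier coefficient at that entry's acquisition time
        base = static_phantom.background

        def ramp(ph, t):
            t = np.atleast_1d(np.asarray(t, dtype=float))
            out = base[None] * (1.0 + 0.05 * t[:, None, None, None])
            return out[0] if np.ndim(t) == 0 else out

        monkeypatch.setattr(scanner_mod, "evaluate_phantom", ramp)
        traj = unwrap_trajectory(static_phantom.grid_shape, 2.0, 2, n_sweeps=2)
        samples = acquire(static_phantom, traj, update_interval=0.01)
        out = ifft_reconstruct(samples)
        khat_base = _fft_volume(base).reshape(-1)
        flat = traj.flat_indices()
        V = traj.n_voxels
        for s in range(2):
            k_rec = _fft_volume(out.data[s]).reshape(-1)
            sel = slice(s * V, (s + 1) * V)
            np.testing.assert_allclose(
                k_rec[flat[sel]],
                khat_base[flat[sel]] * (1.0 + 0.05 * traj.times[sel]), atol=1e-10)


class TestSmoothnessPenalty:
    def _series(self, vals):
        data = np.asarray(vals, dtype=float).reshape(-1, 1, 1, 1)
        return ImageSeries(data=data, dt=1.0, t_mid=np.arange(len(vals)) + 0.5)

    def test_constant_series_is_zero(self):
        cfg = EcaConfig(lam=0.0, diff_order=1)
        assert smoothness_penalty(self._series([3.0, 3.0, 3.0]), cfg) == 0.0

    def test_single_voxel_first_difference_example(self):
        cfg = EcaConfig(lam=0.0, diff_order=1)
        assert smoothness_penalty(self._series([0.0, 1.0, 0.0]), cfg) == pytest.approx(2.0)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 2, 2, 1))
        w = rng.random((2, 2, 1))
        p1 = smoothness_penalty(data, EcaConfig(lam=0.0, weights=w))
        p2 = smoothness_penalty(data, EcaConfig(lam=0.0, weights=2 * w))
        assert p2 == pytest.approx(2 * p1, rel=1e-12)


class TestNormalOperator:
    @pytest.mark.parametrize("weighted", [False, True], ids=["uniform", "weighted"])
    def test_selfadjoint_psd_and_tikhonov_bound(self, weighted):
        rng = np.random.default_rng(5)
        grid = (4, 2, 2)
        V, T = 16, 8
        mask = rng.random((V, T)) < 0.4
        w = rng.random(grid) + 0.5 if weighted else None
        lam_rel = 1e-2
        cfg = EcaConfig(lam=lam_rel, weights=w)
        op = build_normal_operator(mask, cfg, grid)
        n = int((~mask).sum())
        y = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        z = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        ay, az = op(y), op(z)
        assert abs(np.vdot(ay, z) - np.vdot(y, az)) < 1e-10 * np.linalg.norm(y) * np.linalg.norm(z)
        quad = float(np.real(np.vdot(op(y), y)))
        assert quad >= 0.0
        lam_abs = cfg.lam_abs(1.0 if w is None else float(w.mean()))
        assert quad >= lam_abs * float(np.vdot(y, y).real) * (1 - 1e-12)


class TestEcaReconstruct:
    def test_fully_sampled_equals_ifft(self, small_phantom):
        traj = unwrap_trajectory(small_phantom.grid_shape, 3.5, 4, n_sweeps=3)
        samples = acquire(small_phantom, traj)
        part = partition_trajectory(traj, 3.5)
        eca = eca_reconstruct(samples, part, EcaConfig())
        ifft = ifft_reconstruct(samples)
        np.testing.assert_allclose(eca.data, ifft.data, atol=1e-12)

    def test_static_noiseless_exact_at_all_times(self, static_phantom):
        traj = unwrap_trajectory(static_phantom.grid_shape, 3.5, 4, n_sweeps=4)
        samples = acquire(static_phantom, traj)
        part = partition_trajectory(traj, 0.25)
        out = eca_reconstruct(samples, part, EcaConfig(lam=0.0, tol=1e-12, maxiter=5000))
        assert out.solver_info.converged
        for vol in out.data:
            np.testing.assert_allclose(vol.real, static_phantom.background, atol=1e-8)
            np.testing.assert_allclose(vol.imag, 0.0, atol=1e-8)

    def test_piecewise_linear_closed_form(self):
        # uniform weights, first differences, lam = 0: each k-frequency is
        # linearly interpolated between its measured values with constant
        # extension outside the measured range
        series, part = random_instance(seed=3, grid_shape=(4, 2, 2), T=12, frac=0.35)
        cfg = EcaConfig(lam=0.0, diff_order=1, tol=1e-13, maxiter=5000)
        mask, data = measured_kspace(series, part)
        # ensure every frequency is constrained somewhere
        assert mask.any(axis=1).all()
        out = impl_kspace(eca_reconstruct(series, part, cfg))
        tgrid = np.arange(part.n_intervals, dtype=float)
        for k in range(mask.shape[0]):
            tm = tgrid[mask[k]]
            vm = data[k, mask[k]]
            expect = (np.interp(tgrid, tm, vm.real)
                      + 1j * np.interp(tgrid, tm, vm.imag))
            np.testing.assert_allclose(out[k], expect, atol=1e-9)

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_dense_oracle(self, order):
        for seed in range(6):
            series, part = random_instance(seed, grid_shape=(4, 4, 2), T=16)
            cfg = EcaConfig(lam=1e-3, diff_order=order, tol=1e-13, maxiter=20000)
            ours = impl_kspace(eca_reconstruct(series, part, cfg))
            oracle = dense_solve(series, part, cfg)
            err = np.linalg.norm(ours - oracle) / np.linalg.norm(oracle)
            assert err < 1e-8

    def test_weighted_path_matches_dense_oracle(self):
        rng = np.random.default_rng(17)
        grid = (4, 2, 2)
        series, part = random_instance(seed=17, grid_shape=grid, T=10)
        w = rng.random(grid) + 0.25
        cfg = EcaConfig(lam=1e-3, weights=w, tol=1e-13, maxiter=20000)
        ours = impl_kspace(eca_reconstruct(series, part, cfg))
        oracle = dense_solve(series, part, cfg)
        err = np.linalg.norm(ours - oracle) / np.linalg.norm(oracle)
        assert err < 1e-8

    def test_data_fidelity_hard_constraint(self):
        series, part = random_instance(seed=9)
        out = eca_reconstruct(series, part, EcaConfig())
        mask, data = measured_kspace(series, part)
        khat = impl_kspace(out)
        np.testing.assert_allclose(khat[mask], data[mask], atol=1e-12)

    def test_unique_solution_independent_of_start(self):
        series, part = random_instance(seed=21)
        cfg = EcaConfig(lam=1e-4, tol=1e-12, maxiter=20000)
        a = eca_reconstruct(series, part, cfg)
        rng = np.random.default_rng(0)
        mask, _ = measured_kspace(series, part)
        n = int((~mask).sum())
        x0 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        b = eca_reconstruct(series, part, cfg, x0=x0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_nonconvergence_is_flagged(self):
        series, part = random_instance(seed=2)
        out = eca_reconstruct(series, part, EcaConfig(maxiter=1, tol=1e-14))
        assert not out.solver_info.converged
        assert out.solver_info.iterations == 1

    def test_endpoint_undershoot_and_precontrast_remedy(self, static_phantom):
        # zero-fill anchoring pulls the sparsely constrained first/last time
        # points toward zero; the pull grows with lam and a pre-contrast
        # anchor removes it
        traj = unwrap_trajectory(static_phantom.grid_shape, 3.5, 4, n_sweeps=4)
        samples = acquire(static_phantom, traj)
        part = partition_trajectory(traj, 0.25)
        ref = float(np.abs(static_phantom.background).mean())

        def end_deficit(cfg):
            out = eca_reconstruct(samples, part, cfg)
            ends = np.abs(out.data[[0, -1]]).mean()
            return ref - float(ends)

        d_big = end_deficit(EcaConfig(lam=0.05, maxiter=4000))
        d_small = end_deficit(EcaConfig(lam=1e-4, maxiter=4000))
        d_pre = end_deficit(EcaConfig(lam=0.05, maxiter=4000, init="precontrast",
                                      init_volume=static_phantom.background))
        assert d_big > d_small > 0.0
        assert abs(d_pre) < 0.05 * d_big

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EcaConfig(lam=-1.0)
        with pytest.raises(ValueError):
            EcaConfig(diff_order=3)
        with pytest.raises(ValueError):
            EcaConfig(init="precontrast")
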