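"""Fiber mechanics: bending forces, growth law, diffusion, persistence length."""

import numpy as np
import pytest

import filasim as fs
from filasim.params import MechParams
from filasim.world import World

from conftest import free_world, free_config

KBT = fs.KBT_ROOM


def wlc_energy(vertices, K, l0):
    """Independent discrete worm-like-chain energy (test oracle)."""
    seg = np.diff(np.asarray(vertices, float), axis=0)
    phi = np.arctan2(seg[:, 1], seg[:, 0])
    dphi = np.diff(phi)
    dphi = np.arctan2(np.sin(dphi), np.cos(dphi))
    return K / (2 * l0) * np.sum(dphi**2)


class TestBendingForces:
    def test_straight_fiber_zero_force(self):
        v = np.column_stack([np.arange(5) * 0.2, np.zeros(5)])
        f = fs.bending_forces(v, K=KBT * 15)
        assert np.allclose(f, 0.0, atol=1e-14)

    def test_fewer_than_three_vertices(self):
        f = fs.bending_forces(np.array([[0.0, 0.0], [0.2, 0.0]]), K=1.0)
        assert np.all(f == 0.0)

    @pytest.mark.parametrize("vertices", [
        # 90-degree elbow, l = 0.2
        np.array([[0.0, 0.0], [0.2, 0.0], [0.2, 0.2]]),
        # random wiggly fiber
        np.cumsum(np.random.default_rng(7).normal(0, 0.15, (8, 2)), axis=0),
    ])
    def test_matches_finite_difference_gradient(self, vertices):
        K = KBT * 15
        f = fs.bending_forces(vertices, K, segment_length=0.2)
        eps = 1e-6
        num = np.zeros_like(vertices, dtype=float)
        for i in range(len(vertices)):
            for j in range(2):
                vp = vertices.astype(float).copy()
                vm = vp.copy()
                vp[i, j] += eps
                vm[i, j] -= eps
                num[i, j] = -(wlc_energy(vp, K, 0.2)
                              - wlc_energy(vm, K, 0.2)) / (2 * eps)
        assert np.abs(f - num).max() < 1e-4

    def test_force_and_torque_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            v = np.cumsum(rng.normal(0, 0.2, (10, 2)), axis=0)
            f = fs.bending_forces(v, K=KBT * 15, segment_length=0.2)
            assert np.abs(f.sum(axis=0)).max() < 1e-10
            torque = np.sum(v[:, 0] * f[:, 1] - v[:, 1] * f[:, 0])
            assert abs(torque) < 1e-10


class TestTipGrowth:
    params = MechParams(v0=0.033, fs=0.8)

    def test_unloaded_speed(self):
        v = fs.tip_growth_speed(np.zeros(2), np.array([1.0, 0.0]), self.params)
        assert v == pytest.approx(0.033)

    def test_antagonistic_force_reduces_exponentially(self):
        v = fs.tip_growth_speed(np.array([-0.8, 0.0]), np.array([1.0, 0.0]),
                                self.params)
        assert v == pytest.approx(0.033 * np.exp(-1.0), rel=1e-12)

    def test_aiding_force_does_not_accelerate(self):
        v = fs.tip_growth_speed(np.array([2.0, 0.0]), np.array([1.0, 0.0]),
                                self.params)
        assert v == pytest.approx(0.033)


class TestIntegration:
    def test_athermal_straight_fiber_only_grows(self):
        w = free_world([np.array([[0.0, 0.0], [0.2, 0.0], [0.4, 0.0]])],
                       growing=True, kBT=0.0, duration=50.0)
        w.run(50.0)
        fib = w.fibers[0]
        assert fib.length == pytest.approx(0.4 + 0.033 * 50.0, rel=1e-9)
        # stayed perfectly straight
        assert np.allclose(fib.vertices[:, 1], 0.0, atol=1e-12)

    def test_com_diffusion_matches_einstein_relation(self):
        # >= 500 independent rigid 2-vertex fibers, far apart
        n = 500
        fibs = [np.array([[10.0 * i, 0.0], [10.0 * i, 0.2]]) for i in range(n)]
        w = free_world(fibs, dt=1e-3, seed=21)
        w.rng = np.random.default_rng(21)
        X0 = w.X.copy()
        T = 0.5
        w.run(T)
        c0 = X0.reshape(n, 2, 2).mean(axis=1)
        c1 = w.X.reshape(n, 2, 2).mean(axis=1)
        msd = ((c1 - c0) ** 2).sum(axis=1)
        sum_gamma = 2 * w.gamma          # two vertices
        pred = 4 * KBT * T / sum_gamma
        se = msd.std() / np.sqrt(n)
        assert abs(msd.mean() - pred) < 3 * se

    def test_bitwise_deterministic_trajectories(self):
        cfg = fs.bar_config(length=4.0, budget=40, duration=3.0, nucleators=6)
        runs = []
        for _ in range(2):
            w = World(cfg, seed=5)
            w.run()
            runs.append((w.X.copy(), w.nv.copy(), w.n_fibers))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_unstable_timestep_rejected(self):
        cfg = free_config(dt=0.5, steric=True)
        cfg.steric.enabled = True
        with pytest.raises(ValueError, match="dt"):
            World.from_fibers([np.array([[0, 0], [0.2, 0]])], config=cfg)

    def test_kernel_matches_reference_step(self):
        # same forces/solve in the compiled and numpy paths (short horizon;
        # contact dynamics amplify rounding differences exponentially)
        cfg = fs.bar_config(length=4.0, budget=30, duration=1.0,
                            nucleators=6, kBT=0.0)
        wa = World(cfg, seed=3)
        wa.use_kernel = False
        wb = World(cfg, seed=3)
        wb.use_kernel = True
        wa.run(0.1)
        wb.run(0.1)
        assert wa.X.shape == wb.X.shape
        assert np.abs(wa.X - wb.X).max() < 1e-6


class TestPersistenceLength:
    def test_straight_fibers_flagged_infinite(self):
        fibs = [np.column_stack([np.arange(12) * 0.2, np.full(12, i)])
                for i in range(60)]
        est, se = fs.estimate_persistence_length(fibs)
        assert np.isinf(est)

    def test_too_few_fibers_rejected(self):
        with pytest.raises(ValueError):
            fs.estimate_persistence_length(
                [np.column_stack([np.arange(12) * 0.2, np.zeros(12)])] * 10)

    def test_recovers_lp_from_independent_wlc_sampler(self):
        # oracle sampler, written here, independent of the package's
        rng = np.random.default_rng(5)
        Lp, l0 = 15.0, 0.2
        fibs = []
        for _ in range(300):
            dphi = rng.normal(0, np.sqrt(l0 / Lp), 34)
            phi = np.concatenate([[rng.uniform(0, 2 * np.pi)]]) + \
                np.concatenate([[0.0], np.cumsum(dphi)])
            steps = l0 * np.column_stack([np.cos(phi), np.sin(phi)])
            fibs.append(np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]))
        est, se = fs.estimate_persistence_length(fibs, n_bootstrap=50)
        assert abs(est - Lp) / Lp < 0.15

    def test_recovers_lp_from_equilibrated_dynamics(self):
        # soft (ADF/cofilin-like) fibers, Lp = 2 µm, thermal dynamics
        rng = np.random.default_rng(9)
        Lp = 2.0
        fibs = [fs.sample_wlc_fiber(10, Lp, rng, origin=(40.0 * i, 0.0))
                for i in range(250)]
        w = free_world(fibs, Lp=Lp, seed=17)
        w.rng = np.random.default_rng(17)
        w.run(10.0)
        sample = [w.fiber_vertices(i) for i in range(w.n_fibers)]
        est, se = fs.estimate_persistence_length(sample, n_bootstrap=50)
        assert abs(est - Lp) / Lp < 0.20
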