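"""Time stepper: fixed point, diffusion accuracy, budgets, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest

from cawave import scenarios
from cawave.frac_diffusion import riesz_matrix
from cawave.model_core import GridSpec
from cawave.reactions import equilibrium_bound, leak_rate, pump_rate
from cawave.simulator import (build_operators, linescan, make_initial_state,
                              run, step)
from cawave.wave_analysis import amplitude


def mini_scenario(**kw):
    return scenarios.mini_fixture(**kw)


class TestInitialState:
    def test_resting_fields(self, tiny_params):
        st = make_initial_state(tiny_params)
        assert (st.C == tiny_params.C0).all()
        for k, spec in enumerate(tiny_params.buffers):
            b = st.bound[:, :, k]
            assert (b == equilibrium_bound(tiny_params.C0, spec)).all()
            assert 0 < b[0, 0] < spec.B_total

    def test_pump_leak_balance_at_every_node(self, tiny_params):
        st = make_initial_state(tiny_params)
        net = leak_rate(tiny_params.pump, tiny_params.C0) - pump_rate(
            st.C, tiny_params.pump)
        assert np.abs(net).max() < 1e-15

    def test_forced_crus_open(self, tiny_params):
        st = make_initial_state(tiny_params, forced=[(2.0, 2.0)])
        assert (st.lattice.state == 1).sum() == 1


class TestFixedPoint:
    def test_resting_run_drift(self, tiny_params):
        """100 ms with firing suppressed: drift below 1e-6 uM anywhere."""
        p = replace(tiny_params, t_end=100.0)
        ops = build_operators(p)
        st = make_initial_state(p)
        rng = np.random.default_rng(0)
        for _ in range(int(round(100.0 / p.dt))):
            step(st, p, ops, rng)
        assert np.abs(st.C - p.C0).max() < 1e-6
        assert len(st.lattice.firing_log()) == 0


class TestDiffusionAccuracy:
    def test_fickian_gaussian_spread(self):
        """beta=2, diffusion only: anisotropic Gaussian evolution matches
        the heat kernel to <2% of the peak and variance grows as 2*D*t."""
        g = GridSpec(length_x=12.8, length_y=12.8)
        p = replace(mini_scenario(stochastic=False).build_parameters(), grid=g)
        p = replace(p, diffusion=replace(p.diffusion, beta=2.0))
        ops = build_operators(p, reactions=False)
        x = (np.arange(g.nx) - (g.nx - 1) / 2) * g.dx
        y = (np.arange(g.ny) - (g.ny - 1) / 2) * g.dy
        s0 = 0.6
        C = np.exp(-(x[:, None] ** 2 + y[None, :] ** 2) / (2 * s0**2))
        st = make_initial_state(p)
        st.C = C.copy()
        st._tmp = np.empty_like(st.C)
        st.bound = np.empty((g.nx, g.ny, 0))
        rng = np.random.default_rng(0)
        t = 5.0
        mass0 = st.C.sum()
        var_x0 = (st.C * x[:, None] ** 2).sum() / mass0
        for _ in range(int(round(t / p.dt))):
            step(st, p, ops, rng)
        D = p.diffusion.Dx, p.diffusion.Dy
        sx = np.sqrt(s0**2 + 2 * D[0] * t)
        sy = np.sqrt(s0**2 + 2 * D[1] * t)
        exact = (s0**2 / (sx * sy)) * np.exp(
            -(x[:, None] ** 2 / (2 * sx**2) + y[None, :] ** 2 / (2 * sy**2)))
        assert np.abs(st.C - exact).max() / exact.max() < 0.02
        var_x = (st.C * x[:, None] ** 2).sum() / st.C.sum()
        assert var_x - var_x0 == pytest.approx(2 * D[0] * t, rel=0.02)

    def test_total_release_grid_independent(self):
        """Total calcium released per spark is sigma * T_open, at both
        dx = 0.1 and dx = 0.05 um (diffusion only, beta = 2)."""
        totals = []
        for h in (0.1, 0.05):
            g = GridSpec(length_x=4.0, length_y=4.0, dx=h, dy=h)
            sc = mini_scenario(beta=2.0, stochastic=False)
            p = replace(sc.build_parameters(), grid=g, t_end=12.0)
            ops = build_operators(p, reactions=False)
            st = make_initial_state(p, forced=sc.forced_crus)
            st.bound = np.empty((g.nx, g.ny, 0))
            rng = np.random.default_rng(0)
            for _ in range(int(round(12.0 / p.dt))):
                step(st, p, ops, rng)
            cell = g.dx * g.dy * p.cru.depth
            totals.append((st.C - p.C0).sum() * cell)
        sigma = p.cru.I_cru * 1e6 / (2 * p.cru.faraday)
        expected = sigma * p.cru.T_open
        assert totals[0] == pytest.approx(expected, rel=1e-9)
        assert totals[1] == pytest.approx(expected, rel=1e-9)

    def test_implicit_explicit_cross_check(self):
        """Full reactions, beta=2.25, smooth initial bump on a 32x32 grid:
        the production stepper agrees with a fully explicit reference at
        dt = 1e-4 ms to < 0.5% max-norm after 5 ms."""
        g = GridSpec(length_x=3.2, length_y=3.2)
        sc = mini_scenario(stochastic=False)
        p = replace(sc.build_parameters(), grid=g, t_end=5.0)
        x = (np.arange(g.nx) - (g.nx - 1) / 2) * g.dx
        C0f = p.C0 + 2.0 * np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / 0.5)
        # buffers locally equilibrated with the bump (the physical manifold)
        bound0 = np.stack([equilibrium_bound(C0f, b) for b in p.buffers])
        bound0_sim = np.moveaxis(bound0, 0, -1).copy()

        ops = build_operators(p)
        st = make_initial_state(p)
        st.C = C0f.copy()
        st.bound = bound0_sim
        rng = np.random.default_rng(0)
        for _ in range(int(round(5.0 / p.dt))):
            step(st, p, ops, rng)

        # explicit reference, first order at tiny dt
        from cawave.reactions import buffer_rate, reaction_arrays
        Lx = riesz_matrix(p.diffusion.beta, g.nx, g.dx, p.diffusion.Dx)
        Ly = riesz_matrix(p.diffusion.beta, g.ny, g.dy, p.diffusion.Dy)
        kp, km, bt = reaction_arrays(p)
        leak = leak_rate(p.pump, p.C0)
        C = C0f.copy()
        bound = bound0.copy()
        dt = 1e-4
        for _ in range(int(round(5.0 / dt))):
            rates = (kp[:, None, None] * C * (bt[:, None, None] - bound)
                     - km[:, None, None] * bound)
            dC = Lx @ C + C @ Ly.T + leak - pump_rate(C, p.pump) - rates.sum(0)
            bound += dt * rates
            C += dt * dC
        scale = np.abs(C - p.C0).max()
        assert np.abs(st.C - C).max() / scale < 0.005

    def test_dt_refinement_amplitude(self):
        """Halving dt changes the deterministic single-spark amplitude by
        less than 1%."""
        amps = []
        for dt in (0.005, 0.0025):
            sc = scenarios.single_spark(beta=2.25)
            p = replace(sc.build_parameters(), dt=dt, t_end=25.0)
            traj = run(sc, params=p, seed=0, t_end=25.0)
            amps.append(amplitude(traj))
        assert abs(amps[1] - amps[0]) / amps[0] < 0.01


class TestBudget:
    def test_single_step_calcium_budget(self, tiny_params):
        """Over one step with a forced CRU the gain of (free + bound)
        equals the source deposit minus the net pump-leak removal."""
        p = replace(tiny_params, diffusion=replace(tiny_params.diffusion, beta=2.0))
        ops = build_operators(p)
        st = make_initial_state(p, forced=[(2.0, 2.0)])
        cell = p.grid.dx * p.grid.dy * p.cru.depth
        total0 = (st.C.sum() + st.bound.sum()) * cell
        # oracle: reconstruct the post-diffusion field the reactions see
        deposit_rate = p.dt * ops.src_rate
        Cmid = st.C.copy()
        k = st.lattice.index_at((2.0, 2.0))
        i, j = st.lattice.ix[k], st.lattice.iy[k]
        Cmid[i, j] += ops.w_pre * deposit_rate
        Cmid = ops.Ex @ Cmid @ ops.EyT
        Cmid[i, j] += (1.0 - ops.w_pre) * deposit_rate
        pump_removed = (pump_rate(Cmid, p.pump) - leak_rate(p.pump, p.C0)).sum()

        rng = np.random.default_rng(0)
        step(st, p, ops, rng)
        total1 = (st.C.sum() + st.bound.sum()) * cell
        deposit = p.dt * ops.src_rate * cell
        expected = deposit - p.dt * pump_removed * cell
        assert total1 - total0 == pytest.approx(expected, rel=1e-8)


class TestRun:
    def test_zero_horizon(self, tiny_params):
        sc = mini_scenario()
        traj = run(sc, params=replace(tiny_params, t_end=0.0), seed=0)
        assert len(traj.snapshots) == 1 and traj.times[0] == 0.0

    def test_reproducible_with_seed(self):
        sc = mini_scenario()
        t1 = run(sc, seed=42)
        t2 = run(sc, seed=42)
        assert t1.firing_log.equals(t2.firing_log)
        assert np.array_equal(t1.snapshots[-1], t2.snapshots[-1])

    def test_snapshot_times_strictly_increasing(self):
        traj = run(mini_scenario(), seed=3)
        assert (np.diff(traj.times) > 0).all()

    def test_monotone_front_in_deterministic_limit(self):
        """With the firing probability saturated above a threshold, the set
        of fired CRUs grows monotonically and the front advances."""
        sc = mini_scenario()
        p = sc.build_parameters()
        p = replace(p, dt=0.005,
                    cru=replace(p.cru, P_max=200.0, K_sens=0.6, n_cru=12.0))
        traj = run(sc, params=p, seed=0)
        log = traj.firing_log
        assert len(log) > 3
        assert log["t_fire_ms"].is_monotonic_increasing
        # distance of newly fired CRUs from the origin grows with time
        d = np.hypot(log["x_um"] - 2.0, log["y_um"] - 2.0).to_numpy()
        t = log["t_fire_ms"].to_numpy()
        assert (np.diff([d[t <= tt].max() for tt in np.unique(t)]) >= 0).all()


class TestLinescan:
    def test_resting_linescan_constant(self, tiny_params):
        sc = mini_scenario(stochastic=False)
        sc = replace(sc, forced_crus=())
        traj = run(sc, params=tiny_params, seed=0, probe_rows=[2.0])
        ls = linescan(traj, "x", 2.0)
        assert np.allclose(ls.image, tiny_params.C0, atol=1e-9)

    def test_single_spark_transient_at_cru_row(self):
        sc = mini_scenario(stochastic=False)
        traj = run(sc, seed=0, probe_rows=[2.0])
        ls = linescan(traj, "x", 2.0)
        i_peak = np.unravel_index(ls.image.argmax(), ls.image.shape)[0]
        assert ls.positions[i_peak] == pytest.approx(2.0, abs=0.2)
        assert ls.image.max() > 10 * 0.1

    def test_snapshot_based_and_axis_y(self):
        traj = run(mini_scenario(stochastic=False), seed=0)
        ls = linescan(traj, "y", 2.0)
        assert ls.image.shape == (40, len(traj.times))

    def test_off_grid_coordinate_rejected(self):
        traj = run(mini_scenario(stochastic=False), seed=0)
        with pytest.raises(Exception):
            linescan(traj, "x", 2.03)
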