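"""Finite-volume solver: conservation, equilibria, convolution, time scaling."""

import numpy as np
import pytest

import gridfield as gf
from gridfield.solver import (
    N_POP,
    PopulationField,
    SolverParams,
    bernoulli,
    evolve_full,
    evolve_homogeneous,
    firing_rate_field,
    fokker_planck_step,
    steady_state_detect,
)
from gridfield.stationary import stationary_density
from conftest import B_REFERENCE, W0_REFERENCE


def _homog_field(state, sheet, sgrid, tau=1.0):
    prof = stationary_density(state, sgrid)
    prof = prof / (prof.sum() * sgrid.ds)
    vals = np.broadcast_to(
        prof[None, None, None, :], (N_POP, sheet.n_x, sheet.n_x, sgrid.n_s)
    ).copy()
    return PopulationField(values=vals, sheet=sheet, sgrid=sgrid, tau=tau, sigma=state.sigma)


class TestBernoulli:
    def test_limits_and_identity(self):
        w = np.array([-800.0, -30.0, -1.0, -1e-12, 0.0, 1e-12, 1.0, 30.0, 800.0])
        b = bernoulli(w)
        assert np.all(np.isfinite(b))
        assert b[4] == pytest.approx(1.0)
        # B(-w) = B(w) + w (detailed balance of the interface rates)
        assert np.allclose(bernoulli(-w), b + w, rtol=1e-12)
        # tails: B(w) ~ -w for w -> -inf, ~ 0 for w -> +inf
        assert b[0] == pytest.approx(800.0)
        assert b[-1] == pytest.approx(0.0, abs=1e-300)


class TestHomogeneousSolver:
    def test_discrete_equilibrium_preserved(self, phi_eps):
        """The discrete fixed point (Gaussian cell samples closing the
        discrete consistency loop) is preserved to round-off, and the
        analytic profile is its O(ds^2) neighbour."""
        sgrid = gf.SGrid(3.0, 256)
        f0, _ = gf.discrete_stationary_profile(
            phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid
        )
        run = evolve_homogeneous(
            f0, phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid,
            SolverParams(dt=0.05, t_end=5.0),
        )
        assert np.abs(run.profiles[-1] - f0).max() < 1e-10
        st = gf.solve_consistency(phi_eps, W0_REFERENCE, B_REFERENCE, 0.03)
        analytic = stationary_density(st, sgrid)
        assert np.abs(f0 - analytic).sum() * sgrid.ds < 1e-3

    def test_mass_conserved_and_positive(self, phi_eps):
        sgrid = gf.SGrid(3.0, 128)
        rng = np.random.default_rng(7)
        f0 = rng.uniform(0, 1, sgrid.n_s)
        f0 /= f0.sum() * sgrid.ds
        run = evolve_homogeneous(
            f0, phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid,
            SolverParams(dt=0.01, t_end=10.0), record_every=1.0,
        )
        masses = run.profiles.sum(axis=1) * sgrid.ds
        assert np.max(np.abs(masses - 1.0)) < 1e-10
        assert run.profiles.min() >= 0.0

    def test_exponential_convergence_is_log_linear(self, phi_eps):
        """Post-transient decay toward the discrete fixed point is a clean
        exponential: R^2 > 0.99 for log L1-error vs t."""
        sgrid = gf.SGrid(3.0, 512)
        rng = np.random.default_rng(11)
        f0 = np.zeros(sgrid.n_s)
        idx = rng.choice(sgrid.n_s, 51, replace=False)
        f0[idx] = sgrid.n_s / (51 * sgrid.s_max)
        ref, _ = gf.discrete_stationary_profile(
            phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid
        )
        run = evolve_homogeneous(
            f0, phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid,
            SolverParams(dt=0.01, t_end=12.0), record_every=0.1,
        )
        err = run.l1_distance(ref)
        # window: below the multi-mode transient, above the round-off floor
        mask = (err < 0.05 * err[0]) & (err > 1e-12)
        t, y = run.times[mask], np.log(err[mask])
        assert mask.sum() > 20
        slope, icpt = np.polyfit(t, y, 1)
        resid = y - (slope * t + icpt)
        r2 = 1 - resid.var() / y.var()
        assert slope < 0
        assert r2 > 0.99

    def test_reflected_ou_spectral_gap(self):
        """With constant Phi and the boundary far away the solver must relax
        at exactly the Ornstein-Uhlenbeck rate 1/tau (independent oracle for
        the time scaling of the scheme)."""

        class _Const:
            def value(self, x):
                return 2.0

            def derivative(self, x):
                return 0.0

        sigma, tau = 0.01, 1.0
        sgrid = gf.SGrid(4.0, 256)
        st = gf.solve_consistency(_Const(), 0.0, 1.0, sigma)
        finf = stationary_density(st, sgrid)
        finf = finf / (finf.sum() * sgrid.ds)
        # perturb with the first OU eigenfunction (s - mu) f_inf
        pert = (sgrid.centers - 2.0) * finf
        f0 = finf + 0.01 * pert / np.abs(pert).sum() / sgrid.ds
        f0 = np.maximum(f0, 0)
        f0 /= f0.sum() * sgrid.ds
        run = evolve_homogeneous(
            f0, _Const(), 0.0, 1.0, sigma, sgrid,
            SolverParams(dt=0.005, t_end=8.0, tau=tau), record_every=0.1,
        )
        # measure against the run's own limit so the quadrature offset of the
        # discrete fixed point does not pollute the plateau
        err = np.abs(run.means - run.means[-1])
        mask = (run.times < 4.0) & (err > 1e-10)
        assert mask.sum() > 20
        slope = np.polyfit(run.times[mask], np.log(err[mask]), 1)[0]
        assert -slope == pytest.approx(1.0 / tau, rel=0.02)

    def test_grid_refinement_second_order(self, phi_eps):
        """Halving ds changes the steady mean by O(ds^2)."""
        means = {}
        for ns in (64, 128, 256):
            sgrid = gf.SGrid(3.0, ns)
            st = gf.solve_consistency(phi_eps, W0_REFERENCE, B_REFERENCE, 0.03)
            f0 = stationary_density(st, sgrid)
            f0 /= f0.sum() * sgrid.ds
            run = evolve_homogeneous(
                f0, phi_eps, W0_REFERENCE, B_REFERENCE, 0.03, sgrid,
                SolverParams(dt=0.02, t_end=30.0),
            )
            means[ns] = run.means[-1]
        e1 = abs(means[64] - means[256])
        e2 = abs(means[128] - means[256])
        assert e2 < e1 / 2.5  # ~factor 4 for second order, allow slack


class TestFiringRateField:
    def test_homogeneous_mean_gives_uniform_rate(self, phi_eps, shifts):
        sheet = gf.SheetGrid(64)
        conn = gf.eval_connectivity("tanh_bump", sheet)
        m = 0.14
        means = np.full((N_POP, 64, 64), m)
        rates = firing_rate_field(means, conn, shifts, phi_eps, np.full(N_POP, 3.0))
        # exactly uniform in space and across populations ...
        assert np.ptp(rates) < 1e-12
        # ... at the value Phi(W0 m + B) up to the kernel quadrature error
        expected = phi_eps.value(conn.W0 * m + 3.0)
        assert np.allclose(rates, expected, atol=1e-6)

    def test_zero_kernel_returns_drive(self, phi_eps, shifts):
        sheet = gf.SheetGrid(8)
        conn = gf.eval_connectivity("constant", sheet, params={"value": 0.0})
        rng = np.random.default_rng(3)
        means = rng.uniform(0, 1, (N_POP, 8, 8))
        drive = np.array([1.0, 2.0, 3.0, 4.0])
        rates = firing_rate_field(means, conn, shifts, phi_eps, drive)
        for b in range(N_POP):
            assert np.allclose(rates[b], phi_eps.value(drive[b]), atol=1e-12)

    def test_spectral_equals_direct_summation(self, phi_eps, shifts):
        """O(n^4) direct double sum oracle on a small sheet."""
        n = 8
        sheet = gf.SheetGrid(n)
        conn = gf.eval_connectivity("tanh_bump", sheet)
        rng = np.random.default_rng(5)
        means = rng.uniform(0, 1, (N_POP, n, n))
        B = 3.0
        _, inputs = firing_rate_field(
            means, conn, shifts, phi_eps, np.full(N_POP, B), return_inputs=True
        )
        x = sheet.centers
        h2 = sheet.h**2

        def W(r):
            return gf.tanh_bump_kernel()(r)

        def mi(d):
            return d - np.round(d)

        direct = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for bp in range(N_POP):
                    rx, ry = shifts.vectors[bp]
                    for a in range(n):
                        for b in range(n):
                            dx = mi(x[i] - x[a] - rx)
                            dy = mi(x[j] - x[b] - ry)
                            acc += W(np.hypot(dx, dy)) * means[bp, a, b]
                direct[i, j] = acc * h2 / 4.0 + B
        assert np.allclose(inputs[0], direct, atol=1e-11)


class TestFullSystem:
    def test_homogeneous_initial_data_stays_homogeneous(self, phi_eps, shifts):
        sheet = gf.SheetGrid(8)
        sgrid = gf.SGrid(3.0, 32)
        conn = gf.eval_connectivity("tanh_bump", sheet)
        st = gf.solve_consistency(phi_eps, conn.W0, 3.0, 0.05)
        fld = _homog_field(st, sheet, sgrid)
        run = evolve_full(
            fld, conn, shifts, phi_eps, np.full(N_POP, 3.0),
            SolverParams(dt=0.02, t_end=5.0),
        )
        tm = run.field.total_mean()
        assert tm.max() - tm.min() < 1e-8
        # and close to stationary (up to quadrature shift of the fixed point)
        assert abs(tm.mean() / N_POP - st.mean) < 5e-3

    def test_mass_positivity_and_periodicity(self, phi_eps, shifts):
        sheet = gf.SheetGrid(8)
        sgrid = gf.SGrid(3.0, 32)
        conn = gf.eval_connectivity("tanh_bump", sheet)
        fld = gf.preset_initial_data(
            "random", sheet, sgrid, phi_eps, conn.W0, 3.0, 0.03, seed=2
        )
        run = evolve_full(
            fld, conn, shifts, phi_eps, np.full(N_POP, 3.0),
            SolverParams(dt=0.05, t_end=10.0),
        )
        assert np.max(np.abs(run.field.site_mass() - 1.0)) < 1e-10
        assert run.field.values.min() >= 0.0


class TestFieldIO:
    def test_hdf5_round_trip_and_hash_guard(self, tmp_path, phi_eps):
        sheet = gf.SheetGrid(8)
        sgrid = gf.SGrid(3.0, 16)
        conn = gf.eval_connectivity("tanh_bump", sheet)
        fld = gf.preset_initial_data(
            "random", sheet, sgrid, phi_eps, conn.W0, 3.0, 0.03, seed=1
        )
        fld.t = 2.5
        p = tmp_path / "field.h5"
        gf.save_field(fld, p, config_hash="abc123")
        back = gf.load_field(p, expect_config_hash="abc123")
        assert np.array_equal(back.values, fld.values)
        assert back.t == 2.5 and back.sigma == 0.03
        with pytest.raises(ValueError, match="hash"):
            gf.load_field(p, expect_config_hash="different")


class TestSteadyDetect:
    def test_constant_sequence_converges_immediately(self):
        snaps = np.ones((4, 5))
        ok, final = steady_state_detect(np.arange(4.0), snaps, tolerance=1e-8)
        assert ok and np.allclose(final, 1.0)

    def test_moving_target_not_converged(self):
        t = np.arange(6.0)
        snaps = np.outer(1 + t, np.ones(5))  # keeps drifting
        ok, final = steady_state_detect(t, snaps, tolerance=1e-3)
        assert not ok and final is None

    def test_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            steady_state_detect(np.array([0.0]), np.ones((1, 3)), 1e-6)
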