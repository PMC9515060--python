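"""Fourier kernel, growth factors, eigenstructure and the noise threshold."""

import numpy as np
import pytest
from scipy.special import j1

import gridfield as gf
from gridfield.stability import (
    cosine_sum,
    critical_sigma,
    fourier_kernel,
    growth_factor,
    lattice_scan,
    mode_eigenvalues,
    mode_matrix,
    pattern_preview,
)
from conftest import B_REFERENCE, W0_REFERENCE

#: Dominant-mode families reported for the reference tanh kernel.
PRINTED_ORBIT = {(4, 0), (4, 1), (3, 3), (1, 4), (0, 4)}


def _orbit(modes):
    out = set()
    for k1, k2 in modes:
        for a in (k1, -k1):
            for b in (k2, -k2):
                out |= {(a, b), (b, a)}
    return out


class TestFourierKernel:
    def test_zero_mode_is_W0(self, tanh_conn_256):
        assert fourier_kernel(tanh_conn_256, (0, 0)) == pytest.approx(
            tanh_conn_256.W0, rel=1e-12
        )

    def test_non_integer_mode_rejected(self, tanh_conn_64):
        with pytest.raises(ValueError, match="integer"):
            fourier_kernel(tanh_conn_64, (0.5, 1))

    def test_ball_kernel_matches_bessel_closed_form(self):
        """Transform of the disk indicator: 2*pi*r*J1(r|k|)/|k|.

        The scaling (including the leading factor r) is pinned down by the
        brute-force quadrature of the defining integral, computed here on an
        independent midpoint grid.
        """
        r = 0.2
        conn = gf.eval_connectivity(
            "ball", gf.SheetGrid(512), params={"radius": r, "depth": -1.0}
        )
        # independent quadrature oracle on a shifted (cell-center) grid
        n = 701
        x = -0.5 + (np.arange(n) + 0.5) / n
        X, Y = np.meshgrid(x, x, indexing="ij")
        inside = np.hypot(X, Y) <= r
        for k in [(1, 0), (2, 1), (4, 0), (3, 3)]:
            kvec = 2 * np.pi * np.array(k)
            knorm = np.linalg.norm(kvec)
            closed = -2 * np.pi * r * j1(r * knorm) / knorm
            oracle = -np.sum(np.cos(kvec[0] * X + kvec[1] * Y) * inside) / n**2
            assert oracle == pytest.approx(closed, abs=2e-4)
            assert fourier_kernel(conn, k) == pytest.approx(closed, abs=2e-3)

    def test_tanh_kernel_side_lobe_positive(self, tanh_conn_256):
        # first side lobe of the (inhibitory) disk-like transform: positive
        assert fourier_kernel(tanh_conn_256, (4, 0)) > 0


class TestCosineSum:
    def test_zero_mode_and_zero_shift(self, shifts):
        assert cosine_sum(shifts, (0, 0)) == pytest.approx(4.0)
        assert cosine_sum(gf.ShiftSet(0.0), (7, -3)) == pytest.approx(4.0)

    @pytest.mark.parametrize("k", [(4, 1), (0, 4), (-3, 3), (8, 8)])
    def test_matches_direct_complex_sum(self, shifts, k):
        kvec = 2 * np.pi * np.array(k, dtype=float)
        direct = np.exp(-1j * shifts.vectors @ kvec).sum()
        assert abs(direct.imag) < 1e-13
        assert cosine_sum(shifts, k) == pytest.approx(direct.real, abs=1e-14)
        assert -4.0 - 1e-12 <= cosine_sum(shifts, k) <= 4.0 + 1e-12


class TestGrowthFactor:
    def test_zero_mode_value(self, fig2_state, phi_eps, tanh_conn_256, shifts):
        F0 = growth_factor(fig2_state, phi_eps, tanh_conn_256, shifts, (0, 0))
        phi0p = phi_eps.derivative(W0_REFERENCE * fig2_state.mean + B_REFERENCE)
        assert F0 == pytest.approx(phi0p * tanh_conn_256.W0, rel=1e-12)
        assert F0 <= 0

    def test_saturated_modulation_always_stable(self, tanh_conn_64, shifts):
        # sigmoid driven deep into saturation: Phi0' ~ 0 -> F ~ 0
        phi = gf.sigmoid(15.0)
        st = gf.solve_consistency(phi, -0.1, 5.0, 0.05)
        rep = lattice_scan(st, phi, tanh_conn_64, shifts, K=4)
        assert np.max(np.abs(rep.F)) < 1e-6
        assert rep.stable_zero_noise and rep.stable_noisy

    def test_dominant_modes_in_printed_orbit(
        self, fig2_state, phi_eps, tanh_conn_256, shifts
    ):
        rep = lattice_scan(fig2_state, phi_eps, tanh_conn_256, shifts, K=8)
        allowed = _orbit(PRINTED_ORBIT)
        assert rep.dominant_modes  # nonempty
        assert set(rep.dominant_modes) <= allowed

    def test_dihedral_symmetry_for_radial_kernel(
        self, fig2_state, phi_eps, tanh_conn_256, shifts
    ):
        rep = lattice_scan(fig2_state, phi_eps, tanh_conn_256, shifts, K=6)
        F = rep.F
        assert np.allclose(F, F[::-1, :], atol=1e-12)
        assert np.allclose(F, F[:, ::-1], atol=1e-12)
        assert np.allclose(F, F.T, atol=1e-12)


class TestModeEigenvalues:
    @pytest.mark.parametrize("F, tau", [(1.0, 1.0), (0.0, 0.5), (2.7, 2.0), (-3.1, 1.0)])
    def test_closed_form_against_numeric_eigensolve(self, F, tau, shifts):
        # assemble a mode matrix whose growth factor equals F and eigensolve it
        k = (4, 1)
        cs = cosine_sum(shifts, k)
        phi0p_What = 4.0 * F / cs
        A = mode_matrix(phi0p_What, 1.0, shifts, k, tau)
        numeric = np.sort_complex(np.linalg.eigvals(A))
        closed = np.sort_complex(mode_eigenvalues(F, tau).astype(complex))
        assert np.allclose(numeric, closed, atol=1e-10)

    def test_marginal_and_degenerate_cases(self):
        ev = mode_eigenvalues(1.0, 1.0)
        assert np.isclose(ev[-1], 0.0)
        assert np.allclose(ev[:3], -1.0)
        assert np.allclose(mode_eigenvalues(0.0, 2.0), -0.5)

    def test_eigenvalue_product_matches_characteristic_polynomial(self):
        for F, tau in [(0.3, 1.0), (2.0, 0.7)]:
            ev = mode_eigenvalues(F, tau)
            assert np.prod(ev) == pytest.approx((1 - F) / tau**4, rel=1e-12)


class TestCriticalSigma:
    def test_saturated_modulation_sentinel(self, shifts):
        # weak constant inhibition: the sigmoid sits in saturation and the
        # only nonzero transform mode is k = 0 with F <= 0
        phi = gf.sigmoid(15.0)
        conn = gf.eval_connectivity("constant", gf.SheetGrid(16), params={"value": -0.1})
        assert critical_sigma(phi, conn, shifts, B=5.0, sigma_hi=0.5) is None

    def test_bisection_agrees_with_grid_scan(self, phi_eps, tanh_conn_256, shifts):
        sc = critical_sigma(phi_eps, tanh_conn_256, shifts, B_REFERENCE)
        assert sc is not None
        # dense grid scan of max F * M_inf / sigma crossing 1
        sigmas = np.linspace(0.9 * sc, 1.1 * sc, 400)
        vals = []
        for s in sigmas:
            st = gf.solve_consistency(phi_eps, tanh_conn_256.W0, B_REFERENCE, s)
            rep = lattice_scan(st, phi_eps, tanh_conn_256, shifts, K=8)
            vals.append(rep.max_F * st.M_inf / st.sigma)
        vals = np.array(vals)
        idx = np.flatnonzero((vals[:-1] > 1) & (vals[1:] <= 1))
        assert len(idx) == 1
        crossing = sigmas[idx[0]]
        assert sc == pytest.approx(crossing, abs=1e-4 + np.diff(sigmas)[0])

    def test_condition_holds_above_and_fails_below(self, phi_eps, tanh_conn_256, shifts):
        sc = critical_sigma(phi_eps, tanh_conn_256, shifts, B_REFERENCE)
        for s, stable in [(1.1 * sc, True), (0.9 * sc, False)]:
            st = gf.solve_consistency(phi_eps, tanh_conn_256.W0, B_REFERENCE, s)
            rep = lattice_scan(st, phi_eps, tanh_conn_256, shifts, K=8)
            assert rep.stable_noisy is stable


class TestPatternPreview:
    def test_single_axial_mode_gives_four_stripes(self):
        grid = gf.SheetGrid(64)
        fld = pattern_preview([(4, 0)], grid)
        # constant along y, 4 periods along x
        assert np.allclose(fld, fld[:, :1])
        ft = np.abs(np.fft.fft(fld[:, 0]))
        assert np.argmax(ft[1:33]) + 1 == 4

    def test_two_orthogonal_modes_checkerboard(self):
        grid = gf.SheetGrid(64)
        fld = pattern_preview([(4, 0), (0, 4)], grid)
        assert np.allclose(fld, fld.T)

    def test_hexagonal_combination_peak_count(self):
        """Modes (4,1), (1,4), (3,-3): the local-maximum count matches a
        brute-force peak search and is consistent with a hexagonal lattice."""
        grid = gf.SheetGrid(128)
        fld = pattern_preview([(4, 1), (1, 4), (3, -3)], grid)
        peaks = 0
        for dx in (-1, 0, 1):
            pass
        rolled = [
            np.roll(np.roll(fld, dx, 0), dy, 1)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0)
        ]
        is_peak = np.all([fld > r for r in rolled], axis=0)
        n_peaks = int(is_peak.sum())
        # ~|k|^2-scale count: the three wavevectors tile the torus with
        # 13-17 maxima; exact count pinned by this same brute-force rule
        assert 10 <= n_peaks <= 20

    def test_empty_mode_list_rejected(self):
        with pytest.raises(ValueError):
            pattern_preview([], gf.SheetGrid(16))
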