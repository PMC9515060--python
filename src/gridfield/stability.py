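"""Linear stability of the homogeneous state against sheet-periodic modes.

Perturbing the homogeneous stationary state by a single spatial Fourier mode
k = 2*pi*(k1, k2), k1, k2 integers, the four-population linearisation has the
per-mode growth factor

    F(k) = (1/4) * Phi0' * W_hat(k) * sum_beta exp(-i k . r^beta),

with Phi0' = Phi'(W0 <f_inf> + B) and W_hat the Fourier transform of the
connectivity restricted to the sheet.  For equal cardinal shifts the complex
sum collapses to 2 cos(2 pi k1 z) + 2 cos(2 pi k2 z), so F is real.  Each
mode contributes eigenvalues {-1/tau (x3), (F(k) - 1)/tau}: without noise the
homogeneous state is stable iff F(k) < 1 for all k, and with noise iff
F(k) < sigma / M_inf(sigma) — noise *stabilises*, since sigma/M_inf >= 1.
The critical noise sigma_c solves max_k F(k; sigma) = sigma / M_inf(sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kernels import Connectivity, Modulation, SheetGrid, ShiftSet
from .stationary import HomogeneousState, solve_consistency

__all__ = [
    "StabilityReport",
    "fourier_kernel",
    "cosine_sum",
    "growth_factor",
    "mode_eigenvalues",
    "mode_matrix",
    "lattice_scan",
    "critical_sigma",
    "pattern_preview",
]


def fourier_kernel(conn: Connectivity, k: tuple[int, int]) -> float:
    """W_hat(k) = int_Omega W(x) exp(-i 2 pi (k1, k2) . x) dx at a lattice mode.

    Computed as the discrete transform of the periodised kernel samples scaled
    by cell area.  Only integer mode pairs exist on the torus.  Evenness of W
    makes the transform real; the imaginary residual is checked.
    """
    k1, k2 = k
    if k1 != int(k1) or k2 != int(k2):
        raise ValueError("the torus admits only integer lattice modes")
    k1, k2 = int(k1), int(k2)
    n = conn.grid.n_x
    ft = np.fft.fft2(conn.samples)[k1 % n, k2 % n] * conn.grid.h**2
    if abs(ft.imag) > 1e-10 * max(abs(conn.W0), 1e-30):
        raise ValueError(
            f"non-negligible imaginary part {ft.imag:.3e} in W_hat; kernel not even?"
        )
    return float(ft.real)


def cosine_sum(shifts: ShiftSet, k: tuple[int, int]) -> float:
    """sum_beta exp(-i k . r^beta) for cardinal equal-length shifts.

    Opposite shifts pair into cosines: 2 cos(2 pi k1 z) + 2 cos(2 pi k2 z).
    """
    k1, k2 = k
    z = shifts.z
    return float(2.0 * np.cos(2.0 * np.pi * k1 * z) + 2.0 * np.cos(2.0 * np.pi * k2 * z))


def growth_factor(
    state: HomogeneousState,
    phi: Modulation,
    conn: Connectivity,
    shifts: ShiftSet,
    k: tuple[int, int],
) -> float:
    """F(k) = (1/4) Phi0' W_hat(k) sum_beta exp(-i k . r^beta)."""
    phi0p = phi.derivative(state.W0 * state.mean + state.B)
    return 0.25 * phi0p * fourier_kernel(conn, k) * cosine_sum(shifts, k)


def mode_eigenvalues(F_k: float, tau: float = 1.0) -> np.ndarray:
    """Eigenvalues of the per-mode 4x4 linearisation.

    The coupling matrix is rank one (every population feels the same weighted
    sum), so three eigenvalues sit at -1/tau and the remaining one at
    (F(k) - 1)/tau, which decides stability.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return np.array([-1.0 / tau, -1.0 / tau, -1.0 / tau, (F_k - 1.0) / tau])


def mode_matrix(
    phi0_prime: float,
    W_hat: float,
    shifts: ShiftSet,
    k: tuple[int, int],
    tau: float = 1.0,
) -> np.ndarray:
    """Assembled per-mode 4x4 matrix A with tau du/dt = tau A u.

    A[b, b'] = (Phi0' W_hat / (4 tau)) exp(-i k . r^{b'}) - delta_{bb'}/tau.
    Provided so the closed-form eigenvalues can be verified numerically.
    """
    k1, k2 = k
    kvec = 2.0 * np.pi * np.array([k1, k2], dtype=float)
    phases = np.exp(-1j * shifts.vectors @ kvec)
    A = (phi0_prime * W_hat / (4.0 * tau)) * np.ones((4, 1)) * phases[None, :]
    return A - np.eye(4) / tau


@dataclass(frozen=True)
class StabilityReport:
    """Growth factors on the mode lattice |k1|, |k2| <= K and derived flags."""

    state: HomogeneousState
    K: int
    k1: np.ndarray  # (2K+1, 2K+1) integer lattice
    k2: np.ndarray
    W_hat: np.ndarray
    cos_sum: np.ndarray
    F: np.ndarray
    dominant_modes: list = field(default_factory=list)
    sigma_c: float | None = None

    @property
    def ratio(self) -> np.ndarray:
        """M_inf * F(k) / sigma; instability where this exceeds 1."""
        return self.state.M_inf * self.F / self.state.sigma

    @property
    def max_F(self) -> float:
        return float(self.F.max())

    @property
    def stable_zero_noise(self) -> bool:
        return bool(self.max_F < 1.0)

    @property
    def stable_noisy(self) -> bool:
        return bool(self.max_F < self.state.threshold_ratio)


def _dominant_orbit(k1, k2, F, rel_tol=1e-9):
    fmax = F.max()
    tol = rel_tol * max(abs(fmax), 1.0)
    hits = np.argwhere(F >= fmax - tol)
    modes = sorted((int(k1[i, j]), int(k2[i, j])) for i, j in hits)
    return modes


def lattice_scan(
    state: HomogeneousState,
    phi: Modulation,
    conn: Connectivity,
    shifts: ShiftSet,
    K: int = 8,
) -> StabilityReport:
    """Evaluate F(k) over the lattice |k1|, |k2| <= K.

    Dominant modes are reported as the full symmetry orbit of the maximiser
    (ties within 1e-9 relative), ordered lexicographically.
    """
    ks = np.arange(-K, K + 1)
    K1, K2 = np.meshgrid(ks, ks, indexing="ij")
    spectrum = conn.spectrum()
    n = conn.grid.n_x
    W_hat = spectrum[K1 % n, K2 % n]
    cs = 2.0 * np.cos(2.0 * np.pi * K1 * shifts.z) + 2.0 * np.cos(2.0 * np.pi * K2 * shifts.z)
    phi0p = phi.derivative(state.W0 * state.mean + state.B)
    F = 0.25 * phi0p * W_hat * cs
    return StabilityReport(
        state=state,
        K=K,
        k1=K1,
        k2=K2,
        W_hat=W_hat,
        cos_sum=cs,
        F=F,
        dominant_modes=_dominant_orbit(K1, K2, F),
    )


def _max_growth(sigma, phi, conn, shifts, B, K):
    state = solve_consistency(phi, conn.W0, B, sigma)
    report = lattice_scan(state, phi, conn, shifts, K)
    return report.max_F, state


def critical_sigma(
    phi: Modulation,
    conn: Connectivity,
    shifts: ShiftSet,
    B: float,
    *,
    K: int = 8,
    sigma_lo: float = 1e-4,
    sigma_hi: float = 1.0,
    tol: float = 1e-6,
) -> float | None:
    """The noise level at which max_k F(k; sigma) = sigma / M_inf(sigma).

    Above the returned sigma_c the homogeneous state is linearly stable on the
    scanned lattice; below it the dominant mode grows.  Returns ``None`` when
    the excess max_k F - sigma/M_inf is negative over the whole bracket
    ("stable for all sigma" sentinel, e.g. saturated modulation with
    Phi0' = 0).  The consistency equation and M_inf are re-solved at every
    iterate since Phi0 depends on sigma.
    """

    def excess(sigma):
        max_F, state = _max_growth(sigma, phi, conn, shifts, B, K)
        return max_F - state.threshold_ratio

    # locate a sign change on a log grid
    grid = np.geomspace(sigma_lo, sigma_hi, 25)
    vals = [excess(s) for s in grid]
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa > 0 >= fb:
            bracket = (a, b)
            break
    if bracket is None:
        if max(vals) <= 0:
            return None
        raise ValueError(
            "max_k F - sigma/M_inf does not change sign from + to - on "
            f"[{sigma_lo}, {sigma_hi}]; widen the bracket"
        )
    return float(optimize.brentq(excess, *bracket, xtol=tol))


def pattern_preview(modes, grid: SheetGrid) -> np.ndarray:
    """Equal-weight sum of cos(k . x) over the sheet for a list of mode pairs.

    Previews the spatial pattern a set of dominant modes would seed: a single
    axial mode gives stripes, two orthogonal modes a checkerboard, and three
    suitably chosen non-collinear modes a hexagonal-like lattice.
    """
    modes = list(modes)
    if not modes:
        raise ValueError("mode list must be nonempty")
    x = grid.centers
    X, Y = np.meshgrid(x, x, indexing="ij")
    out = np.zeros_like(X)
    for k1, k2 in modes:
        out += np.cos(2.0 * np.pi * (k1 * X + k2 * Y))
    return out
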