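"""Spatially homogeneous stationary states of the noisy neural field.

When every sheet location sees the same input, the population density in the
activity variable s relaxes to a Gaussian of variance sigma centred at the
self-consistent firing rate Phi0, truncated to s >= 0 by the no-flux boundary:

    f_inf(s) = (1/Z) exp(-(s - Phi0)^2 / (2 sigma)),
    Z = sqrt(pi sigma / 2) (1 + erf(Phi0 / sqrt(2 sigma))),

where Phi0 = Phi(W0 <f_inf> + B) and the mean <f_inf> must solve the scalar
consistency equation

    <f_inf> = Phi0 + sigma exp(-Phi0^2 / (2 sigma)) / Z.

For inhibitory coupling (W0 <= 0) and Phi'(W0 m + B) > 1/W0 the consistency
map is strictly decreasing in m, so the root is unique.  The second central
moment M_inf(sigma) of f_inf controls the noisy linear-stability threshold:
instability requires a Fourier growth factor to exceed sigma / M_inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import erfc, erfcx

from .kernels import Modulation, SGrid

__all__ = [
    "HomogeneousState",
    "NonUniqueRootWarning",
    "solve_consistency",
    "stationary_density",
    "discrete_stationary_profile",
    "central_moment",
    "truncated_gaussian_stats",
    "consistency_gain",
]

_SQRT2 = np.sqrt(2.0)
_SQRT_2_PI = np.sqrt(2.0 / np.pi)


class NonUniqueRootWarning(UserWarning):
    """The uniqueness hypotheses of the consistency equation do not hold."""


def _mills(alpha):
    """Inverse Mills ratio phi(alpha)/(1 - Phi(alpha)) of the standard normal.

    Computed through erfcx so it is accurate for strongly negative alpha
    (mild truncation) as well as strongly positive alpha (severe truncation).
    """
    return _SQRT_2_PI / erfcx(np.asarray(alpha, dtype=float) / _SQRT2)


def truncated_gaussian_stats(phi0: float, sigma: float) -> tuple[float, float, float]:
    """(Z, mean, variance) of the Gaussian N(phi0, sigma) truncated to [0, inf).

    Z is the mass normalisation of the *unnormalised* Gaussian kernel
    exp(-(s-phi0)^2/(2 sigma)); mean and variance are those of the normalised
    truncated density.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sd = np.sqrt(sigma)
    alpha = -phi0 / sd
    lam = float(_mills(alpha))
    with np.errstate(under="ignore"):
        Z = float(np.sqrt(np.pi * sigma / 2.0) * erfc(alpha / _SQRT2))
    mean = phi0 + sd * lam
    var = sigma * (1.0 + alpha * lam - lam * lam)
    return Z, mean, var


def consistency_gain(eta):
    """Sensitivity g(eta) of the truncated-Gaussian mean to its location.

    g(eta) = 1 - (2/sqrt(pi)) * E(eta) * (E(eta)/sqrt(pi) + eta) with
    E(eta) = exp(-eta^2)/(1 + erf(eta)) = 1/erfcx(-eta); here
    eta = Phi0/sqrt(2 sigma).  g is bounded in [0, 1] for all real eta with
    supremum 1 reached in the eta -> infinity limit, which is what makes the
    consistency map monotone under the inhibitory-coupling hypotheses.
    """
    eta = np.asarray(eta, dtype=float)
    E = 1.0 / erfcx(-eta)
    out = 1.0 - (2.0 / np.sqrt(np.pi)) * E * (E / np.sqrt(np.pi) + eta)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HomogeneousState:
    """A solved spatially homogeneous stationary state."""

    sigma: float
    phi0: float
    Z: float
    mean: float
    M_inf: float
    B: float
    W0: float

    @property
    def threshold_ratio(self) -> float:
        """sigma / M_inf, the noisy linear-stability threshold on F(k)."""
        return self.sigma / self.M_inf


def _zero_noise_state(phi: Modulation, W0: float, B: float) -> HomogeneousState:
    """Deterministic limit: the density collapses onto the fixed point of
    m = Phi(W0 m + B) (nonnegative part)."""

    def resid(m):
        return max(phi.value(W0 * m + B), 0.0) - m

    hi = max(phi.value(B), 0.0) + 1.0
    m = optimize.brentq(resid, 0.0, hi, xtol=1e-14) if resid(0.0) > 0 else 0.0
    phi0 = float(phi.value(W0 * m + B))
    return HomogeneousState(sigma=0.0, phi0=phi0, Z=0.0, mean=m, M_inf=0.0, B=B, W0=W0)


def solve_consistency(
    phi: Modulation,
    W0: float,
    B: float,
    sigma: float,
    *,
    tol: float = 1e-12,
) -> HomogeneousState:
    """Solve the mean consistency equation and return the stationary state.

    The root of G(m) = truncated-Gaussian-mean(Phi(W0 m + B), sigma) - m is
    bracketed on [0, Phi(B) + sqrt(sigma/(2 pi)) + 1] (the upper end follows
    from <f_inf> <= Phi0 + sqrt(sigma/(2 pi)) and monotonicity of Phi) and
    located by Brent's method, so non-smooth modulations (ReLU) are admissible.
    Outside the uniqueness hypotheses a root is still returned but a
    ``NonUniqueRootWarning`` is issued.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0.0:
        return _zero_noise_state(phi, W0, B)

    def G(m):
        phi0 = phi.value(W0 * m + B)
        _, mean, _ = truncated_gaussian_stats(phi0, sigma)
        return mean - m

    hi = max(phi.value(B), 0.0) + np.sqrt(sigma / (2.0 * np.pi)) + 1.0
    g0, ghi = G(0.0), G(hi)
    if not (g0 > 0 > ghi):
        raise ValueError(
            "consistency equation has no sign change on the bracket "
            f"[0, {hi:.3g}] (G(0)={g0:.3g}, G(hi)={ghi:.3g}); "
            "model assumptions violated"
        )
    m_star = optimize.brentq(G, 0.0, hi, xtol=tol, rtol=8.9e-16)

    if W0 > 0 or phi.derivative(W0 * m_star + B) <= (1.0 / W0 if W0 != 0 else -np.inf):
        warnings.warn(
            "uniqueness hypotheses (W0 <= 0, Phi'(W0 m + B) > 1/W0) do not hold "
            "at the located root; other roots may exist",
            NonUniqueRootWarning,
        )

    phi0 = float(phi.value(W0 * m_star + B))
    Z, mean, var = truncated_gaussian_stats(phi0, sigma)
    return HomogeneousState(
        sigma=sigma, phi0=phi0, Z=Z, mean=mean, M_inf=var, B=B, W0=W0
    )


def stationary_density(state: HomogeneousState, grid: SGrid) -> np.ndarray:
    """The stationary profile f_inf sampled at the cell centers of ``grid``.

    Samples carry the continuum normalisation Z, so the ds-weighted sum equals
    1 minus the Gaussian tail mass beyond s_max.  The grid must capture the
    tail: s_max >= Phi0 + 6 sqrt(sigma).
    """
    if state.sigma <= 0:
        raise ValueError("stationary_density requires sigma > 0")
    required = state.phi0 + 6.0 * np.sqrt(state.sigma)
    if grid.s_max < required:
        raise ValueError(
            f"s_max = {grid.s_max} truncates the stationary profile; "
            f"need s_max >= {required:.4g}"
        )
    s = grid.centers
    with np.errstate(under="ignore"):
        return np.exp(-((s - state.phi0) ** 2) / (2.0 * state.sigma)) / state.Z


def discrete_stationary_profile(
    phi: Modulation,
    W0: float,
    B: float,
    sigma: float,
    grid: SGrid,
) -> tuple[np.ndarray, float]:
    """The exact fixed point of the discretised homogeneous problem.

    The exponential-fitting flux makes the cell-center samples of a Gaussian
    centred at Phi0 stationary for *any* Phi0; the discrete consistency
    condition closes the loop through the ds-weighted mean instead of the
    continuum integral, so the discrete fixed point differs from the analytic
    profile by the O(ds^2) quadrature error.  Returns (profile, phi0).
    """
    s = grid.centers

    def profile_for(phi0):
        with np.errstate(under="ignore"):
            v = np.exp(-((s - phi0) ** 2) / (2.0 * sigma))
        return v / (v.sum() * grid.ds)

    def resid(m):
        phi0 = phi.value(W0 * m + B)
        f = profile_for(phi0)
        return float(f @ s) * grid.ds - m

    hi = max(phi.value(B), 0.0) + np.sqrt(sigma / (2.0 * np.pi)) + 1.0
    m = optimize.brentq(resid, 0.0, hi, xtol=1e-14)
    phi0 = float(phi.value(W0 * m + B))
    return profile_for(phi0), phi0


def central_moment(state: HomogeneousState, *, method: str = "closed_form") -> float:
    """Second central moment M_inf = int (s - <f_inf>)^2 f_inf ds.

    The closed truncated-normal form is the default; ``method="quad"``
    integrates adaptively instead (relative tolerance 1e-10) and exists as an
    independent route for cross-checking.
    """
    if method == "closed_form":
        return state.M_inf
    if method != "quad":
        raise ValueError("method must be 'closed_form' or 'quad'")
    sd = np.sqrt(state.sigma)

    def integrand(s):
        return (s - state.mean) ** 2 * np.exp(
            -((s - state.phi0) ** 2) / (2.0 * state.sigma)
        ) / state.Z

    upper = max(state.phi0, 0.0) + 15.0 * sd
    val, _ = integrate.quad(integrand, 0.0, upper, epsrel=1e-10, limit=200)
    return float(val)
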