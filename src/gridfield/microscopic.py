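"""Particle simulation of the reflected-SDE neuron network.

The Fokker-Planck description is the many-particle limit of a network of
noisy rate neurons whose activity is kept nonnegative by reflection at zero
(a Skorokhod problem): each neuron obeys

    tau ds = (Phi(coupling + B) - s) dt + sqrt(2 sigma tau) dW - dl,

where l is the nondecreasing boundary local time that only grows while
s = 0.  Two coupling topologies are provided: the all-to-all single
population (coupling W0 * mean activity / per-neuron), whose mean-field
limit is the homogeneous equation, and the sheet-structured four-orientation
network with the shifted kernels, whose limit is the full system.  The
discretisation is Euler-Maruyama with reflection either by clamping to zero
(local-time increment = clamped deficit, the standard projection scheme) or
by mirroring (s <- |s|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Connectivity, Modulation, ShiftSet
from .solver import N_POP, firing_rate_field

__all__ = [
    "ParticleEnsemble",
    "particle_step",
    "particle_step_sheet",
    "empirical_moments",
    "simulate_meanfield",
]


@dataclass
class ParticleEnsemble:
    """Activity levels and accumulated boundary local time, plus RNG state.

    ``s`` has the particle axis last: shape (M,) for the all-to-all model or
    (4, n, n, M) for the sheet network.
    """

    s: np.ndarray
    local_time: np.ndarray
    rng: np.random.Generator
    t: float = 0.0

    @classmethod
    def create(cls, shape, seed: int, s0: float | np.ndarray = 0.0) -> "ParticleEnsemble":
        s = np.broadcast_to(np.asarray(s0, dtype=float), shape).copy()
        if np.any(s < 0):
            raise ValueError("initial activities must be nonnegative")
        return cls(s=s, local_time=np.zeros(shape), rng=np.random.default_rng(seed))


def _reflect(s_raw: np.ndarray, local_time: np.ndarray, scheme: str) -> np.ndarray:
    deficit = np.maximum(-s_raw, 0.0)
    if scheme == "clamp":
        local_time += deficit
        return s_raw + deficit
    if scheme == "mirror":
        local_time += 2.0 * deficit
        return np.abs(s_raw)
    raise ValueError("reflection scheme must be 'clamp' or 'mirror'")


def particle_step(
    ens: ParticleEnsemble,
    phi: Modulation,
    W0: float,
    B: float,
    sigma: float,
    dt: float,
    *,
    tau: float = 1.0,
    reflection: str = "clamp",
) -> ParticleEnsemble:
    """One Euler-Maruyama step of the all-to-all network (in place).

    The coupling is W0 times the current empirical mean activity, the exact
    finite-M analogue of the homogeneous mean-field drive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = phi.value(W0 * ens.s.mean() + B)
    noise = ens.rng.standard_normal(ens.s.shape)
    s_raw = ens.s + (drive - ens.s) * dt / tau + np.sqrt(2.0 * sigma * dt / tau) * noise
    ens.s = _reflect(s_raw, ens.local_time, reflection)
    ens.t += dt
    return ens


def particle_step_sheet(
    ens: ParticleEnsemble,
    conn: Connectivity,
    shifts: ShiftSet,
    phi: Modulation,
    drive,
    sigma: float,
    dt: float,
    *,
    tau: float = 1.0,
    reflection: str = "clamp",
) -> ParticleEnsemble:
    """One step of the sheet-structured four-orientation network (in place).

    ``ens.s`` has shape (4, n, n, M); the pairwise kernel double sum over
    columns reduces to the torus convolution of the per-column mean activity,
    evaluated spectrally.  ``drive`` is the four-vector B^beta.
    """
    if ens.s.ndim != 4 or ens.s.shape[0] != N_POP:
        raise ValueError("sheet ensemble must have shape (4, n, n, M)")
    means = ens.s.mean(axis=-1)
    rates = firing_rate_field(means, conn, shifts, phi, drive)
    noise = ens.rng.standard_normal(ens.s.shape)
    s_raw = (
        ens.s
        + (rates[..., None] - ens.s) * dt / tau
        + np.sqrt(2.0 * sigma * dt / tau) * noise
    )
    ens.s = _reflect(s_raw, ens.local_time, reflection)
    ens.t += dt
    return ens


def empirical_moments(ens: ParticleEnsemble):
    """Unbiased mean/variance over the particle axis with standard errors.

    Returns (mean, var, sem) where sem = sqrt(var/M); for the sheet ensemble
    the statistics are per (beta, x, y).
    """
    M = ens.s.shape[-1]
    if M < 2:
        raise ValueError("need at least two particles for moments")
    mean = ens.s.mean(axis=-1)
    var = ens.s.var(axis=-1, ddof=1)
    sem = np.sqrt(var / M)
    return mean, var, sem


def simulate_meanfield(
    M: int,
    phi: Modulation,
    W0: float,
    B: float,
    sigma: float,
    *,
    t_end: float = 20.0,
    dt: float = 1e-3,
    tau: float = 1.0,
    seed: int = 0,
    s0: float = 0.0,
    reflection: str = "clamp",
) -> ParticleEnsemble:
    """Run the all-to-all ensemble to ``t_end`` and return the final state."""
    ens = ParticleEnsemble.create((M,), seed=seed, s0=s0)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        particle_step(ens, phi, W0, B, sigma, dt, tau=tau, reflection=reflection)
    return ens
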