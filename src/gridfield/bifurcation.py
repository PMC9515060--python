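"""Continuation in the noise strength and pattern classification.

Steady states of the full system are tracked along a ladder of noise values
sigma by solving the time-dependent problem to stabilisation and reusing each
steady field as the initial datum for the next sigma (left-to-right or
right-to-left).  The diagram records the spatial maximum and minimum of the
total mean activity <f>(x) = sum_beta <f^beta>(x): the two coincide on the
homogeneous branch and split when a pattern forms.  Sweeping in both
directions exposes hysteresis — near the transition the branch reached
depends on the sweep direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import Connectivity, Modulation, SGrid, SheetGrid, ShiftSet
from .solver import (
    N_POP,
    PopulationField,
    SolverParams,
    evolve_full,
)
from .stationary import solve_consistency, stationary_density

__all__ = [
    "BranchPoint",
    "BifurcationBranch",
    "preset_initial_data",
    "classify_pattern",
    "sweep",
]

PRESETS = ("random", "perturbed_homogeneous", "stripe_band")


def preset_initial_data(
    kind: str,
    sheet: SheetGrid,
    sgrid: SGrid,
    phi: Modulation,
    W0: float,
    B: float,
    sigma: float,
    *,
    seed: int = 0,
    amplitude: float | None = None,
    band_width: float = 0.25,
    tau: float = 1.0,
) -> PopulationField:
    """Build a normalised initial field of one of the preset classes.

    - ``random``: the homogeneous profile modulated by iid uniform spatial
      noise of relative amplitude 0.3 (generic data; large basins win).
    - ``perturbed_homogeneous``: mean-zero spatial perturbation of relative
      amplitude 1e-2 (probes local stability of the homogeneous state).
    - ``stripe_band``: activity level one enforced in a horizontal band of
      width ``band_width``, homogeneous profile elsewhere (seeds the
      stripe-like branch).

    Because every site carries unit probability mass, a perturbation cannot
    scale the local density — it must deform it.  Perturbations therefore
    shift the local profile centre (the translation mode f_inf(s - delta),
    which changes the local mean activity by ~delta while preserving mass);
    multiplicative factors would be cancelled exactly by the per-site
    renormalisation.
    """
    state = solve_consistency(phi, W0, B, sigma)
    prof = stationary_density(state, sgrid)
    prof = prof / (prof.sum() * sgrid.ds)
    n = sheet.n_x
    rng = np.random.default_rng(seed)
    s = sgrid.centers

    def shifted(centers):
        """Truncated-Gaussian profiles centred at ``centers`` (site-wise)."""
        with np.errstate(under="ignore"):
            v = np.exp(-((s - centers[..., None]) ** 2) / (2.0 * sigma))
        return v

    if kind == "random":
        # generic data: per-site profile centres drawn uniformly on the
        # activity scale of the patterned branches
        amp = 1.0 if amplitude is None else amplitude
        centers = rng.uniform(0.0, amp, size=(N_POP, n, n))
        values = shifted(centers)
    elif kind == "perturbed_homogeneous":
        amp = 1e-2 if amplitude is None else amplitude
        xi = rng.uniform(-1.0, 1.0, size=(n, n))
        xi -= xi.mean()
        delta = amp * state.mean * xi
        values = np.broadcast_to(shifted(state.phi0 + delta), (N_POP, n, n, sgrid.n_s))
    elif kind == "stripe_band":
        # profile with mean activity ~1 inside the band
        band_prof = np.exp(-((sgrid.centers - 1.0) ** 2) / (2.0 * sigma))
        band_prof /= band_prof.sum() * sgrid.ds
        y = sheet.centers
        in_band = np.abs(y) < band_width / 2.0
        values = np.broadcast_to(
            prof[None, None, None, :], (N_POP, n, n, sgrid.n_s)
        ).copy()
        values[:, :, in_band, :] = band_prof[None, None, None, :]
    else:
        raise ValueError(f"unknown preset {kind!r}; choose from {PRESETS}")

    clipped = values < 0
    if np.any(clipped):
        import warnings

        warnings.warn("perturbation amplitude produced negative values; clipped")
        values = np.maximum(values, 0.0)
    values = values / (values.sum(axis=-1, keepdims=True) * sgrid.ds)
    return PopulationField(
        values=np.ascontiguousarray(values),
        sheet=sheet,
        sgrid=sgrid,
        tau=tau,
        sigma=sigma,
    )


def _orbit_rep(k1: int, k2: int) -> tuple[int, int]:
    """Canonical representative of a mode under the 8-fold dihedral symmetry."""
    a, b = abs(k1), abs(k2)
    return (max(a, b), min(a, b))


def classify_pattern(
    total_mean: np.ndarray,
    *,
    homogeneous_tol: float = 1e-6,
    dominant_frac: float = 0.25,
) -> str:
    """Label a steady pattern from the Fourier signature of <f>(x).

    homogeneous: all nonzero-mode amplitudes below ``homogeneous_tol`` of the
    zero mode.  stripe-like: all dominant modes (>= ``dominant_frac`` of the
    largest) collinear, i.e. a single orientation.  hexagonal-like: at least
    three pairwise non-collinear dominant orbits with comparable amplitude.
    Anything else: other (the eye-like branch lands here).
    """
    fld = np.asarray(total_mean, dtype=float)
    ft = np.fft.fft2(fld)
    n = fld.shape[0]
    amp = np.abs(ft)
    zero = amp[0, 0]
    amp[0, 0] = 0.0
    peak = amp.max()
    if zero <= 0 or peak < homogeneous_tol * zero:
        return "homogeneous"

    k = np.fft.fftfreq(n, d=1.0 / n).astype(int)
    K1, K2 = np.meshgrid(k, k, indexing="ij")
    sel = amp >= dominant_frac * peak
    vecs = {}
    for k1, k2, a in zip(K1[sel], K2[sel], amp[sel]):
        rep = _orbit_rep(int(k1), int(k2))
        vecs[rep] = max(vecs.get(rep, 0.0), float(a))
    # collinearity on the orbit level: orbits (a, 0) are "axial", (a, a)
    # "diagonal"; two modes are collinear iff parallel as integer vectors.
    raw = [(int(a), int(b)) for a, b in zip(K1[sel], K2[sel])]

    def collinear(u, v):
        return u[0] * v[1] - u[1] * v[0] == 0

    groups: list[tuple[int, int]] = []
    for v in raw:
        if not any(collinear(v, g) for g in groups):
            groups.append(v)
    if len(groups) == 1:
        return "stripe-like"
    if len(groups) >= 3:
        amps = sorted(vecs.values(), reverse=True)
        if len(amps) >= 2 and amps[min(2, len(amps) - 1)] >= 0.25 * amps[0]:
            return "hexagonal-like"
    return "other"


@dataclass
class BranchPoint:
    sigma: float
    max_mean: float
    min_mean: float
    converged: bool
    label: str


@dataclass
class BifurcationBranch:
    direction: str  # "l2r" (increasing sigma) or "r2l"
    points: list[BranchPoint] = field(default_factory=list)
    fields: list[PopulationField] = field(default_factory=list)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([p.sigma for p in self.points])

    @property
    def max_means(self) -> np.ndarray:
        return np.array([p.max_mean for p in self.points])

    @property
    def min_means(self) -> np.ndarray:
        return np.array([p.min_mean for p in self.points])

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]


def sweep(
    sigmas,
    preset,
    conn: Connectivity,
    shifts: ShiftSet,
    phi: Modulation,
    B: float,
    sheet: SheetGrid,
    sgrid: SGrid,
    params: SolverParams,
    *,
    seed: int = 0,
    keep_fields: bool = False,
    homogeneous_tol: float = 1e-5,
) -> BifurcationBranch:
    """Continuation sweep over ``sigmas`` (order defines the direction).

    The first noise value is solved from ``preset`` (a preset name or a
    ready-made PopulationField); every subsequent value restarts from the
    previous steady field.  Non-convergence at one sigma is recorded and the
    sweep continues from the last converged field.
    """
    sigmas = list(sigmas)
    if any(s <= 0 for s in sigmas):
        raise ValueError("noise values must be positive")
    direction = "l2r" if sigmas[-1] >= sigmas[0] else "r2l"
    branch = BifurcationBranch(direction=direction)

    if isinstance(preset, PopulationField):
        fld = preset.copy()
    else:
        fld = preset_initial_data(
            preset, sheet, sgrid, phi, conn.W0, B, sigmas[0], seed=seed, tau=params.tau
        )

    for sigma in sigmas:
        fld = PopulationField(
            values=fld.values.copy(),
            sheet=sheet,
            sgrid=sgrid,
            t=0.0,
            tau=params.tau,
            sigma=sigma,
        )
        run = evolve_full(
            fld, conn, shifts, phi, np.full(N_POP, B), params, stop_at_steady=True
        )
        total = run.field.total_mean()
        label = classify_pattern(total, homogeneous_tol=homogeneous_tol)
        branch.points.append(
            BranchPoint(
                sigma=float(sigma),
                max_mean=float(total.max()),
                min_mean=float(total.min()),
                converged=run.converged,
                label=label,
            )
        )
        if keep_fields:
            branch.fields.append(run.field.copy())
        if run.converged:
            fld = run.field
        else:
            import warnings

            warnings.warn(
                f"no steady state within t_end at sigma = {sigma:.4g}; "
                "continuing from the last converged field"
            )
    return branch
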