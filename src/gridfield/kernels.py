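"""Connectivity kernels, modulation functions and the two discretisation grids.

The neural sheet is the flat torus Omega = [-0.5, 0.5)^2: neurons are ordered
by connection strength and wrapped periodically.  Connectivity W is inhibitory
(W <= 0) and even in each coordinate; each of the four orientation populations
sees the kernel shifted by a small vector r^beta = z e_beta along a cardinal
direction, which is what lets a velocity input translate the activity pattern.
The activity variable s >= 0 lives on its own truncated uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SheetGrid",
    "SGrid",
    "Connectivity",
    "Modulation",
    "ShiftSet",
    "eval_connectivity",
    "connectivity_integral",
    "modulation_eval",
    "relu",
    "smooth_product",
    "smooth_sqrt",
    "sigmoid",
    "tanh_bump_kernel",
]

#: Amplitude/steepness of the inhibitory tanh-bump kernel used throughout the
#: numerical experiments: W(|x|) = -0.005*128^2 * (1 + tanh(10 - 50 |x|)),
#: an approximately disk-shaped inhibition of radius 0.2.
TANH_KERNEL_PARAMS = {"amplitude": 0.005 * 128**2, "offset": 10.0, "steepness": 50.0}


@dataclass(frozen=True)
class SheetGrid:
    """Uniform n_x x n_x discretisation of the periodic sheet [-0.5, 0.5)^2."""

    n_x: int

    def __post_init__(self) -> None:
        if self.n_x < 4:
            raise ValueError("SheetGrid requires n_x >= 4")

    @property
    def h(self) -> float:
        return 1.0 / self.n_x

    @property
    def centers(self) -> np.ndarray:
        """Cell centers, strictly inside the domain."""
        return -0.5 + (np.arange(self.n_x) + 0.5) * self.h

    @property
    def displacements(self) -> np.ndarray:
        """Displacement lattice {i*h} in FFT index order, min-imaged to [-0.5, 0.5).

        Differences of cell centers fall on this lattice, so kernels sampled
        here feed directly into circular (torus) convolutions.
        """
        n = self.n_x
        return (((np.arange(n) + n // 2) % n) - n // 2) * self.h

    def wavevectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical wavevector components 2*pi*k for the FFT mode layout."""
        k = np.fft.fftfreq(self.n_x, d=1.0 / self.n_x)  # integer modes
        return 2.0 * np.pi * k, 2.0 * np.pi * k


@dataclass(frozen=True)
class SGrid:
    """Uniform finite-volume grid for the activity variable s in [0, s_max]."""

    s_max: float = 3.0
    n_s: int = 512

    def __post_init__(self) -> None:
        if self.n_s < 8:
            raise ValueError("SGrid requires n_s >= 8")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")

    @property
    def ds(self) -> float:
        return self.s_max / self.n_s

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_s) + 0.5) * self.ds

    @property
    def interior_edges(self) -> np.ndarray:
        """Cell interfaces s = j*ds, j = 1..n_s-1 (no-flux at the two ends)."""
        return np.arange(1, self.n_s) * self.ds


def _min_image(d: np.ndarray) -> np.ndarray:
    return d - np.round(d)


@dataclass(frozen=True)
class Connectivity:
    """Inhibitory connectivity sampled on the displacement lattice of a grid.

    ``samples[i, j]`` is W evaluated at displacement (d_i, d_j) in FFT index
    order, so ``fft2(samples) * h^2`` gives the restricted-domain Fourier
    transform W_hat at integer lattice modes.
    """

    grid: SheetGrid
    samples: np.ndarray
    W0: float
    W0_error: float = 0.0
    func: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    name: str = "tabulated"

    def __post_init__(self) -> None:
        if self.samples.shape != (self.grid.n_x, self.grid.n_x):
            raise ValueError("sample array does not match the sheet grid")

    def spectrum(self) -> np.ndarray:
        """W_hat on the full integer mode lattice (real array, FFT order)."""
        ft = np.fft.fft2(self.samples) * self.grid.h**2
        return ft.real

    def shifted_spectra(self, shifts: "ShiftSet") -> np.ndarray:
        """DFTs of the four shifted kernels W(. - r^beta), shape (4, n, n).

        When the parametric form is known the shifted kernel is re-sampled on
        the displacement lattice, so the spectral convolution agrees with the
        direct quadrature sum to round-off even when z is not a grid
        multiple; tabulated kernels fall back to the exact phase factor
        (band-limited interpolation of the samples).
        """
        key = ("shifted", float(shifts.z))
        cache = object.__getattribute__(self, "_cache") if hasattr(self, "_cache") else None
        if cache is None:
            cache = {}
            object.__setattr__(self, "_cache", cache)
        if key in cache:
            return cache[key]
        n = self.grid.n_x
        h2 = self.grid.h**2
        out = np.empty((4, n, n), dtype=complex)
        if self.func is not None:
            d = self.grid.displacements
            dx, dy = np.meshgrid(d, d, indexing="ij")
            for b, (rx, ry) in enumerate(shifts.vectors):
                r = np.hypot(_min_image(dx - rx), _min_image(dy - ry))
                out[b] = np.fft.fft2(np.asarray(self.func(r), dtype=float)) * h2
        else:
            kx = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / n)
            base = np.fft.fft2(self.samples) * h2
            for b, (rx, ry) in enumerate(shifts.vectors):
                phase = np.exp(-1j * (kx[:, None] * rx + kx[None, :] * ry))
                out[b] = base * phase
        cache[key] = out
        return out


def tanh_bump_kernel(
    amplitude: float = TANH_KERNEL_PARAMS["amplitude"],
    offset: float = TANH_KERNEL_PARAMS["offset"],
    steepness: float = TANH_KERNEL_PARAMS["steepness"],
) -> Callable[[np.ndarray], np.ndarray]:
    """Radial profile -amplitude*(1 + tanh(offset - steepness*r)).

    With the defaults this is the inhibitory kernel of the reference numerical
    experiments: a smoothed disk of inhibition of radius offset/steepness = 0.2.
    """

    def w(r: np.ndarray) -> np.ndarray:
        return -amplitude * (1.0 + np.tanh(offset - steepness * np.asarray(r)))

    return w


_RADIAL_KERNELS: dict[str, Callable[..., Callable[[np.ndarray], np.ndarray]]] = {
    "tanh_bump": tanh_bump_kernel,
    "constant": lambda value=-1.0: (lambda r: np.full_like(np.asarray(r, dtype=float), value)),
    "ball": lambda radius=0.2, depth=-1.0: (
        lambda r: np.where(np.asarray(r) <= radius, depth, 0.0)
    ),
}


def eval_connectivity(
    kernel: str | Callable[[np.ndarray], np.ndarray] | np.ndarray,
    grid: SheetGrid,
    *,
    params: dict | None = None,
    tol_positive: float = 1e-12,
    tol_asym: float = 1e-12,
) -> Connectivity:
    """Sample a connectivity kernel on the displacement lattice of ``grid``.

    ``kernel`` may be the name of a built-in radial form ("tanh_bump",
    "constant", "ball"), a radial callable W(r), or a pre-tabulated (n, n)
    array in FFT displacement order.  Periodic (min-image) distance is used so
    the samples respect the torus geometry.  Kernels taking positive values
    violate the inhibitory assumption and are rejected; tabulated kernels with
    asymmetry above ``tol_asym`` are rejected, smaller asymmetries are averaged
    out.
    """
    params = dict(params or {})
    name = "tabulated"
    func = None

    if isinstance(kernel, str):
        if kernel not in _RADIAL_KERNELS:
            raise ValueError(f"unknown kernel kind {kernel!r}")
        radial = _RADIAL_KERNELS[kernel](**params)
        name = kernel
        func = radial
    elif callable(kernel):
        radial = kernel
        name = getattr(kernel, "__name__", "callable")
        func = radial
    else:
        samples = np.asarray(kernel, dtype=float)
        radial = None

    if radial is not None:
        d = grid.displacements
        dx, dy = np.meshgrid(d, d, indexing="ij")
        samples = np.asarray(radial(np.hypot(_min_image(dx), _min_image(dy))), dtype=float)

    # Evenness: index i <-> -i mod n in each axis.
    reflected = 0.25 * (
        samples
        + np.flip(np.roll(samples, -1, axis=0), axis=0)
        + np.flip(np.roll(samples, -1, axis=1), axis=1)
        + np.flip(np.flip(np.roll(np.roll(samples, -1, 0), -1, 1), 0), 1)
    )
    asym = np.max(np.abs(samples - reflected))
    scale = max(np.max(np.abs(samples)), 1.0)
    if asym > tol_asym * scale:
        raise ValueError(
            f"kernel is not even in each coordinate (asymmetry {asym:.3e})"
        )
    samples = reflected

    if np.max(samples) > tol_positive * scale:
        raise ValueError(
            "kernel takes positive values; the connectivity must be inhibitory (W <= 0)"
        )
    samples = np.minimum(samples, 0.0)

    W0 = float(samples.sum() * grid.h**2)

    # One refinement level for a quadrature error estimate (callable kernels only).
    err = 0.0
    if func is not None:
        fine = SheetGrid(2 * grid.n_x)
        d = fine.displacements
        dx, dy = np.meshgrid(d, d, indexing="ij")
        W0_fine = float(
            np.minimum(np.asarray(func(np.hypot(_min_image(dx), _min_image(dy)))), 0.0).sum()
            * fine.h**2
        )
        err = abs(W0_fine - W0)

    return Connectivity(grid=grid, samples=samples, W0=W0, W0_error=err, func=func, name=name)


def connectivity_integral(conn: Connectivity) -> float:
    """The integral W0 = int_Omega W dx (midpoint rule on the native grid)."""
    return conn.W0


# ---------------------------------------------------------------------------
# Modulation (activation) functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modulation:
    """Firing-rate modulation Phi together with its first derivative."""

    kind: str
    eps: float = 0.0
    slope: float = 0.0

    def __call__(self, x):
        return self.value(x)

    def value(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        elif self.kind == "smooth_product_eps":
            out = 0.5 * x * (1.0 + x / np.sqrt(x * x + self.eps))
        elif self.kind == "smooth_sqrt_eps":
            out = 0.5 * (x + np.sqrt(x * x + self.eps))
        elif self.kind == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-self.slope * x))
        else:  # pragma: no cover - guarded by factories
            raise ValueError(f"unknown modulation kind {self.kind!r}")
        return out if out.ndim else float(out)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "relu":
            out = np.where(x > 0.0, 1.0, 0.0)
        elif self.kind == "smooth_product_eps":
            u = np.sqrt(x * x + self.eps)
            out = 0.5 * (1.0 + x / u) + 0.5 * x * self.eps / u**3
        elif self.kind == "smooth_sqrt_eps":
            out = 0.5 * (1.0 + x / np.sqrt(x * x + self.eps))
        elif self.kind == "sigmoid":
            p = 1.0 / (1.0 + np.exp(-self.slope * x))
            out = self.slope * p * (1.0 - p)
        else:  # pragma: no cover
            raise ValueError(f"unknown modulation kind {self.kind!r}")
        return out if out.ndim else float(out)


def relu() -> Modulation:
    return Modulation(kind="relu")


def smooth_product(eps: float = 0.01) -> Modulation:
    """Smooth approximation 0.5*x*(1 + x/sqrt(x^2 + eps)) of the ReLU."""
    if eps <= 0:
        raise ValueError("eps must be positive for the smooth variants")
    return Modulation(kind="smooth_product_eps", eps=eps)


def smooth_sqrt(eps: float = 0.01) -> Modulation:
    """Strictly positive smoothing 0.5*(x + sqrt(x^2 + eps)) of the ReLU."""
    if eps <= 0:
        raise ValueError("eps must be positive for the smooth variants")
    return Modulation(kind="smooth_sqrt_eps", eps=eps)


def sigmoid(slope: float = 15.0) -> Modulation:
    return Modulation(kind="sigmoid", slope=slope)


def modulation_eval(phi: Modulation, x) -> tuple:
    """Evaluate a modulation function and its analytic first derivative."""
    return phi.value(x), phi.derivative(x)


# ---------------------------------------------------------------------------
# Orientation shifts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftSet:
    """Equal-length cardinal shifts r^beta = z e_beta.

    beta = 1..4 corresponds to north, west, south, east with preferred
    headings pi/2, pi, 3*pi/2, 2*pi.  The default z = 2/128 is two cells of a
    128-point sheet, matching the grid implied by the reference kernel's
    128^2 amplitude factor.
    """

    z: float = 2.0 / 128.0

    @property
    def vectors(self) -> np.ndarray:
        z = self.z
        return np.array([[0.0, z], [-z, 0.0], [0.0, -z], [z, 0.0]])

    @property
    def angles(self) -> np.ndarray:
        return np.array([np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi])
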