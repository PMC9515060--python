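"""Velocity-coupled input drive, trajectories, and single-cell firing fields.

An animal's movement enters the network through the per-orientation input

    B^beta(t) = B + alpha v(t) cos(theta(t) - theta^beta),

which biases the four populations so the sheet pattern translates with the
animal.  Tracking one sheet location while feeding a trajectory through the
system, and marking the animal's position whenever that neuron's firing rate
is positive, paints the neuron's firing field in physical space — hexagonal
for low noise, progressively delocalised as the noise grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import Connectivity, Modulation, ShiftSet
from .solver import (
    N_POP,
    PopulationField,
    SolverParams,
    _check_dt_accuracy,
    firing_rate_field,
    fokker_planck_step,
)

__all__ = [
    "Trajectory",
    "DriveParams",
    "input_drive",
    "synthetic_trajectory",
    "firing_field",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class DriveParams:
    """Constant input B, velocity gain alpha and the preferred headings."""

    B: float = 3.0
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    @property
    def preferred_angles(self) -> np.ndarray:
        return np.array([np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi])


def input_drive(params: DriveParams, v, theta) -> np.ndarray:
    """B^beta = B + alpha v cos(theta - theta^beta) for beta = 1..4.

    Scalars give a four-vector; arrays of shape (T,) give (4, T).  The four
    cardinal cosines cancel pairwise, so the drives always sum to 4B.
    """
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ang = params.preferred_angles.reshape((N_POP,) + (1,) * v.ndim)
    return params.B + params.alpha * v * np.cos(theta - ang)


@dataclass
class Trajectory:
    """Timestamped positions in a circular arena (seconds, centimetres)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_radius: float = 80.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.arena_radius * (1 + 1e-9)):
            raise ValueError("positions outside the arena")

    def velocity(self, smooth_window: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Speed v(t) (cm/s) and heading theta(t) by central differences.

        ``smooth_window`` applies a moving average to the velocity components
        before extracting speed and heading (odd window, 1 = no smoothing).
        """
        if len(self.t) < 2:
            raise ValueError("need at least two samples for a velocity")
        vx = np.gradient(self.x, self.t)
        vy = np.gradient(self.y, self.t)
        if smooth_window > 1:
            kern = np.ones(smooth_window) / smooth_window
            vx = np.convolve(vx, kern, mode="same")
            vy = np.convolve(vy, kern, mode="same")
        return np.hypot(vx, vy), np.arctan2(vy, vx)

    def resample(self, times: np.ndarray) -> "Trajectory":
        times = np.asarray(times, dtype=float)
        return Trajectory(
            t=times,
            x=np.interp(times, self.t, self.x),
            y=np.interp(times, self.t, self.y),
            arena_radius=self.arena_radius,
        )


def synthetic_trajectory(
    arena_radius: float = 80.0,
    duration: float = 300.0,
    mean_speed: float = 15.0,
    *,
    dt: float = 0.02,
    seed: int = 0,
    heading_relax: float = 1.0,
    speed_rel_sd: float = 0.15,
) -> Trajectory:
    """Smooth random foraging path in a circular arena.

    The heading performs an Ornstein-Uhlenbeck-style random walk and the
    speed fluctuates around ``mean_speed`` (relative s.d. ``speed_rel_sd``,
    clipped at zero); the boundary reflects the heading inward.  Stands in
    for recorded rodent position data, which is not bundled.
    """
    if arena_radius <= 0:
        raise ValueError("arena radius must be positive")
    rng = np.random.default_rng(seed)
    n = max(int(round(duration / dt)), 0) + 1
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    x[0] = y[0] = 0.0
    theta = rng.uniform(0, 2 * np.pi)
    speed = mean_speed
    for i in range(1, n):
        theta += np.sqrt(2.0 * heading_relax * dt) * rng.standard_normal()
        speed += (mean_speed - speed) * dt + (
            mean_speed * speed_rel_sd * np.sqrt(2.0 * dt) * rng.standard_normal()
        )
        speed = max(speed, 0.0)
        nx = x[i - 1] + speed * np.cos(theta) * dt
        ny = y[i - 1] + speed * np.sin(theta) * dt
        r = np.hypot(nx, ny)
        if r > arena_radius:
            # reflect the heading about the boundary tangent and step inward
            phi = np.arctan2(ny, nx)
            theta = 2 * phi + np.pi - theta
            nx = x[i - 1] + speed * np.cos(theta) * dt
            ny = y[i - 1] + speed * np.sin(theta) * dt
            r = np.hypot(nx, ny)
            if r > arena_radius:  # corner case: pull to the boundary
                nx, ny = nx * arena_radius / r, ny * arena_radius / r
        x[i], y[i] = nx, ny
    return Trajectory(t=t, x=x, y=y, arena_radius=arena_radius)


@dataclass
class FiringFieldResult:
    """Positions (cm) at which the tracked neuron fired, with timestamps."""

    times: np.ndarray
    positions: np.ndarray  # (n_fired, 2)
    rates: np.ndarray  # tracked-neuron rate at every sample


def firing_field(
    fld: PopulationField,
    traj: Trajectory,
    conn: Connectivity,
    shifts: ShiftSet,
    phi: Modulation,
    drive_params: DriveParams,
    params: SolverParams,
    *,
    tracked_cell: tuple[int, int] = None,
    tracked_beta: int = 0,
    threshold: float = 0.0,
    sample_every: float = 0.05,
    time_scale: float = 1.0,
) -> FiringFieldResult:
    """Couple a trajectory into the field and record the firing positions.

    ``fld`` should already hold a stabilised (patterned) steady state obtained
    with alpha = 0.  The trajectory is resampled to the PDE step by linear
    interpolation; one second of trajectory time advances the field by
    ``time_scale`` units of tau.  The tracked neuron fires at a sample when
    its rate exceeds ``threshold`` (default exactly 0, meaningful for
    ReLU-type modulations; strictly positive sigmoids fire everywhere).
    """
    n = fld.sheet.n_x
    if tracked_cell is None:
        tracked_cell = (n // 2, n // 2)  # sheet position ~ (0, 0)
    ix, iy = tracked_cell
    if not (0 <= ix < n and 0 <= iy < n):
        raise ValueError("tracked sheet position outside the grid")
    if len(traj.t) < 2:
        return FiringFieldResult(
            times=np.empty(0), positions=np.empty((0, 2)), rates=np.empty(0)
        )

    dt = params.dt if params.dt is not None else 0.01
    _check_dt_accuracy(dt, fld.tau)
    t_pde_end = (traj.t[-1] - traj.t[0]) * time_scale
    n_steps = int(np.floor(t_pde_end / dt))
    pde_times = np.arange(n_steps + 1) * dt
    wall_times = traj.t[0] + pde_times / time_scale
    rs = traj.resample(wall_times)
    v, theta = rs.velocity()

    f = fld.values.copy()
    sample_stride = max(1, int(round(sample_every / dt)))
    fire_t, fire_xy, rate_trace = [], [], []
    for i in range(n_steps + 1):
        means = (f @ fld.sgrid.centers) * fld.sgrid.ds
        drive = input_drive(drive_params, v[i], theta[i])
        rates = firing_rate_field(means, conn, shifts, phi, drive)
        if i % sample_stride == 0:
            r = float(rates[tracked_beta, ix, iy])
            rate_trace.append(r)
            if r > threshold:
                fire_t.append(wall_times[i])
                fire_xy.append((rs.x[i], rs.y[i]))
        if i < n_steps:
            f = fokker_planck_step(f, rates, fld.sgrid, fld.sigma, fld.tau, dt)
    return FiringFieldResult(
        times=np.asarray(fire_t),
        positions=np.asarray(fire_xy).reshape(-1, 2),
        rates=np.asarray(rate_trace),
    )


def read_trajectory_csv(path, arena_radius: float = 80.0) -> Trajectory:
    """Read a trajectory table with columns t, x, y (seconds, centimetres)."""
    df = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    return Trajectory(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        arena_radius=arena_radius,
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)
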