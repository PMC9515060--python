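"""Configuration, reproducibility metadata and programmatic run entry point.

A run is described by a TOML document with blocks ``model`` (kernel,
modulation, shift length z, input B, velocity gain alpha, tau, sigma),
``grids``, ``solver``, ``sweep`` and ``trajectory``, plus a top-level
``seed`` and ``outdir``.  Unknown keys are rejected with their full path.
Every invocation writes a JSON manifest listing the produced files with
content hashes and the configuration echo, so downstream steps can refuse
mismatched inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bifurcation, navigation, stability
from .kernels import (
    Modulation,
    SGrid,
    SheetGrid,
    ShiftSet,
    eval_connectivity,
    relu,
    sigmoid,
    smooth_product,
    smooth_sqrt,
)
from .microscopic import empirical_moments, simulate_meanfield
from .solver import SolverParams, evolve_homogeneous
from .stationary import solve_consistency, stationary_density

__all__ = ["RunConfig", "ConfigError", "load_config", "run"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


_SCHEMA = {
    "seed": int,
    "outdir": str,
    "model": {
        "kernel": {"kind": str, "amplitude": float, "offset": float,
                   "steepness": float, "radius": float, "depth": float,
                   "value": float},
        "modulation": {"kind": str, "eps": float, "slope": float},
        "z": float,
        "B": float,
        "alpha": float,
        "tau": float,
        "sigma": float,
    },
    "grids": {"n_x": int, "s_max": float, "n_s": int},
    "solver": {"dt": float, "t_end": float, "steady_tol": float,
               "check_every": float},
    "sweep": {"sigma_start": float, "sigma_end": float, "n_steps": int,
              "preset": str},
    "trajectory": {"file": str, "arena_radius": float, "duration": float,
                   "mean_speed": float, "time_scale": float},
}


def _validate(node, schema, path=""):
    if not isinstance(node, dict):
        raise ConfigError(f"expected a table at {path or '<root>'}")
    for key, val in node.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown configuration key {here!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            _validate(val, expect, here)
        elif expect is float:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ConfigError(f"{here!r} must be a number")
        elif not isinstance(val, expect) or isinstance(val, bool) and expect is int:
            raise ConfigError(f"{here!r} must be of type {expect.__name__}")


@dataclass
class RunConfig:
    """Validated configuration with the raw document kept for echoing."""

    raw: dict
    text: str = ""

    def __post_init__(self) -> None:
        _validate(self.raw, _SCHEMA)

    # -- required accessors -------------------------------------------------
    def require(self, *path):
        node = self.raw
        for p in path:
            if not isinstance(node, dict) or p not in node:
                raise ConfigError(f"missing required key {'.'.join(path)!r}")
            node = node[p]
        return node

    def get(self, *path, default=None):
        node = self.raw
        for p in path:
            if not isinstance(node, dict) or p not in node:
                return default
            node = node[p]
        return node

    # -- model builders ------------------------------------------------------
    def sheet(self) -> SheetGrid:
        return SheetGrid(int(self.get("grids", "n_x", default=32)))

    def sgrid(self) -> SGrid:
        return SGrid(
            s_max=float(self.get("grids", "s_max", default=3.0)),
            n_s=int(self.get("grids", "n_s", default=64)),
        )

    def modulation(self) -> Modulation:
        kind = self.get("model", "modulation", "kind", default="smooth_product_eps")
        if kind == "relu":
            return relu()
        if kind == "smooth_product_eps":
            return smooth_product(float(self.get("model", "modulation", "eps", default=0.01)))
        if kind == "smooth_sqrt_eps":
            return smooth_sqrt(float(self.get("model", "modulation", "eps", default=0.01)))
        if kind == "sigmoid":
            return sigmoid(float(self.get("model", "modulation", "slope", default=15.0)))
        raise ConfigError(f"unknown modulation kind {kind!r}")

    def connectivity(self, grid: SheetGrid | None = None):
        grid = grid or self.sheet()
        kern = dict(self.get("model", "kernel", default={"kind": "tanh_bump"}))
        kind = kern.pop("kind", "tanh_bump")
        return eval_connectivity(kind, grid, params=kern)

    def shifts(self) -> ShiftSet:
        return ShiftSet(float(self.get("model", "z", default=2.0 / 128.0)))

    def solver_params(self) -> SolverParams:
        return SolverParams(
            tau=float(self.get("model", "tau", default=1.0)),
            dt=self.get("solver", "dt", default=None),
            t_end=float(self.get("solver", "t_end", default=50.0)),
            steady_tol=float(self.get("solver", "steady_tol", default=1e-6)),
            check_every=float(self.get("solver", "check_every", default=1.0)),
            seed=int(self.get("seed", default=0)),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    return RunConfig(raw=tomllib.loads(text), text=text)


def _write_manifest(outdir: Path, cfg: RunConfig, files: list[Path]) -> Path:
    entries = []
    for f in files:
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        entries.append({"path": f.name, "sha256": digest})
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": cfg.raw,
        "files": entries,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mf = outdir / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2))
    return mf


def run(cfg: RunConfig, subcommand: str, outdir=None) -> dict:
    """Execute one subcommand, write its artifacts and return a summary."""
    outdir = Path(outdir or cfg.get("outdir", default="out"))
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    summary: dict = {"subcommand": subcommand, "config_hash": cfg.config_hash()}

    phi = cfg.modulation()
    B = float(cfg.require("model", "B"))
    sigma = cfg.get("model", "sigma")
    if sigma is None and subcommand != "sweep":
        raise ConfigError("missing required key 'model.sigma'")

    if subcommand == "stationary":
        conn = cfg.connectivity()
        state = solve_consistency(phi, conn.W0, B, float(sigma))
        df = pd.DataFrame(
            [{
                "sigma": state.sigma, "phi0": state.phi0, "Z": state.Z,
                "mean": state.mean, "M_inf": state.M_inf,
            }]
        )
        p = outdir / "stationary.csv"
        df.to_csv(p, index=False)
        files.append(p)
        summary.update(df.iloc[0].to_dict())

    elif subcommand == "stability":
        conn = cfg.connectivity()
        shifts = cfg.shifts()
        state = solve_consistency(phi, conn.W0, B, float(sigma))
        report = stability.lattice_scan(state, phi, conn, shifts, K=8)
        df = pd.DataFrame({
            "k1": report.k1.ravel(), "k2": report.k2.ravel(),
            "W_hat": report.W_hat.ravel(), "cos_sum": report.cos_sum.ravel(),
            "F": report.F.ravel(), "ratio": report.ratio.ravel(),
        })
        p = outdir / "stability_lattice.csv"
        df.to_csv(p, index=False)
        files.append(p)
        sigma_c = stability.critical_sigma(phi, conn, shifts, B)
        summary.update({
            "max_F": report.max_F,
            "dominant_modes": report.dominant_modes,
            "stable_zero_noise": report.stable_zero_noise,
            "stable_noisy": report.stable_noisy,
            "sigma_c": sigma_c,
        })
        p = outdir / "stability_summary.json"
        p.write_text(json.dumps(summary, indent=2, default=str))
        files.append(p)

    elif subcommand == "simulate":
        conn = cfg.connectivity()
        sgrid = cfg.sgrid()
        params = cfg.solver_params()
        state = solve_consistency(phi, conn.W0, B, float(sigma))
        f0 = stationary_density(state, sgrid)
        f0 = f0 / (f0.sum() * sgrid.ds)
        runout = evolve_homogeneous(f0, phi, conn.W0, B, float(sigma), sgrid, params)
        df = pd.DataFrame({"t": runout.times, "mean": runout.means})
        p = outdir / "homogeneous_timeseries.csv"
        df.to_csv(p, index=False)
        files.append(p)
        summary["final_mean"] = float(runout.means[-1])

    elif subcommand == "bifurcate":
        conn = cfg.connectivity()
        shifts = cfg.shifts()
        sgrid = cfg.sgrid()
        params = cfg.solver_params()
        s0 = float(cfg.require("sweep", "sigma_start"))
        s1 = float(cfg.require("sweep", "sigma_end"))
        nstep = int(cfg.get("sweep", "n_steps", default=8))
        preset = cfg.get("sweep", "preset", default="random")
        sigmas = np.linspace(s0, s1, nstep)
        branch = bifurcation.sweep(
            sigmas, preset, conn, shifts, phi, B, cfg.sheet(), sgrid, params,
            seed=int(cfg.get("seed", default=0)),
        )
        df = pd.DataFrame({
            "direction": branch.direction,
            "sigma": branch.sigmas,
            "max": branch.max_means,
            "min": branch.min_means,
            "converged": [p_.converged for p_ in branch.points],
            "label": branch.labels,
        })
        p = outdir / f"branch_{branch.direction}.csv"
        df.to_csv(p, index=False)
        files.append(p)
        summary["labels"] = branch.labels

    elif subcommand == "navigate":
        conn = cfg.connectivity()
        shifts = cfg.shifts()
        sgrid = cfg.sgrid()
        params = cfg.solver_params()
        traj_file = cfg.get("trajectory", "file")
        if traj_file:
            traj = navigation.read_trajectory_csv(
                traj_file, float(cfg.get("trajectory", "arena_radius", default=80.0))
            )
        else:
            traj = navigation.synthetic_trajectory(
                arena_radius=float(cfg.get("trajectory", "arena_radius", default=80.0)),
                duration=float(cfg.get("trajectory", "duration", default=60.0)),
                mean_speed=float(cfg.get("trajectory", "mean_speed", default=15.0)),
                seed=int(cfg.get("seed", default=0)),
            )
        fld = bifurcation.preset_initial_data(
            "random", cfg.sheet(), sgrid, phi, conn.W0, B, float(sigma),
            seed=int(cfg.get("seed", default=0)), tau=params.tau,
        )
        from .solver import evolve_full

        settle = evolve_full(
            fld, conn, shifts, phi, np.full(4, B), params, stop_at_steady=True
        )
        result = navigation.firing_field(
            settle.field, traj, conn, shifts, phi,
            navigation.DriveParams(B=B, alpha=float(cfg.get("model", "alpha", default=0.3))),
            params,
            time_scale=float(cfg.get("trajectory", "time_scale", default=1.0)),
        )
        df = pd.DataFrame({
            "t": result.times,
            "x": result.positions[:, 0],
            "y": result.positions[:, 1],
        })
        p = outdir / "firing_positions.csv"
        df.to_csv(p, index=False)
        files.append(p)
        summary["n_firings"] = int(len(result.times))

    elif subcommand == "particles":
        conn = cfg.connectivity()
        params = cfg.solver_params()
        ens = simulate_meanfield(
            M=10_000, phi=phi, W0=conn.W0, B=B, sigma=float(sigma),
            t_end=params.t_end, seed=int(cfg.get("seed", default=0)),
        )
        mean, var, sem = empirical_moments(ens)
        df = pd.DataFrame([{"mean": mean, "var": var, "sem": sem, "t": ens.t}])
        p = outdir / "particles.csv"
        df.to_csv(p, index=False)
        files.append(p)
        summary.update({"mean": float(mean), "sem": float(sem)})

    else:
        raise ConfigError(f"unknown subcommand {subcommand!r}")

    files.append(_write_manifest(outdir, cfg, files))
    summary["files"] = [str(f) for f in files]
    return summary
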