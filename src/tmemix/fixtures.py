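"""Deterministic generators of small test inputs.

Every fixture is fully determined by its spec (name, seed, geometry,
overrides): field snapshots for the spatial operators, toy states for
the friction matrix, and tight-tolerance reference trajectories of the
scenario presets used as regression baselines.  Baselines are stored as
CSV next to a manifest carrying a content hash; regeneration must
reproduce the stored hash or the mismatch is surfaced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tmemix.grid import Grid2D
from tmemix.spatial import FieldState, SpatialParams, chemical_field, _tanh_disk
from tmemix import ode as _ode

__all__ = ["FixtureSpec", "make_field_fixture", "reference_ode_run"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for a fixture."""

    name: str
    seed: int = 0
    geometry: tuple[tuple[str, float], ...] = ()
    overrides: tuple[tuple[str, float], ...] = ()

    def rng(self) -> np.random.Generator:
        key = hashlib.sha256(
            f"{self.name}:{self.seed}".encode()
        ).digest()[:8]
        return np.random.default_rng(int.from_bytes(key, "little"))


def make_field_fixture(
    kind: str,
    grid: Grid2D,
    value: float = 0.5,
    seed: int = 0,
    radius: float | None = None,
    width: float = 10.0,
    offset: float | None = None,
    species: str = "c",
    params: SpatialParams | None = None,
) -> FieldState:
    """Deterministic FieldState pattern: uniform, disk, two-disks or gradient.

    ``value`` is the plateau mass fraction of the chosen species; the
    chemoattractant is initialized to its quasi-static profile.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("value must lie in [0, 1]")
    params = params or SpatialParams()
    idx = {"c": 0, "t": 1, "na": 2, "a": 3}[species]
    state = FieldState.zeros(grid)
    cx, cy = grid.lx / 2.0, grid.ly / 2.0
    if radius is None:
        radius = 0.15 * min(grid.lx, grid.ly)
    if offset is None:
        offset = 2.0 * radius
    if kind == "uniform":
        state.phi[idx][:] = value
    elif kind == "disk":
        if radius + 2 * width > min(cx, cy):
            raise ValueError("disk does not fit in the grid")
        state.phi[idx] = _tanh_disk(grid, (cx, cy), radius, width, value)
    elif kind == "two-disks":
        if offset + radius + 2 * width > min(cx, cy):
            raise ValueError("disks do not fit in the grid")
        state.phi[idx] = np.minimum(
            _tanh_disk(grid, (cx - offset, cy), radius, width, value)
            + _tanh_disk(grid, (cx + offset, cy), radius, width, value),
            value,
        )
    elif kind == "gradient":
        x, _ = grid.coords()
        state.phi[idx] = value * x / grid.lx
    elif kind == "random-smooth":
        rng = FixtureSpec(kind, seed).rng()
        raw = rng.random(grid.shape)
        for _ in range(12):  # heavy smoothing: keeps gradients mild
            padded = np.pad(raw, 1, mode="edge")
            raw = (
                padded[:-2, 1:-1]
                + padded[2:, 1:-1]
                + padded[1:-1, :-2]
                + padded[1:-1, 2:]
                + 4 * raw
            ) / 8.0
        raw = (raw - raw.min()) / max(raw.max() - raw.min(), 1e-300)
        state.phi[idx] = 0.05 + value * raw
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    state.c = chemical_field(state.phi[0], params, grid)
    return state


def make_mixture_fixture(
    grid: Grid2D, seed: int = 0, scale: float = 0.2
) -> FieldState:
    """Smooth random state populating all four species (sum well below 1)."""
    rng = FixtureSpec("mixture", seed).rng()
    state = FieldState.zeros(grid)
    params = SpatialParams()
    for i in range(4):
        raw = rng.random(grid.shape)
        for _ in range(12):
            padded = np.pad(raw, 1, mode="edge")
            raw = (
                padded[:-2, 1:-1]
                + padded[2:, 1:-1]
                + padded[1:-1, :-2]
                + padded[1:-1, 2:]
                + 4 * raw
            ) / 8.0
        raw = (raw - raw.min()) / max(raw.max() - raw.min(), 1e-300)
        state.phi[i] = 0.02 + scale * raw
    state.c = chemical_field(state.phi[0], params, grid)
    return state


def _trajectory_hash(traj: _ode.Trajectory) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(traj.times, 12)).tobytes())
    h.update(np.ascontiguousarray(np.round(traj.states, 12)).tobytes())
    return h.hexdigest()


def reference_ode_run(
    preset: str,
    directory: Path | str | None = None,
    t_end: float = 100.0,
    n_out: int = 201,
) -> _ode.Trajectory:
    """Tight-tolerance baseline trajectory for a scenario preset.

    With ``directory`` given, the trajectory is stored as CSV with a
    manifest (preset, settings, content hash); a later call regenerates
    it and raises if the regenerated hash disagrees with the manifest —
    a regression in the integrator or the preset tables.
    """
    params = _ode.scenario_params(preset)
    traj = _ode.simulate(
        _ode.CellState(0.01, 0.01, 0.01, 0.01),
        params,
        t_end=t_end,
        n_out=n_out,
        rtol=1e-11,
        atol=1e-14,
    )
    if directory is None:
        return traj
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / f"{preset}.manifest.json"
    csv_path = directory / f"{preset}.csv"
    digest = _trajectory_hash(traj)
    manifest = {
        "preset": preset,
        "t_end": t_end,
        "n_out": n_out,
        "hash": digest,
    }
    if manifest_path.exists():
        stored = json.loads(manifest_path.read_text())
        if stored["hash"] != digest:
            raise RuntimeError(
                f"baseline hash mismatch for preset {preset!r}: "
                f"stored {stored['hash'][:12]}…, regenerated {digest[:12]}…"
            )
    else:
        traj.to_csv(csv_path)
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return traj
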