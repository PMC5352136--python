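"""Langevin dynamics co-evolving RNA atoms, explicit Mg2+ and condensation
variables, with system setup at a target Mg2+ concentration.

The integrator is the BAOAB splitting of Langevin dynamics, which gives
accurate configurational sampling at practical timesteps.  The condensation
fractions theta_i are propagated as fictitious-mass degrees of freedom with
their own friction and are re-clamped to [0, 1] after every position update.
Mg2+ ions are confined by reflecting walls of the cubic box, which keeps the
nominal concentration fixed; the RNA itself is never wrapped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import h5py
import numpy as np

from .energy import (EnergyParams, Forces, SystemState, energy_and_forces)
from .structure import NativeTopology

__all__ = ["SimulationConfig", "Trajectory", "LangevinIntegrator",
           "setup_system", "mg_count", "step", "run"]

_MM_TO_DENSITY = 6.02214076e-7  # ions per A^3 for 1 mM


@dataclass
class SimulationConfig:
    timestep: float = 0.0005        # reduced time
    n_steps: int = 1000
    save_interval: int = 100
    temperature: float = 1.0        # reduced
    gamma_atoms: float = 1.0        # friction, 1/time
    gamma_mg: float = 1.0
    gamma_theta: float = 10.0
    mass_atom: float = 1.0
    mass_mg: float = 1.0
    mass_theta: float = 0.05
    box: float = 200.0              # cubic side, A
    c_mg_mm: float = 0.0
    c_mono_mm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.c_mg_mm < 0:
            raise ValueError("Mg concentration must be non-negative")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def mg_count(c_mg_mm: float, box: float) -> int:
    """Number of explicit Mg2+ at concentration ``c_mg_mm`` in a cubic box."""
    return int(round(c_mg_mm * _MM_TO_DENSITY * float(box) ** 3))


def setup_system(topo: NativeTopology, config: SimulationConfig,
                 params: EnergyParams | None = None) -> SystemState:
    """Initial state: native RNA at the box centre, Mg2+ placed uniformly at
    random outside hard cores, theta at the Manning baseline,
    Maxwell-Boltzmann velocities."""
    params = params or EnergyParams(c_mono_mm=config.c_mono_mm)
    rng = np.random.default_rng(config.seed)
    coords = topo.native_coords.copy()
    if len(coords) != topo.n_atoms:
        raise ValueError("topology lacks native coordinates")
    center = coords.mean(axis=0)
    coords += (np.full(3, config.box / 2.0) - center)
    span = coords.max(axis=0) - coords.min(axis=0)
    if np.any(span > config.box):
        raise ValueError("box too small to contain the RNA")
    if np.any(coords < 0) or np.any(coords > config.box):
        raise ValueError("RNA does not fit in the box")

    n_mg = mg_count(config.c_mg_mm, config.box)
    min_sep_atom = params.r_mg + 0.5 * params.sigma_rep
    min_sep_mg = 2.0 * params.r_mg
    mg = np.empty((0, 3))
    if n_mg:
        placed = []
        attempts = 0
        while len(placed) < n_mg:
            attempts += 1
            if attempts > 200 * n_mg + 1000:
                raise ValueError("box too small to place all Mg2+ ions")
            cand = rng.uniform(0.0, config.box, size=3)
            d_atom = np.min(np.linalg.norm(coords - cand, axis=1))
            if d_atom < min_sep_atom:
                continue
            if placed and np.min(np.linalg.norm(
                    np.asarray(placed) - cand, axis=1)) < min_sep_mg:
                continue
            placed.append(cand)
        mg = np.asarray(placed)

    n_p = len(topo.phosphate_idx)
    theta = np.full(n_p, params.theta_ref)
    T = config.temperature
    state = SystemState(
        coords=coords, mg=mg, theta=theta,
        v_coords=rng.normal(0.0, np.sqrt(T / config.mass_atom),
                            size=coords.shape),
        v_mg=rng.normal(0.0, np.sqrt(T / config.mass_mg), size=mg.shape),
        v_theta=rng.normal(0.0, np.sqrt(T / config.mass_theta), size=n_p),
        box=config.box, temperature=T)
    return state


@dataclass
class Trajectory:
    """In-memory trajectory; HDF5 round-trip for persistence."""

    coords: np.ndarray              # (F, N, 3)
    mg: np.ndarray                  # (F, M, 3)
    theta: np.ndarray               # (F, P)
    time: np.ndarray                # (F,)
    energy: np.ndarray              # (F,)
    seed: int = 0
    config_hash: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def frame(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.coords[k], self.mg[k], self.theta[k]

    def save_h5(self, path: str) -> None:
        with h5py.File(path, "w") as h:
            for name in ("coords", "mg", "theta", "time", "energy"):
                h.create_dataset(name, data=getattr(self, name))
            h.attrs["seed"] = self.seed
            h.attrs["config_hash"] = self.config_hash

    @classmethod
    def load_h5(cls, path: str) -> "Trajectory":
        with h5py.File(path, "r") as h:
            return cls(coords=h["coords"][...], mg=h["mg"][...],
                       theta=h["theta"][...], time=h["time"][...],
                       energy=h["energy"][...],
                       seed=int(h.attrs.get("seed", 0)),
                       config_hash=str(h.attrs.get("config_hash", "")))


class LangevinIntegrator:
    """BAOAB Langevin integrator over atoms, Mg2+ ions and theta variables.

    ``bias`` is an optional callable ``bias(state, forces) -> float`` that
    returns a bias energy and accumulates its forces in place (used for
    umbrella sampling).
    """

    def __init__(self, state: SystemState, topo: NativeTopology,
                 params: EnergyParams, config: SimulationConfig,
                 bias=None):
        self.state = state
        self.topo = topo
        self.params = params
        self.config = config
        self.bias = bias
        self.rng = np.random.default_rng(config.seed)
        dt = config.timestep
        self._c1 = {k: np.exp(-g * dt) for k, g in
                    (("atoms", config.gamma_atoms), ("mg", config.gamma_mg),
                     ("theta", config.gamma_theta))}
        self._c2 = {k: np.sqrt(1.0 - c * c) for k, c in self._c1.items()}
        self.potential, self.forces = self._eval()

    def _eval(self) -> tuple[float, Forces]:
        e, f = energy_and_forces(self.state, self.topo, self.params)
        if self.bias is not None:
            e += self.bias(self.state, f)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite potential energy")
        for arr, label in ((f.atoms, "atom"), (f.mg, "Mg"), (f.theta, "theta")):
            if arr.size and not np.all(np.isfinite(arr)):
                worst = int(np.argmax(~np.isfinite(
                    np.atleast_2d(arr)).all(axis=-1)))
                raise FloatingPointError(
                    f"force overflow on {label} index {worst}")
        return e, f

    def _kick(self, half_dt: float) -> None:
        s, f, c = self.state, self.forces, self.config
        s.v_coords += half_dt * f.atoms / c.mass_atom
        s.v_mg += half_dt * f.mg / c.mass_mg
        s.v_theta += half_dt * f.theta / c.mass_theta

    def _drift(self, half_dt: float) -> None:
        s = self.state
        s.coords += half_dt * s.v_coords
        s.mg += half_dt * s.v_mg
        s.theta += half_dt * s.v_theta
        self._apply_walls()

    def _apply_walls(self) -> None:
        s = self.state
        if s.box is not None and s.n_mg:
            L = s.box
            for _ in range(2):      # at most two reflections per step
                low = s.mg < 0
                s.mg[low] = -s.mg[low]
                s.v_mg[low] = -s.v_mg[low]
                high = s.mg > L
                s.mg[high] = 2 * L - s.mg[high]
                s.v_mg[high] = -s.v_mg[high]
        # clamp condensation fractions, kill velocity at the bound
        lo = s.theta < 0.0
        hi = s.theta > 1.0
        s.theta[lo] = 0.0
        s.theta[hi] = 1.0
        s.v_theta[lo | hi] = 0.0

    def _thermostat(self) -> None:
        s, c = self.state, self.config
        T = c.temperature
        for key, vel, mass, shape in (
                ("atoms", s.v_coords, c.mass_atom, s.coords.shape),
                ("mg", s.v_mg, c.mass_mg, s.mg.shape),
                ("theta", s.v_theta, c.mass_theta, s.theta.shape)):
            if vel.size == 0:
                continue
            noise = self.rng.standard_normal(shape)
            vel *= self._c1[key]
            vel += self._c2[key] * np.sqrt(T / mass) * noise

    def step(self, n: int = 1) -> None:
        half = 0.5 * self.config.timestep
        for _ in range(n):
            self._kick(half)
            self._drift(half)
            self._thermostat()
            self._drift(half)
            self.potential, self.forces = self._eval()
            self._kick(half)


def step(state: SystemState, topo: NativeTopology, params: EnergyParams,
         config: SimulationConfig, rng_seed: int | None = None) -> SystemState:
    """Single BAOAB update of a copy of ``state`` (functional interface)."""
    cfg = config if rng_seed is None else \
        SimulationConfig(**{**asdict(config), "seed": rng_seed})
    integ = LangevinIntegrator(state.copy(), topo, params, cfg)
    integ.step(1)
    return integ.state


def run(state: SystemState, topo: NativeTopology, params: EnergyParams,
        config: SimulationConfig, bias=None,
        out_path: str | None = None) -> Trajectory:
    """Run ``config.n_steps`` steps, saving every ``save_interval`` steps
    (frame 0 included)."""
    integ = LangevinIntegrator(state, topo, params, config, bias=bias)
    frames_x, frames_m, frames_t, times, energies = [], [], [], [], []

    def record(step_no: int) -> None:
        frames_x.append(state.coords.copy())
        frames_m.append(state.mg.copy())
        frames_t.append(state.theta.copy())
        times.append(step_no * config.timestep)
        energies.append(integ.potential)

    record(0)
    done = 0
    while done < config.n_steps:
        chunk = min(config.save_interval, config.n_steps - done)
        integ.step(chunk)
        done += chunk
        record(done)
    traj = Trajectory(
        coords=np.asarray(frames_x), mg=np.asarray(frames_m),
        theta=np.asarray(frames_t), time=np.asarray(times),
        energy=np.asarray(energies), seed=config.seed,
        config_hash=config.config_hash())
    if out_path is not None:
        traj.save_h5(out_path)
    return traj
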