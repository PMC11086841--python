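"""Langevin dynamics on model potentials.

Two integrators are provided: a BAOAB splitting for underdamped dynamics
(exact Ornstein–Uhlenbeck substep, excellent configurational sampling) and
Euler–Maruyama for the overdamped limit.

Units: energies in kcal/mol, lengths in Å, temperatures in K, and *reduced*
time units chosen so that a unit mass has thermal velocity ``sqrt(k_B T)``
(i.e. the mass unit is kcal/mol·τ²/Å²). Equilibrium observables — the only
quantities the estimators consume — are independent of this choice; it
simply makes the toy engine's closed forms (equipartition, Euler–Maruyama
moments, Ornstein–Uhlenbeck relaxation e^(−κt/γ)) exact without unit
conversion factors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .potentials import ModelPotential

__all__ = ["LangevinConfig", "IntegratorInstabilityError", "simulate_langevin", "substream"]


class IntegratorInstabilityError(RuntimeError):
    """Raised when a trajectory diverges; carries the offending step index."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"integrator diverged at step {step}")


@dataclass(frozen=True)
class LangevinConfig:
    """Thermostat and timestep settings for the toy Langevin engine.

    friction is in inverse reduced-time units, timestep in reduced time,
    mass per coordinate (unit mass ⇒ thermal velocity sqrt(k_B·T)).
    ``scheme`` selects "underdamped" (BAOAB) or "overdamped"
    (Euler–Maruyama; mass is ignored, mobility is 1/(m·γ)).
    """

    temperature: float = 300.0
    friction: float = 10.0
    timestep: float = 0.01
    mass: float = 1.0
    scheme: str = "underdamped"

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if self.friction <= 0:
            raise ValueError(f"friction must be positive, got {self.friction}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.scheme not in ("underdamped", "overdamped"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def substream(seed: int, *tags) -> np.random.Generator:
    """Named reproducible random substream fanned out from one master seed.

    The same (seed, tags) always yields the same generator; distinct tags
    yield statistically independent streams.
    """
    tag_ints = [
        zlib.crc32(t.encode()) if isinstance(t, str) else int(t) % (2**31)
        for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *tag_ints]))


def simulate_langevin(
    potential: ModelPotential,
    config: LangevinConfig,
    start,
    n_steps: int,
    seed: int | np.random.Generator,
    extra_force=None,
    guard: float = 1e6,
    start_velocity=None,
    return_velocities: bool = False,
):
    """Integrate Langevin dynamics and return the trajectory of positions.

    Parameters
    ----------
    extra_force : callable, optional
        ``extra_force(x, step) -> force array`` added to the conservative
        force each step (used for restraints, walls and adaptive biases).
    guard : float
        Coordinate-magnitude/energy bound beyond which an
        IntegratorInstabilityError is raised, naming the step.
    start_velocity : array, optional
        Initial velocities; default drawn from Maxwell–Boltzmann
        (underdamped scheme only).

    Identical (potential, config, start, n_steps, seed) give a bit-identical
    trajectory.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.array(start, dtype=float)
    if x.shape != (potential.dimension,):
        raise ValueError(f"start must have shape ({potential.dimension},)")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "langevin")
    dt, gamma, m, T = config.timestep, config.friction, config.mass, config.temperature
    kT = KB * T

    def total_force(x, step):
        f = -potential.gradient(x)
        if extra_force is not None:
            f = f + extra_force(x, step)
        return f

    traj = np.empty((n_steps, potential.dimension))
    vels = np.empty((n_steps, potential.dimension)) if return_velocities else None

    if config.scheme == "overdamped":
        mob = 1.0 / (m * gamma)
        sig = np.sqrt(2.0 * kT * mob * dt)
        for i in range(n_steps):
            f = total_force(x, i)
            x = x + mob * f * dt + sig * rng.standard_normal(x.shape)
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > guard:
                raise IntegratorInstabilityError(i)
            traj[i] = x
        return (traj, None) if return_velocities else traj

    # BAOAB underdamped
    if start_velocity is None:
        v = rng.normal(0.0, np.sqrt(kT / m), size=x.shape)
    else:
        v = np.array(start_velocity, dtype=float)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT / m * (1.0 - c1 * c1))
    f = total_force(x, 0)
    for i in range(n_steps):
        v = v + 0.5 * dt * f / m
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x = x + 0.5 * dt * v
        f = total_force(x, i + 1)
        v = v + 0.5 * dt * f / m
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > guard:
            raise IntegratorInstabilityError(i)
        traj[i] = x
        if return_velocities:
            vels[i] = v
    return (traj, vels) if return_velocities else traj
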