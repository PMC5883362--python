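"""Stochastic integrators for the extended system.

The physical coordinates ``x`` follow underdamped Langevin dynamics under the
extended potential

    U_kappa(x, z) = V(x) + 1/2 kappa ||theta(x) - z||^2,

discretized with the BAOAB splitting, which gives accurate configurational
sampling at moderate timesteps.  The CV targets ``z`` follow overdamped
Langevin dynamics at the artificial thermal energy beta_bar_inv,

    gamma_bar dz = kappa (theta(x) - z) dt + sqrt(2 gamma_bar beta_bar_inv) dW,

discretized with Euler-Maruyama.  ``step_targets`` returns a *proposal*; the
controller decides acceptance via the soft-ratcheting rule.

The physical step converts kcal/mol forces to amu·Å²/ps² accelerations; the
target equation is integrated with gamma_bar as a bare mobility, so the
stationary law var(z - theta) = beta_bar_inv / kappa holds in Å² with
energies in kcal/mol.
"""

from __future__ import annotations

import numpy as np

from .model import (
    KCAL_PER_MOL_IN_AKMA,
    CVDefinition,
    ParticleSystem,
    ReTAMDParams,
    evaluate_cvs,
)

__all__ = [
    "Potential",
    "NoiseModel",
    "restraint_energy",
    "restraint_forces",
    "coupled_force",
    "step_physical",
    "step_targets",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


class Potential:
    """Interface for a classical potential V(x).

    Subclasses implement ``energy`` (kcal/mol) and ``forces``
    (kcal/(mol·Å), the negative gradient of ``energy``).
    """

    def energy(self, positions: np.ndarray) -> float:
        raise NotImplementedError

    def forces(self, positions: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ZeroPotential(Potential):
    """Free particles: V = 0 everywhere."""

    def energy(self, positions: np.ndarray) -> float:
        return 0.0

    def forces(self, positions: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(positions, dtype=float))


class NoiseModel:
    """Independent, reproducible Gaussian noise substreams.

    One master seed spawns three child streams — physical noise, CV-target
    noise, and acceptance uniforms — so controller rejections never
    desynchronize the physical trajectory.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        phys, targ, acc = ss.spawn(3)
        self.physical = np.random.default_rng(phys)
        self.targets = np.random.default_rng(targ)
        self.acceptance = np.random.default_rng(acc)

    def normal_physical(self, shape) -> np.ndarray:
        return self.physical.standard_normal(shape)

    def normal_targets(self, shape) -> np.ndarray:
        return self.targets.standard_normal(shape)

    def uniform_acceptance(self) -> float:
        return float(self.acceptance.random())


def restraint_energy(theta: np.ndarray, z: np.ndarray, kappa: float) -> float:
    """Harmonic coupling energy 1/2 kappa ||theta - z||^2 (Frobenius norm)."""
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    if theta.shape != z.shape:
        raise ValueError(f"shape mismatch: theta {theta.shape} vs z {z.shape}")
    diff = theta - z
    return 0.5 * kappa * float(np.sum(diff * diff))


def restraint_forces(
    cvdef: CVDefinition,
    theta: np.ndarray,
    z: np.ndarray,
    kappa: float,
    n_atoms: int,
) -> np.ndarray:
    """Force from the harmonic CV restraint on every atom.

    An atom in group alpha of size n feels -kappa (theta_alpha - z_alpha)/n;
    atoms in no group feel nothing.
    """
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    if theta.shape != z.shape:
        raise ValueError(f"shape mismatch: theta {theta.shape} vs z {z.shape}")
    out = np.zeros((n_atoms, 3))
    for a, g in enumerate(cvdef.groups):
        out[g] -= kappa * (theta[a] - z[a]) / len(g)
    return out


def coupled_force(
    system: ParticleSystem,
    potential: Potential,
    cvdef: CVDefinition | None,
    z: np.ndarray | None,
    kappa: float,
    positions: np.ndarray,
) -> np.ndarray:
    """Total force: physical potential plus CV restraint (if any)."""
    positions = np.asarray(positions, dtype=float)
    f = np.asarray(potential.forces(positions), dtype=float)
    if cvdef is not None and z is not None:
        theta = evaluate_cvs(positions, cvdef)
        f = f + restraint_forces(cvdef, theta, z, kappa, len(positions))
    return f


class BAOAB:
    """BAOAB Langevin integrator at friction gamma and thermal energy beta_inv.

    Caches the force so each step costs one force evaluation.  Setting
    gamma = 0 recovers velocity Verlet (no thermostat) and a zero-noise
    stream makes the step fully deterministic.
    """

    def __init__(
        self,
        masses: np.ndarray,
        gamma: float,
        beta_inv: float,
        dt: float,
    ):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.m = np.asarray(masses, dtype=float)[:, None]
        self.gamma = float(gamma)
        self.beta_inv = float(beta_inv)
        self.dt = float(dt)
        # O-step coefficients; gamma=0 degrades gracefully to c1=1, c2=0.
        self.c1 = np.exp(-self.gamma * self.dt)
        self.c2 = np.sqrt(max(0.0, 1.0 - self.c1 * self.c1))
        # thermal velocity scale sqrt(beta_inv/m) in Å/ps
        self.sigma_v = np.sqrt(self.beta_inv * KCAL_PER_MOL_IN_AKMA / self.m)

    def accel(self, forces: np.ndarray) -> np.ndarray:
        return forces * (KCAL_PER_MOL_IN_AKMA / self.m)

    def step(self, x, v, forces, force_fn, noise):
        """One BAOAB step; returns (x', v', forces at x')."""
        dt = self.dt
        v = v + 0.5 * dt * self.accel(forces)
        x = x + 0.5 * dt * v
        eta = noise if isinstance(noise, np.ndarray) else noise.normal_physical(x.shape)
        v = self.c1 * v + self.c2 * self.sigma_v * eta
        x = x + 0.5 * dt * v
        new_forces = force_fn(x)
        if not np.all(np.isfinite(new_forces)):
            raise IntegrationError("non-finite forces")
        v = v + 0.5 * dt * self.accel(new_forces)
        return x, v, new_forces


def step_physical(
    x: np.ndarray,
    v: np.ndarray,
    forces: np.ndarray,
    system: ParticleSystem,
    params: ReTAMDParams,
    potential: Potential,
    cvdef: CVDefinition | None,
    z: np.ndarray | None,
    noise: NoiseModel,
    step_index: int = 0,
):
    """One BAOAB Langevin step of the physical coordinates under coupled_force.

    Returns (x', v', forces'); deterministic given the noise stream.
    """
    integ = BAOAB(system.masses, params.gamma, params.beta_inv, params.dt)

    def force_fn(pos):
        return coupled_force(system, potential, cvdef, z, params.kappa, pos)

    try:
        return integ.step(np.asarray(x, float), np.asarray(v, float), forces,
                          force_fn, noise)
    except IntegrationError as err:
        raise IntegrationError(f"step {step_index}: {err}") from err


def step_targets(
    z: np.ndarray,
    theta: np.ndarray,
    params: ReTAMDParams,
    beta_bar_inv: float,
    noise: NoiseModel | np.ndarray,
) -> np.ndarray:
    """Euler-Maruyama proposal for the CV targets.

    z' = z + (dt/gamma_bar) kappa (theta - z)
           + sqrt(2 dt beta_bar_inv / gamma_bar) eta
    """
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(theta))
            and np.isfinite(beta_bar_inv)):
        raise ValueError("non-finite input to step_targets")
    drift = (params.dt / params.gamma_bar) * params.kappa * (theta - z)
    amp = np.sqrt(2.0 * params.dt * beta_bar_inv / params.gamma_bar)
    eta = noise if isinstance(noise, np.ndarray) else noise.normal_targets(z.shape)
    return z + drift + amp * eta
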