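"""The re-TAMD controller: adaptive artificial temperature, soft-ratcheting
acceptance of CV-target proposals, and the main simulation loops.

The artificial thermal energy rises as the ligand approaches the receptor,

    beta_bar_inv = k / min(D) + h,

with min(D) the smallest ligand-receptor atom distance; a ligand pressed
against the surface is therefore strongly encouraged to move, while a ligand
drifting away cools toward ``h``.  Proposed target moves that take every CV
target farther from the receptor are only accepted with probability
min(1, f_1 f_2 ... f_N) where

    f_i = exp[-(D_i - D_i_new)^2] / (c D_i^2),

the soft-ratcheting filter that keeps the ligand diffusing along the surface
instead of escaping to the bulk.  Any proposal that brings at least one
target closer is accepted unconditionally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dynamics import BAOAB, IntegrationError, NoiseModel, Potential, coupled_force
from .model import (
    ConfigurationError,
    CVDefinition,
    ParticleSystem,
    ReTAMDParams,
    evaluate_cvs,
)

__all__ = [
    "StepRecord",
    "Trajectory",
    "RunResult",
    "adaptive_beta_bar",
    "ratchet_factor",
    "soft_ratchet_decision",
    "run_retamd",
    "run_plain_md",
]

logger = logging.getLogger(__name__)


@dataclass
class StepRecord:
    """Per-step bookkeeping of the controller."""

    step: int
    z: np.ndarray
    theta: np.ndarray
    D: np.ndarray
    min_distance: float
    beta_bar_inv: float
    accepted: bool
    acceptance_prob: float


@dataclass
class Trajectory:
    """Coordinate frames plus the system they belong to."""

    coordinates: np.ndarray       # (n_frames, n_atoms, 3) Å
    times: np.ndarray             # (n_frames,) ps
    system: ParticleSystem

    @property
    def n_frames(self) -> int:
        return len(self.coordinates)


@dataclass
class RunResult:
    trajectory: Trajectory
    records: pd.DataFrame
    final_x: np.ndarray
    final_v: np.ndarray
    final_z: np.ndarray | None = None
    acceptance_rate: float | None = None
    extras: dict = field(default_factory=dict)


def adaptive_beta_bar(min_distance: float, k_adapt: float, h_adapt: float) -> float:
    """Distance-adaptive artificial thermal energy k/min(D) + h (kcal/mol).

    Strictly decreasing in min_distance (for k > 0) with limit ``h`` at
    large separation.
    """
    if min_distance <= 0:
        raise ValueError(f"min_distance must be > 0, got {min_distance}")
    return k_adapt / min_distance + h_adapt


def ratchet_factor(
    D_old: float, D_new: float, c_ratchet: float, form: str = "literal"
) -> float:
    """Soft-ratcheting factor for one CV.

    ``literal`` evaluates exp[-(D_old - D_new)^2] / (c D_old^2): larger ``c``
    means a stricter restraint.  ``exponent-scaled`` evaluates the alternative
    exp[-(D_old - D_new)^2 / (c D_old^2)], in which larger ``c`` is more
    permissive; it is provided for comparison only.
    """
    if D_old <= 0:
        raise ValueError(f"D_old must be > 0, got {D_old}")
    if c_ratchet <= 0:
        raise ValueError(f"c_ratchet must be > 0, got {c_ratchet}")
    dd2 = (D_old - D_new) ** 2
    if form == "literal":
        return float(np.exp(-dd2) / (c_ratchet * D_old**2))
    if form == "exponent-scaled":
        return float(np.exp(-dd2 / (c_ratchet * D_old**2)))
    raise ValueError(f"unknown ratchet form {form!r}")


def soft_ratchet_decision(
    D_old_vec: np.ndarray,
    D_new_vec: np.ndarray,
    c_ratchet: float,
    uniform_draw: float,
    form: str = "literal",
) -> tuple[bool, float]:
    """Accept/reject a CV-target proposal.

    If at least one D_new_i < D_old_i the proposal is accepted with
    probability 1 unconditionally; otherwise the acceptance probability is
    min(1, prod_i f_i) and the proposal is accepted iff
    ``uniform_draw < prob``.
    """
    D_old = np.atleast_1d(np.asarray(D_old_vec, dtype=float))
    D_new = np.atleast_1d(np.asarray(D_new_vec, dtype=float))
    if D_old.shape != D_new.shape:
        raise ValueError(f"length mismatch: {D_old.shape} vs {D_new.shape}")
    if D_old.size < 1:
        raise ValueError("need at least one CV distance")
    if np.any(D_new < D_old):
        return True, 1.0
    factors = [ratchet_factor(o, n, c_ratchet, form) for o, n in zip(D_old, D_new)]
    prob = min(1.0, float(np.prod(factors)))
    return bool(uniform_draw < prob), prob


def _pair_min_distance(pos, rec_idx, lig_idx):
    return float(cdist(pos[lig_idx], pos[rec_idx]).min())


def _target_distances(z, pos, rec_idx):
    return cdist(np.atleast_2d(z), pos[rec_idx]).min(axis=1)


def run_retamd(
    system: ParticleSystem,
    potential: Potential,
    cvdef: CVDefinition,
    params: ReTAMDParams,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    z0: np.ndarray | None = None,
    starvation_window: int = 1000,
    stop_condition=None,
) -> RunResult:
    """Run the full re-TAMD loop.

    Per step: (1) BAOAB-integrate x under the current targets z;
    (2) recompute theta and min(D) and refresh beta_bar_inv;
    (3) propose z' by Euler-Maruyama; (4) compute the target-receptor
    distances of z' and apply the soft-ratcheting decision, keeping the
    previous z on rejection; (5) record a StepRecord.  Frames are stored
    every ``params.frame_stride`` steps.  An optional ``stop_condition(x,
    step)`` ends the run early (first-passage studies); the stopping step
    is reported in ``extras["stopped_at"]``.

    Ratcheting and adaptation both require a receptor partition; with both
    disabled (``use_ratchet=False``, ``use_adaptive=False``) the loop is
    vanilla TAMD at constant artificial thermal energy ``h_adapt`` and runs
    on receptor-free systems too.
    """
    cvdef.validate(system.n_atoms, system)
    rec_idx, lig_idx = system.receptor_indices, system.ligand_indices
    needs_receptor = params.use_ratchet or params.use_adaptive
    if needs_receptor and rec_idx.size == 0:
        raise ConfigurationError(
            "ratcheting/adaptive temperature require a receptor partition"
        )

    x = np.array(system.positions if x0 is None else x0, dtype=float)
    v = np.zeros_like(x) if v0 is None else np.array(v0, dtype=float)
    noise = NoiseModel(params.seed)
    integ = BAOAB(system.masses, params.gamma, params.beta_inv, params.dt)
    n_cvs = cvdef.n_cvs

    theta = evaluate_cvs(x, cvdef)
    z = theta.copy() if z0 is None else np.array(z0, dtype=float)

    def force_fn(pos):
        return coupled_force(system, potential, cvdef, z, params.kappa, pos)

    forces = force_fn(x)
    if rec_idx.size:
        D = _target_distances(z, x, rec_idx)
    else:
        D = np.full(n_cvs, np.inf)

    n = params.n_steps
    rec_steps, rec_minD, rec_bbar, rec_acc, rec_prob = [], [], [], [], []
    rec_z = np.empty((n, n_cvs, 3))
    rec_theta = np.empty((n, n_cvs, 3))
    rec_D = np.empty((n, n_cvs))
    frames, frame_times = [x.copy()], [0.0]
    n_accepted = 0
    window_accepts = 0
    starved_warned = False

    for step in range(1, n + 1):
        try:
            x, v, forces = integ.step(x, v, forces, force_fn, noise)
        except IntegrationError as err:
            raise IntegrationError(f"step {step}: {err}") from err

        theta = evaluate_cvs(x, cvdef)
        if rec_idx.size:
            min_d = _pair_min_distance(x, rec_idx, lig_idx)
        else:
            min_d = np.inf
        if params.use_adaptive:
            beta_bar_inv = adaptive_beta_bar(min_d, params.k_adapt, params.h_adapt)
        else:
            beta_bar_inv = params.h_adapt

        # Euler-Maruyama proposal for the CV targets
        drift = (params.dt / params.gamma_bar) * params.kappa * (theta - z)
        amp = np.sqrt(2.0 * params.dt * beta_bar_inv / params.gamma_bar)
        z_prop = z + drift + amp * noise.normal_targets(z.shape)

        if params.use_ratchet:
            D_new = _target_distances(z_prop, x, rec_idx)
            accepted, prob = soft_ratchet_decision(
                D, D_new, params.c_ratchet,
                noise.uniform_acceptance(), params.ratchet_form,
            )
        else:
            D_new = (_target_distances(z_prop, x, rec_idx)
                     if rec_idx.size else np.full(n_cvs, np.inf))
            accepted, prob = True, 1.0

        if accepted:
            z = z_prop
            D = D_new
            n_accepted += 1
            window_accepts += 1

        rec_steps.append(step)
        rec_z[step - 1] = z
        rec_theta[step - 1] = theta
        rec_D[step - 1] = D
        rec_minD.append(min_d)
        rec_bbar.append(beta_bar_inv)
        rec_acc.append(accepted)
        rec_prob.append(prob)

        if step % params.frame_stride == 0:
            frames.append(x.copy())
            frame_times.append(step * params.dt)
        if step % 1000 == 0:
            logger.info(
                "step %d: acc_rate=%.3f beta_bar_inv=%.2f min(D)=%.2f",
                step, n_accepted / step, beta_bar_inv, min_d,
            )
        if params.use_ratchet and step % starvation_window == 0:
            if window_accepts == 0 and not starved_warned:
                warnings.warn(
                    f"no target proposals accepted in the last "
                    f"{starvation_window} steps (through step {step})",
                    RuntimeWarning,
                )
                starved_warned = True
            window_accepts = 0
        if stop_condition is not None and stop_condition(x, step):
            stopped_at = step
            break

    stopped_at = locals().get("stopped_at")
    n_rec = len(rec_steps)
    records = pd.DataFrame({"step": rec_steps})
    for a in range(n_cvs):
        for ci, cname in enumerate("xyz"):
            records[f"z{a}_{cname}"] = rec_z[:n_rec, a, ci]
    for a in range(n_cvs):
        for ci, cname in enumerate("xyz"):
            records[f"theta{a}_{cname}"] = rec_theta[:n_rec, a, ci]
    for a in range(n_cvs):
        records[f"D{a}"] = rec_D[:n_rec, a]
    records["minD"] = rec_minD
    records["beta_bar_inv"] = rec_bbar
    records["accepted"] = rec_acc
    records["prob"] = rec_prob
    records["time"] = records["step"] * params.dt

    traj = Trajectory(np.array(frames), np.array(frame_times), system)
    return RunResult(
        trajectory=traj,
        records=records,
        final_x=x,
        final_v=v,
        final_z=z,
        acceptance_rate=n_accepted / max(1, n_rec),
        extras={"stopped_at": stopped_at},
    )


def run_plain_md(
    system: ParticleSystem,
    potential: Potential,
    params: ReTAMDParams,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    stop_condition=None,
) -> RunResult:
    """Plain Langevin dynamics at beta_inv with no CV coupling (control runs).

    ``stop_condition(x, step)`` optionally ends the run early; the stopping
    step is reported in ``extras["stopped_at"]``.
    """
    x = np.array(system.positions if x0 is None else x0, dtype=float)
    v = np.zeros_like(x) if v0 is None else np.array(v0, dtype=float)
    noise = NoiseModel(params.seed)
    integ = BAOAB(system.masses, params.gamma, params.beta_inv, params.dt)

    def force_fn(pos):
        f = np.asarray(potential.forces(pos), dtype=float)
        return f

    forces = force_fn(x)
    frames, frame_times = [x.copy()], [0.0]
    for step in range(1, params.n_steps + 1):
        try:
            x, v, forces = integ.step(x, v, forces, force_fn, noise)
        except IntegrationError as err:
            raise IntegrationError(f"step {step}: {err}") from err
        if step % params.frame_stride == 0:
            frames.append(x.copy())
            frame_times.append(step * params.dt)
        if stop_condition is not None and stop_condition(x, step):
            stopped_at = step
            break

    stopped_at = locals().get("stopped_at")
    traj = Trajectory(np.array(frames), np.array(frame_times), system)
    records = pd.DataFrame(
        {"step": [params.n_steps], "time": [params.n_steps * params.dt]}
    )
    return RunResult(trajectory=traj, records=records, final_x=x, final_v=v,
                     extras={"stopped_at": stopped_at})
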