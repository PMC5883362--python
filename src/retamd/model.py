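"""Domain types and collective-variable geometry.

The sampler couples physical atomic coordinates ``x`` to slowly evolving
targets ``z`` for a set of collective variables (CVs).  Here every CV is the
unweighted geometric center of an ordered group of ligand atoms, so the CV
map ``theta(x)`` is linear and its gradient is sparse and constant.

Units: coordinates in Å, masses in amu, charges in elementary charge units,
energies in kcal/mol, time in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ParticleSystem",
    "CVDefinition",
    "ReTAMDParams",
    "ExtendedState",
    "evaluate_cvs",
    "cv_gradient",
    "min_ligand_receptor_distance",
    "cv_target_receptor_distances",
]

#: kcal/mol expressed in amu·Å²/ps² (4.184 kJ/mol / 0.01 kJ/mol per amu·Å²/ps²).
KCAL_PER_MOL_IN_AKMA = 418.4

#: Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL_MOL_K = 0.0019872041


class DefinitionError(ValueError):
    """A CV definition is inconsistent with the particle system."""


class ConfigurationError(ValueError):
    """A particle system or parameter set violates a precondition."""


@dataclass
class ParticleSystem:
    """A receptor/ligand particle system.

    Parameters
    ----------
    positions : (n, 3) float array
        Cartesian coordinates in Å.
    masses : (n,) float array
        Per-atom masses in amu; strictly positive.
    charges : (n,) float array
        Partial charges in elementary charge units.
    residue_index : (n,) int array
        Residue identifier per atom (1-based in I/O, arbitrary here), must be
        non-decreasing within each role partition.
    residue_name, atom_name : sequences of str
        PDB-style labels.
    role : (n,) array of {"receptor", "ligand"}
        Partition tag per atom.
    bonded_topology : list of (i, j) pairs, optional
        Bonds for toy chain models.
    """

    positions: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    role: np.ndarray
    bonded_topology: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        n = self.n_atoms
        if self.positions.shape != (n, 3):
            raise ConfigurationError(
                f"positions must be (n, 3); got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ConfigurationError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ConfigurationError("masses must be strictly positive")
        for arr, name in (
            (self.charges, "charges"),
            (self.residue_index, "residue_index"),
            (self.residue_name, "residue_name"),
            (self.atom_name, "atom_name"),
            (self.role, "role"),
        ):
            if len(arr) != n:
                raise ConfigurationError(f"{name} has length {len(arr)}, expected {n}")
        bad = set(self.role) - {"receptor", "ligand"}
        if bad:
            raise ConfigurationError(f"unknown role tags: {sorted(bad)}")
        for idx in (self.receptor_indices, self.ligand_indices):
            if idx.size and np.any(np.diff(self.residue_index[idx]) < 0):
                raise ConfigurationError(
                    "residue_index must be non-decreasing within a role partition"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == "receptor")

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == "ligand")


@dataclass
class CVDefinition:
    """Ordered atom groups whose geometric centers are the CVs theta(x)."""

    groups: list

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise DefinitionError("need at least one CV group")
        self.groups = [np.asarray(sorted(g), dtype=int) for g in self.groups]
        for a, g in enumerate(self.groups):
            if g.size == 0:
                raise DefinitionError(f"CV group {a} is empty")

    @property
    def n_cvs(self) -> int:
        return len(self.groups)

    def validate(self, n_atoms: int, system: ParticleSystem | None = None) -> None:
        for a, g in enumerate(self.groups):
            if np.any(g < 0) or np.any(g >= n_atoms):
                raise DefinitionError(
                    f"CV group {a} has out-of-range atom indices for n={n_atoms}"
                )
        if system is not None:
            ligand = set(system.ligand_indices.tolist())
            for a, g in enumerate(self.groups):
                if not set(g.tolist()) <= ligand:
                    raise DefinitionError(
                        f"CV group {a} references non-ligand atoms; "
                        "CVs are defined on the ligand only"
                    )


@dataclass
class ReTAMDParams:
    """All thermostat, coupling, adaptive-temperature and ratcheting knobs.

    Defaults follow the published all-atom protocol: restraint constant
    κ = 100 kcal/(mol·Å²), physical friction γ = 2 ps⁻¹, thermal energy
    β⁻¹ = 0.6 kcal/mol (≈300 K), target friction γ̄ = 0.02 ps⁻¹.
    """

    kappa: float = 100.0          # kcal/(mol·Å²)
    gamma: float = 2.0            # ps⁻¹
    beta_inv: float = 0.6         # kcal/mol
    gamma_bar: float = 0.02      # ps⁻¹
    k_adapt: float = 40.0         # Å·kcal/mol; 0 disables adaptation
    h_adapt: float = 10.0         # kcal/mol
    c_ratchet: float = 0.02       # dimensionless (Å-numeric distances)
    dt: float = 0.01              # ps
    n_steps: int = 10_000
    seed: int = 0
    use_ratchet: bool = True
    use_adaptive: bool = True
    ratchet_form: str = "literal"  # or "exponent-scaled" (see docs)
    record_stride: int = 1
    frame_stride: int = 100

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "gamma_bar", "dt", "c_ratchet", "beta_inv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.k_adapt < 0:
            raise ConfigurationError("k_adapt must be non-negative")
        if self.h_adapt < 0:
            raise ConfigurationError("h_adapt must be >= 0")
        if self.ratchet_form not in ("literal", "exponent-scaled"):
            raise ConfigurationError(f"unknown ratchet_form {self.ratchet_form!r}")

    @property
    def temperature(self) -> float:
        """Physical temperature T = β⁻¹/k_B in K."""
        return self.beta_inv / BOLTZMANN_KCAL_MOL_K


@dataclass
class ExtendedState:
    """Instantaneous state of the extended (x, z) system."""

    x: np.ndarray                 # (n, 3) Å
    v: np.ndarray                 # (n, 3) Å/ps
    z: np.ndarray                 # (N, 3) Å
    theta: np.ndarray             # (N, 3) Å
    cv_receptor_distances: np.ndarray  # (N,) Å
    min_distance: float           # Å
    beta_bar_inv: float           # kcal/mol
    time: float = 0.0
    step: int = 0


def evaluate_cvs(positions: np.ndarray, cvdef: CVDefinition) -> np.ndarray:
    """Geometric center of each CV group: theta_a = mean of group-a coordinates.

    Returns an (N, 3) array in Å.
    """
    positions = np.asarray(positions, dtype=float)
    cvdef.validate(len(positions))
    return np.stack([positions[g].mean(axis=0) for g in cvdef.groups])


def cv_gradient(cvdef: CVDefinition, n_atoms: int) -> np.ndarray:
    """Gradient of each CV component w.r.t. atom coordinates.

    Since theta_a is an unweighted mean, the gradient is 1/|group a| on each
    member atom's matching coordinate and zero elsewhere.  Returned as a dense
    (N, n_atoms) array W with ``theta = W @ positions``; each row sums to 1.
    """
    cvdef.validate(n_atoms)
    weights = np.zeros((cvdef.n_cvs, n_atoms))
    for a, g in enumerate(cvdef.groups):
        weights[a, g] = 1.0 / len(g)
    return weights


def min_ligand_receptor_distance(
    system: ParticleSystem, positions: np.ndarray | None = None
) -> float:
    """Smallest Euclidean distance over all ligand-atom/receptor-atom pairs (Å)."""
    pos = system.positions if positions is None else np.asarray(positions, float)
    rec, lig = system.receptor_indices, system.ligand_indices
    if rec.size == 0 or lig.size == 0:
        raise ConfigurationError("both receptor and ligand partitions must be non-empty")
    tree = cKDTree(pos[rec])
    d, _ = tree.query(pos[lig], k=1)
    return float(np.min(d))


def cv_target_receptor_distances(
    z: np.ndarray, system: ParticleSystem, positions: np.ndarray | None = None
) -> np.ndarray:
    """Distance from each CV target point z_i to its nearest receptor atom (Å)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    pos = system.positions if positions is None else np.asarray(positions, float)
    rec = system.receptor_indices
    if rec.size == 0:
        raise ConfigurationError("receptor partition is empty")
    tree = cKDTree(pos[rec])
    d, _ = tree.query(z, k=1)
    return np.asarray(d, dtype=float)
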