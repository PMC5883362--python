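"""Built-in potentials and synthetic structure generators.

Two families of test systems make every sampler and analysis feature
exercisable without external data:

* analytic landscapes (double well) with the exact free energy along the CV
  available by quadrature, used to validate the sampler's stationary law and
  its acceleration over plain Langevin dynamics;
* a coarse-grained receptor/ligand complex — a rigid-ish spherical bead
  blob with a sticky pocket plus a flexible charged bead chain — emulating a
  peptide bound to a reader-domain surface pocket.

Toy systems use Å / kcal/mol / ps / amu throughout, so the published
adaptive-temperature and ratcheting presets apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, simpson

from .dynamics import Potential
from .model import CVDefinition, ParticleSystem

__all__ = [
    "AnalyticLandscape",
    "DoubleWellPotential",
    "CGComplex",
    "CGPotential",
    "HarmonicPotential",
    "make_double_well",
    "make_cg_complex",
    "pocket_contact_fraction",
    "write_fixture_pdb",
]


class DoubleWellPotential(Potential):
    """Single particle in V(x) = B[(x1/a)^2 - 1]^2 + 1/2 k_perp (x2^2 + x3^2).

    Minima at x1 = ±a with V = 0; barrier of height B at x1 = 0.
    """

    def __init__(self, barrier_height: float, separation: float, k_perp: float = 10.0):
        if barrier_height <= 0:
            raise ValueError("barrier_height must be > 0")
        if separation <= 0:
            raise ValueError("separation must be > 0")
        self.barrier = float(barrier_height)
        self.a = float(separation) / 2.0
        self.k_perp = float(k_perp)

    def energy_1d(self, x1):
        u = (np.asarray(x1, float) / self.a) ** 2 - 1.0
        return self.barrier * u * u

    def energy(self, positions) -> float:
        p = np.asarray(positions, float).reshape(-1, 3)
        x1 = p[:, 0]
        perp = 0.5 * self.k_perp * np.sum(p[:, 1:] ** 2)
        return float(np.sum(self.energy_1d(x1)) + perp)

    def forces(self, positions) -> np.ndarray:
        p = np.asarray(positions, float).reshape(-1, 3)
        f = np.zeros_like(p)
        u = (p[:, 0] / self.a) ** 2 - 1.0
        f[:, 0] = -4.0 * self.barrier * u * p[:, 0] / self.a**2
        f[:, 1:] = -self.k_perp * p[:, 1:]
        return f


class HarmonicPotential(Potential):
    """Isotropic harmonic well V(x) = 1/2 k |x - x0|^2 per particle."""

    def __init__(self, k_spring: float, center=None):
        if k_spring <= 0:
            raise ValueError("k_spring must be > 0")
        self.k = float(k_spring)
        self.center = None if center is None else np.asarray(center, float)

    def _disp(self, positions):
        p = np.asarray(positions, float).reshape(-1, 3)
        return p if self.center is None else p - self.center

    def energy(self, positions) -> float:
        d = self._disp(positions)
        return 0.5 * self.k * float(np.sum(d * d))

    def forces(self, positions) -> np.ndarray:
        return -self.k * self._disp(positions)


@dataclass
class AnalyticLandscape:
    """A 1D reference landscape with quadrature free energy along the CV.

    For a particle in ``potential`` restrained to a target z with stiffness
    kappa at physical thermal energy beta_inv, the free energy along z is

        F(z) = -beta_inv * ln ∫ exp(-[V(x) + kappa/2 (x - z)^2]/beta_inv) dx.

    The CV-target marginal of the extended dynamics then tracks
    exp(-F(z)/beta_bar_inv) in the adiabatic (slow-z) regime.
    """

    potential: DoubleWellPotential
    x_range: tuple = (-8.0, 8.0)

    def free_energy(self, z_grid, beta_inv: float, kappa: float,
                    rule: str = "quad") -> np.ndarray:
        z_grid = np.atleast_1d(np.asarray(z_grid, float))
        b = beta_inv

        def exponent(x, z):
            return (self.potential.energy_1d(x)
                    + 0.5 * kappa * (x - z) ** 2)

        # shift by the minimum exponent so the integrand never underflows
        xs_scan = np.linspace(*self.x_range, 4001)
        out = np.empty_like(z_grid)
        if rule == "quad":
            for i, z in enumerate(z_grid):
                e0 = exponent(xs_scan, z).min()
                val, _ = quad(lambda x: np.exp(-(exponent(x, z) - e0) / b),
                              *self.x_range, limit=200)
                out[i] = e0 - b * np.log(val)
        elif rule == "simpson":
            xs = np.linspace(*self.x_range, 20001)
            for i, z in enumerate(z_grid):
                e = exponent(xs, z)
                e0 = e.min()
                out[i] = e0 - b * np.log(simpson(np.exp(-(e - e0) / b), x=xs))
        else:
            raise ValueError(f"unknown quadrature rule {rule!r}")
        return out

    def target_density(self, z_grid, beta_inv: float, beta_bar_inv: float,
                       kappa: float) -> np.ndarray:
        """Normalized density of the CV target along z on ``z_grid``."""
        z_grid = np.asarray(z_grid, float)
        F = self.free_energy(z_grid, beta_inv, kappa)
        w = np.exp(-(F - F.min()) / beta_bar_inv)
        return w / np.trapezoid(w, z_grid)


def make_double_well(
    barrier_height: float,
    separation: float,
    k_perp: float = 10.0,
    mass: float = 12.0,
) -> tuple[ParticleSystem, DoubleWellPotential, CVDefinition, AnalyticLandscape]:
    """One particle in a symmetric double well, starting in the left well.

    Returns the system, the potential, the single-CV definition (the
    particle's own position) and the analytic landscape.
    """
    pot = DoubleWellPotential(barrier_height, separation, k_perp)
    system = ParticleSystem(
        positions=np.array([[-pot.a, 0.0, 0.0]]),
        masses=np.array([mass]),
        charges=np.array([0.0]),
        residue_index=np.array([1]),
        residue_name=np.array(["DWP"]),
        atom_name=np.array(["X"]),
        role=np.array(["ligand"]),
    )
    cvdef = CVDefinition(groups=[[0]])
    landscape = AnalyticLandscape(pot, x_range=(-3.0 * pot.a, 3.0 * pot.a))
    return system, pot, cvdef, landscape


# --------------------------------------------------------------------------
# Coarse-grained receptor/ligand complex
# --------------------------------------------------------------------------

#: Calibrated defaults for the CG complex (frozen after a one-time sweep;
#: see docs/methods.md): binding stable under plain Langevin dynamics at
#: beta_inv = 0.6 kcal/mol, escapable under the published adaptive presets.
CG_DEFAULTS = dict(
    receptor_radius=16.0,     # Å
    bond_length=3.8,          # Å, consecutive ligand beads
    bind_distance=3.2,        # Å, ligand shell above the receptor surface
    k_tether=10.0,            # kcal/(mol·Å²), receptor bead restraint
    k_bond=100.0,             # kcal/(mol·Å²)
    k_angle=2.0,              # kcal/(mol·rad²)
    theta0=2.9,               # rad, near-straight chain
    k_rep=10.0,               # kcal/(mol·Å²), soft-sphere
    sigma_rep=3.0,            # Å
    eps_attract=4.0,          # kcal/mol per probe-pocket pair
    r_attract=3.3,            # Å, attraction minimum
    w_attract=1.2,            # Å, attraction width
    n_pocket=2,               # receptor beads forming the pocket site
    cup_target=3.8,           # Å probe distance for raised cup beads; None = flat site
    k_confine=5.0,            # kcal/(mol·Å²)
    confine_radius=25.0,      # Å from receptor centroid
    receptor_mass=100.0,      # amu
    ligand_mass=20.0,         # amu
)

#: Cyclic partial-charge pattern for ligand beads: polar (|q| >= 0.2) and
#: hydrophobic (|q| < 0.2) classes are both always present for length >= 3.
_LIGAND_CHARGE_CYCLE = (0.5, -0.1, -0.4, 0.1, 0.3, -0.15, -0.5, 0.05)
_RECEPTOR_CHARGE_CYCLE = (-0.4, 0.1, 0.5, -0.1, 0.3, -0.05, -0.3, 0.15)


@dataclass
class CGComplex:
    """A generated coarse-grained complex and its bookkeeping."""

    system: ParticleSystem
    potential: "CGPotential"
    cvdef: CVDefinition
    pocket_beads: np.ndarray       # receptor atom indices forming the pocket
    probe_bead: int = -1           # central ligand bead anchored in the cup
    params: dict = field(default_factory=dict)


class CGPotential(Potential):
    """Energy terms of the CG complex.

    Receptor beads are harmonically tethered to reference sites (rigid-ish
    body); the ligand chain has harmonic bonds and angles; all ligand beads
    feel a soft-sphere repulsion from every receptor bead and from non-bonded
    ligand beads, a Gaussian attraction to the pocket beads, and a
    flat-bottom spherical confinement about the receptor centroid.
    """

    def __init__(self, reference, receptor_idx, ligand_idx, pocket_idx,
                 bonds, angles, p, attract_idx=None):
        self.reference = np.asarray(reference, float)
        self.rec = np.asarray(receptor_idx, int)
        self.lig = np.asarray(ligand_idx, int)
        self.pocket = np.asarray(pocket_idx, int)
        self.att_lig = (self.lig if attract_idx is None
                        else np.atleast_1d(np.asarray(attract_idx, int)))
        self.bonds = np.asarray(bonds, int)
        self.angles = np.asarray(angles, int)
        self.p = dict(p)
        self.center = self.reference[self.rec].mean(axis=0)
        # ligand-ligand pairs separated by >1 bond
        nl = len(self.lig)
        ii, jj = np.triu_indices(nl, k=2)
        self._ll_pairs = (self.lig[ii], self.lig[jj])

    # -- individual terms, each returning (energy, forces) ------------------

    def _tether(self, pos, f):
        d = pos[self.rec] - self.reference[self.rec]
        k = self.p["k_tether"]
        f[self.rec] -= k * d
        return 0.5 * k * float(np.sum(d * d))

    def _bonds(self, pos, f):
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        rij = pos[j] - pos[i]
        r = np.linalg.norm(rij, axis=1)
        k, r0 = self.p["k_bond"], self.p["bond_length"]
        dr = r - r0
        fij = (k * dr / r)[:, None] * rij
        np.add.at(f, i, fij)
        np.add.at(f, j, -fij)
        return 0.5 * k * float(np.sum(dr * dr))

    def _angles(self, pos, f):
        if len(self.angles) == 0:
            return 0.0
        i, j, k_ = self.angles[:, 0], self.angles[:, 1], self.angles[:, 2]
        u = pos[i] - pos[j]
        v = pos[k_] - pos[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        ka, t0 = self.p["k_angle"], self.p["theta0"]
        dtheta = theta - t0
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
        # dV/dtheta = ka*dtheta; dtheta/dcos = -1/sin
        coef = ka * dtheta / sin_t
        dcos_du = v / (nu * nv)[:, None] - (cos_t / nu**2)[:, None] * u
        dcos_dv = u / (nu * nv)[:, None] - (cos_t / nv**2)[:, None] * v
        fi = coef[:, None] * dcos_du
        fk = coef[:, None] * dcos_dv
        np.add.at(f, i, fi)
        np.add.at(f, k_, fk)
        np.add.at(f, j, -(fi + fk))
        return 0.5 * ka * float(np.sum(dtheta * dtheta))

    def _soft_rep_pairs(self, pos, f, idx_a, idx_b):
        rij = pos[idx_b] - pos[idx_a]
        r = np.linalg.norm(rij, axis=1)
        k, sig = self.p["k_rep"], self.p["sigma_rep"]
        mask = r < sig
        if not np.any(mask):
            return 0.0
        r_m = np.clip(r[mask], 1e-9, None)
        over = sig - r_m
        fij = (k * over / r_m)[:, None] * rij[mask]
        np.add.at(f, idx_a[mask], -fij)
        np.add.at(f, idx_b[mask], fij)
        return 0.5 * k * float(np.sum(over * over))

    def _repulsion(self, pos, f):
        li, ri = np.meshgrid(self.lig, self.rec, indexing="ij")
        e = self._soft_rep_pairs(pos, f, li.ravel(), ri.ravel())
        e += self._soft_rep_pairs(pos, f, *self._ll_pairs)
        return e

    def _attraction(self, pos, f):
        li, pi = np.meshgrid(self.att_lig, self.pocket, indexing="ij")
        li, pi = li.ravel(), pi.ravel()
        rij = pos[pi] - pos[li]
        r = np.clip(np.linalg.norm(rij, axis=1), 1e-9, None)
        eps, r0, w = self.p["eps_attract"], self.p["r_attract"], self.p["w_attract"]
        g = np.exp(-((r - r0) ** 2) / (2 * w * w))
        e = -eps * float(np.sum(g))
        dVdr = eps * g * (r - r0) / (w * w)
        fij = (dVdr / r)[:, None] * rij    # force on li = -dV/d(pos_li)
        np.add.at(f, li, fij)
        np.add.at(f, pi, -fij)
        return e

    def _confinement(self, pos, f):
        d = pos[self.lig] - self.center
        r = np.linalg.norm(d, axis=1)
        R, k = self.p["confine_radius"], self.p["k_confine"]
        mask = r > R
        if not np.any(mask):
            return 0.0
        over = r[mask] - R
        fi = -(k * over / r[mask])[:, None] * d[mask]
        np.add.at(f, self.lig[mask], fi)
        return 0.5 * k * float(np.sum(over * over))

    def energy(self, positions) -> float:
        pos = np.asarray(positions, float)
        f = np.zeros_like(pos)
        return (self._tether(pos, f) + self._bonds(pos, f)
                + self._angles(pos, f) + self._repulsion(pos, f)
                + self._attraction(pos, f) + self._confinement(pos, f))

    def forces(self, positions) -> np.ndarray:
        pos = np.asarray(positions, float)
        f = np.zeros_like(pos)
        for term in (self._tether, self._bonds, self._angles,
                     self._repulsion, self._attraction, self._confinement):
            term(pos, f)
        return f


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic, nearly uniform points on a sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    pts = np.stack([r * np.cos(phi), y, r * np.sin(phi)], axis=1)
    return radius * pts


def _cv_groups_for_length(ligand_length: int, ligand_offset: int) -> list:
    """Contiguous CV groups mirroring the published CV counts:
    3 groups for a 13-mer, 2 for a 7-mer, 1 for a 3-mer; in between,
    one group per ~4-5 residues."""
    if ligand_length >= 10:
        n_groups = 3
    elif ligand_length >= 5:
        n_groups = 2
    else:
        n_groups = 1
    idx = np.arange(ligand_offset, ligand_offset + ligand_length)
    return [g.tolist() for g in np.array_split(idx, n_groups)]


def make_cg_complex(
    n_receptor: int = 210,
    ligand_length: int = 13,
    seed: int = 0,
    **overrides,
) -> CGComplex:
    """Generate the coarse-grained receptor/ligand complex.

    The receptor is a spherical shell of ``n_receptor`` beads tethered to
    their generated reference sites.  The ligand chain is draped along a
    meridian of the binding shell with its central bead (the anchoring
    residue, playing the acylated-lysine part) over the pocket: the
    ``n_pocket`` receptor beads nearest that bead are raised along their
    radial rays into a concave cup around it and carry the attractive
    wells that hold the central bead.  Deterministic for a given seed.
    """
    if ligand_length < 3:
        raise ValueError("ligand_length must be >= 3")
    if n_receptor < 20:
        raise ValueError("n_receptor must be >= 20")
    p = dict(CG_DEFAULTS)
    p.update(overrides)
    rng = np.random.default_rng(seed)

    rec_pos = _fibonacci_sphere(n_receptor, p["receptor_radius"])
    rec_pos += rng.normal(scale=0.15, size=rec_pos.shape)  # slight roughness

    # ligand along a meridian arc at radius R + bind_distance, over the +y pole
    R_lig = p["receptor_radius"] + p["bind_distance"]
    dang = p["bond_length"] / R_lig
    angles = (np.arange(ligand_length) - (ligand_length - 1) / 2.0) * dang
    lig_pos = np.stack(
        [R_lig * np.sin(angles), R_lig * np.cos(angles),
         np.zeros(ligand_length)], axis=1)

    n_total = n_receptor + ligand_length
    rec_idx = np.arange(n_receptor)
    lig_idx = np.arange(n_receptor, n_total)
    probe_local = ligand_length // 2
    probe_pos = lig_pos[probe_local]

    # pocket: n_pocket receptor beads nearest the central ligand bead;
    # with cup_target set they are raised along their radial rays to that
    # distance from the probe, forming a concave collar around it
    d_probe = np.linalg.norm(rec_pos - probe_pos, axis=1)
    pocket = np.sort(np.argsort(d_probe)[: int(p["n_pocket"])])
    if p["cup_target"] is not None:
        for b in pocket:
            u = rec_pos[b] / np.linalg.norm(rec_pos[b])
            up = float(u @ probe_pos)
            disc = up * up - (probe_pos @ probe_pos - p["cup_target"] ** 2)
            if disc >= 0.0:
                rec_pos[b] = (up - np.sqrt(disc)) * u
            else:
                # radial ray misses the cup sphere: slide the bead straight
                # toward the probe instead
                v = rec_pos[b] - probe_pos
                rec_pos[b] = probe_pos + v * (p["cup_target"]
                                              / np.linalg.norm(v))

    pos = np.vstack([rec_pos, lig_pos])

    charges = np.empty(n_total)
    charges[rec_idx] = [_RECEPTOR_CHARGE_CYCLE[i % len(_RECEPTOR_CHARGE_CYCLE)]
                        for i in range(n_receptor)]
    charges[lig_idx] = [_LIGAND_CHARGE_CYCLE[i % len(_LIGAND_CHARGE_CYCLE)]
                        for i in range(ligand_length)]

    masses = np.empty(n_total)
    masses[rec_idx] = p["receptor_mass"]
    masses[lig_idx] = p["ligand_mass"]

    bonds = [(int(lig_idx[i]), int(lig_idx[i + 1]))
             for i in range(ligand_length - 1)]
    angles_t = [(int(lig_idx[i]), int(lig_idx[i + 1]), int(lig_idx[i + 2]))
                for i in range(ligand_length - 2)]

    system = ParticleSystem(
        positions=pos,
        masses=masses,
        charges=charges,
        residue_index=np.concatenate(
            [np.arange(1, n_receptor + 1), np.arange(1, ligand_length + 1)]),
        residue_name=np.array(["REC"] * n_receptor + ["LIG"] * ligand_length),
        atom_name=np.array(["CA"] * n_total),
        role=np.array(["receptor"] * n_receptor + ["ligand"] * ligand_length),
        bonded_topology=bonds,
        metadata={"pocket_beads": pocket.tolist(), "seed": int(seed),
                  "probe_bead": int(lig_idx[probe_local])},
    )
    potential = CGPotential(pos.copy(), rec_idx, lig_idx, pocket,
                            bonds, angles_t, p,
                            attract_idx=[int(lig_idx[probe_local])])
    cvdef = CVDefinition(groups=_cv_groups_for_length(ligand_length, n_receptor))
    return CGComplex(system=system, potential=potential, cvdef=cvdef,
                     pocket_beads=pocket, probe_bead=int(lig_idx[probe_local]),
                     params=p)


def pocket_contact_fraction(complex_: CGComplex, trajectory,
                            cutoff: float = 4.0) -> float:
    """Fraction of frames with the anchor bead in contact with the pocket.

    The anchor (central ligand) bead is the analog of the acylated lysine in
    a reader-domain complex; a frame counts when it lies within ``cutoff`` of
    any pocket bead.  Plain Langevin runs at beta_inv = 0.6 kcal/mol keep
    this near 1; re-TAMD runs under the published presets drive it near 0
    (dissociation followed by surface diffusion).
    """
    coords = trajectory.coordinates if hasattr(trajectory, "coordinates") \
        else np.asarray(trajectory, float)
    probe = complex_.probe_bead
    pocket = complex_.pocket_beads
    hits = sum(
        1 for fr in coords
        if np.linalg.norm(fr[pocket] - fr[probe], axis=1).min() < cutoff)
    return hits / len(coords)


def write_fixture_pdb(system: ParticleSystem, path) -> tuple[str, str]:
    """Write a PDB fixture plus the sidecar per-atom charge table.

    Returns (pdb_path, charge_table_path); the charge table lives next to
    the PDB with suffix ``.charges.tsv``.
    """
    from . import io as _io

    path = str(path)
    charge_path = path[:-4] + ".charges.tsv" if path.endswith(".pdb") \
        else path + ".charges.tsv"
    _io.write_structure(system, path)
    _io.write_charge_table(system, charge_path)
    return path, charge_path
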