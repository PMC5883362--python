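"""Structure and trajectory I/O.

Structures and multi-model trajectories are standard PDB (written and read
through biotite); partial charges, which PDB cannot carry, live in a sidecar
tab-separated table keyed by atom serial.  Per-step scalars of a run are a
TSV with a commented header.  Receptor/ligand roles map to chains: receptor
atoms on chain A, ligand atoms on chain B by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .controller import Trajectory
from .model import ParticleSystem

__all__ = [
    "write_structure",
    "write_charge_table",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
    "write_records",
    "read_records",
]

RECEPTOR_CHAIN = "A"
LIGAND_CHAIN = "B"
DEFAULT_MASS = 50.0


class PDBFormatError(ValueError):
    pass


def _to_atom_array(system: ParticleSystem, b_factor=None, occupancy=None):
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(system.positions, dtype=np.float32)
    arr.chain_id = np.where(system.role == "receptor", RECEPTOR_CHAIN,
                            LIGAND_CHAIN)
    arr.res_id = system.residue_index.astype(int)
    arr.res_name = np.array([str(s)[:3] for s in system.residue_name])
    arr.atom_name = np.array([str(s) for s in system.atom_name])
    arr.element = np.array(
        [str(s)[0] if len(str(s)) else "C" for s in system.atom_name])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation(
        "b_factor",
        np.zeros(n) if b_factor is None else np.asarray(b_factor, float))
    arr.set_annotation(
        "occupancy",
        np.ones(n) if occupancy is None else np.asarray(occupancy, float))
    return arr


def write_structure(system: ParticleSystem, path, b_factor=None,
                    occupancy=None) -> str:
    """Write a single-model PDB for the system."""
    pdbf = PDBFile()
    pdbf.set_structure(_to_atom_array(system, b_factor, occupancy))
    pdbf.write(str(path))
    return str(path)


def write_charge_table(system: ParticleSystem, path) -> str:
    """Sidecar TSV of per-atom charges (and masses), keyed by atom serial.

    Serials are 1-based, in PDB atom order.
    """
    df = pd.DataFrame({
        "serial": np.arange(1, system.n_atoms + 1),
        "charge": system.charges,
        "mass": system.masses,
    })
    df.to_csv(str(path), sep="\t", index=False, float_format="%.4f")
    return str(path)


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBFormatError(
                        f"{path}: malformed PDB line {lineno}: too short")
                try:
                    for lo in (30, 38, 46):
                        float(line[lo:lo + 8])
                except ValueError as err:
                    raise PDBFormatError(
                        f"{path}: malformed PDB line {lineno}: "
                        f"bad coordinate field") from err


def read_structure(
    pdb_path,
    charge_table_path,
    ligand_chains=(LIGAND_CHAIN,),
    model: int = 1,
) -> ParticleSystem:
    """Read a PDB plus its sidecar charge table into a ParticleSystem.

    Roles are assigned by chain id (``ligand_chains`` → ligand, all other
    chains → receptor); charges (and masses, if the table has a ``mass``
    column) are joined by 1-based atom serial.  Multi-model files yield the
    requested model (first by default).
    """
    _validate_pdb_lines(pdb_path)
    pdbf = PDBFile.read(str(pdb_path))
    arr = pdbf.get_structure(model=model)
    n = arr.array_length()

    table = pd.read_csv(str(charge_table_path), sep="\t", comment="#")
    if "serial" not in table.columns or "charge" not in table.columns:
        raise ValueError(
            f"{charge_table_path}: charge table needs 'serial' and 'charge' columns")
    if len(table) != n:
        missing = sorted(set(range(1, n + 1)) - set(table["serial"].astype(int)))
        raise ValueError(
            f"charge table has {len(table)} rows for {n} atoms"
            + (f"; missing serials {missing[:10]}" if missing else ""))
    table = table.sort_values("serial")
    serials = table["serial"].to_numpy(dtype=int)
    if not np.array_equal(serials, np.arange(1, n + 1)):
        raise ValueError("charge table serials must be 1..n_atoms")
    charges = table["charge"].to_numpy(dtype=float)
    masses = (table["mass"].to_numpy(dtype=float)
              if "mass" in table.columns else np.full(n, DEFAULT_MASS))

    role = np.where(np.isin(arr.chain_id, list(ligand_chains)),
                    "ligand", "receptor")
    return ParticleSystem(
        positions=np.asarray(arr.coord, dtype=float),
        masses=masses,
        charges=charges,
        residue_index=np.asarray(arr.res_id, dtype=int),
        residue_name=np.asarray(arr.res_name, dtype=object),
        atom_name=np.asarray(arr.atom_name, dtype=object),
        role=role,
    )


def write_trajectory(trajectory: Trajectory, path) -> str:
    """Write coordinate frames as a multi-model PDB (MODEL/ENDMDL records)."""
    coords = np.asarray(trajectory.coordinates, float)
    if coords.ndim != 3 or len(coords) == 0:
        raise ValueError("trajectory must have at least one frame")
    template = _to_atom_array(trajectory.system)
    stack = struc.from_template(template, coords.astype(np.float32))
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))
    return str(path)


def read_trajectory(path, system: ParticleSystem | None = None) -> Trajectory:
    """Read a multi-model PDB back into a Trajectory.

    If no system is given, a minimal one is built from the PDB labels with
    zero charges and default masses (sufficient for geometry-only analysis);
    pass the system from :func:`read_structure` for charge-aware analysis.
    """
    _validate_pdb_lines(path)
    pdbf = PDBFile.read(str(path))
    stack = pdbf.get_structure()
    if isinstance(stack, struc.AtomArray):
        coords = np.asarray(stack.coord, float)[None]
        first = stack
    else:
        coords = np.asarray(stack.coord, float)
        first = stack[0]
    if system is not None:
        if system.n_atoms != coords.shape[1]:
            raise ValueError(
                f"trajectory has {coords.shape[1]} atoms, system has "
                f"{system.n_atoms}")
    else:
        n = coords.shape[1]
        role = np.where(first.chain_id == LIGAND_CHAIN, "ligand", "receptor")
        system = ParticleSystem(
            positions=coords[0],
            masses=np.full(n, DEFAULT_MASS),
            charges=np.zeros(n),
            residue_index=np.asarray(first.res_id, dtype=int),
            residue_name=np.asarray(first.res_name, dtype=object),
            atom_name=np.asarray(first.atom_name, dtype=object),
            role=role,
        )
    times = np.arange(len(coords), dtype=float)
    return Trajectory(coordinates=coords, times=times, system=system)


def write_records(records: pd.DataFrame, path, header_comment: str = "") -> str:
    """Per-step scalar time series as TSV with a commented header."""
    with open(str(path), "w") as fh:
        fh.write("# re-TAMD per-step records\n")
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index=False)
    return str(path)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", comment="#")
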