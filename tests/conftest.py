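import numpy as np
import pytest

from retamd.model import CVDefinition, ParticleSystem


def random_system(n_receptor=50, n_ligand=20, seed=0, spread=20.0):
    """A geometry-only random two-partition system for distance/contact tests."""
    rng = np.random.default_rng(seed)
    n = n_receptor + n_ligand
    return ParticleSystem(
        positions=rng.uniform(-spread / 2, spread / 2, size=(n, 3)),
        masses=np.full(n, 12.0),
        charges=rng.choice([-0.5, -0.3, -0.1, 0.1, 0.3, 0.5], size=n),
        residue_index=np.concatenate(
            [np.sort(rng.integers(1, 11, size=n_receptor)),
             np.sort(rng.integers(1, 6, size=n_ligand))]),
        residue_name=np.array(["REC"] * n_receptor + ["LIG"] * n_ligand),
        atom_name=np.array(["CA"] * n),
        role=np.array(["receptor"] * n_receptor + ["ligand"] * n_ligand),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_part_system():
    return random_system()


@pytest.fixture
def ligand_only_system():
    """A 68-atom free chain, CVs defined over three contiguous groups."""
    rng = np.random.default_rng(7)
    n = 68
    system = ParticleSystem(
        positions=rng.normal(scale=8.0, size=(n, 3)),
        masses=np.full(n, 12.0),
        charges=np.zeros(n),
        residue_index=np.repeat(np.arange(1, n // 4 + 1), 4),
        residue_name=np.array(["LIG"] * n),
        atom_name=np.array(["CA"] * n),
        role=np.array(["ligand"] * n),
    )
    groups = np.array_split(np.arange(n), 3)
    return system, CVDefinition(groups=[g.tolist() for g in groups])
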