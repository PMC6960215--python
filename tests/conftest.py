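"""Shared fixtures: small synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hydropol.geometry import Atom, Box, Configuration, Role
from hydropol.synthetic import (
    ShellMixtureParams,
    generate_hydrated_configuration,
    generate_polymer_configuration,
)


def config_from_atoms(atoms, box_lengths=(5.0, 5.0, 5.0)) -> Configuration:
    return Configuration.from_atoms(atoms, Box(tuple(box_lengths)))


def water_molecule(o_pos, h1_pos, h2_pos, molecule_id) -> list[Atom]:
    return [
        Atom(tuple(o_pos), Role.WATER_O, "O", molecule_id=molecule_id),
        Atom(tuple(h1_pos), Role.WATER_H, "H", molecule_id=molecule_id),
        Atom(tuple(h2_pos), Role.WATER_H, "H", molecule_id=molecule_id),
    ]


def random_water_box(n_molecules, edge, rng) -> Configuration:
    """Random rigid waters in a periodic cube (for oracle comparisons)."""
    atoms: list[Atom] = []
    for i in range(n_molecules):
        o = rng.random(3) * edge
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = rng.normal(size=3)
        b -= a * (a @ b)
        b /= np.linalg.norm(b)
        half = np.deg2rad(104.5) / 2
        h1 = o + 0.1 * (np.cos(half) * a + np.sin(half) * b)
        h2 = o + 0.1 * (np.cos(half) * a - np.sin(half) * b)
        atoms += water_molecule(o, h1, h2, i + 1)
    return config_from_atoms(atoms, (edge, edge, edge))


@pytest.fixture(scope="session")
def polymer_small() -> Configuration:
    return generate_polymer_configuration(3, 40, target_density=1.3, seed=11)


@pytest.fixture(scope="session")
def hydrated_small(polymer_small) -> Configuration:
    return generate_hydrated_configuration(
        polymer_small, 0.25, ShellMixtureParams(), seed=5
    )


@pytest.fixture(scope="session")
def polymer_standard() -> Configuration:
    """The standard dry fixture: 5 chains x 100 beads at 1.3 g/cm^3."""
    return generate_polymer_configuration(5, 100, target_density=1.3, seed=7)
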