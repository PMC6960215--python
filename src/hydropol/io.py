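"""Configuration readers/writers: GRO, PDB and extended XYZ.

GRO and PDB go through MDAnalysis.  Extended XYZ (``Lattice="..."`` in the
comment line) has a small dedicated parser because the lattice comment is
not understood by the MDAnalysis XYZ reader.

Role assignment is by residue name: by default SOL/HOH/WAT/SPC/TIP3 are
water (O -> WATER_O, H -> WATER_H), everything else is polymer.  Only
orthorhombic boxes are accepted; triclinic input is rejected.
"""

from __future__ import annotations

import os
import re
import warnings
from typing import Sequence

import numpy as np

from .geometry import (
    ATOMIC_MASSES,
    BONDI_RADII,
    Box,
    Configuration,
    Role,
)

__all__ = [
    "read_configuration",
    "read_configurations",
    "write_configuration",
    "DEFAULT_WATER_RESNAMES",
]

DEFAULT_WATER_RESNAMES = frozenset({"SOL", "HOH", "WAT", "SPC", "TIP3", "TIP4"})

ANGSTROM_PER_NM = 10.0


def _guess_element(name: str) -> str:
    """Element from an atom name: leading alphabetic characters, preferring
    two-letter symbols present in the mass table (Cl, Na, ...)."""
    stripped = re.sub(r"^[0-9]+", "", name.strip())
    letters = re.match(r"[A-Za-z]+", stripped)
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    s = letters.group(0)
    if len(s) >= 2 and s[:2].upper() in ATOMIC_MASSES and s[:2].upper() not in ("CA",):
        # CA in a polymer residue is almost always an aliphatic carbon
        return s[:2].capitalize()
    return s[0].upper()


def _roles_from(resnames, elements, water_resnames) -> np.ndarray:
    roles = np.full(len(elements), int(Role.POLYMER), dtype=np.int8)
    for i, (rn, el) in enumerate(zip(resnames, elements)):
        if rn.upper() in water_resnames:
            roles[i] = int(Role.WATER_O) if el.upper() == "O" else int(Role.WATER_H)
    return roles


def _check_orthorhombic(dimensions) -> Box:
    if dimensions is None or not np.all(np.asarray(dimensions[:3]) > 0):
        raise ValueError("input file has no usable box; an orthorhombic box is required")
    a, b, c, alpha, beta, gamma = [float(x) for x in dimensions]
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {alpha}, {beta}, {gamma}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return Box((a / ANGSTROM_PER_NM, b / ANGSTROM_PER_NM, c / ANGSTROM_PER_NM))


def read_configurations(
    path: str,
    *,
    water_resnames: Sequence[str] | frozenset = DEFAULT_WATER_RESNAMES,
) -> list[Configuration]:
    """Read all frames of a GRO / PDB / extended-XYZ file.

    Returns one :class:`Configuration` per frame (multi-model PDB files
    yield several).  Positions are converted to nm.
    """
    ext = os.path.splitext(path)[1].lower()
    water_resnames = frozenset(r.upper() for r in water_resnames)
    if ext in (".xyz", ".extxyz"):
        return _read_extxyz(path, water_resnames)
    if ext not in (".gro", ".pdb"):
        raise ValueError(f"unsupported configuration format {ext!r}")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    names = [a.name for a in u.atoms]
    elements = [_guess_element(n) for n in names]
    resnames = [a.resname for a in u.atoms]
    roles = _roles_from(resnames, elements, water_resnames)
    molecule_ids = np.asarray(u.atoms.resids, dtype=np.int64)
    radii, masses = _radii_and_masses(elements)

    configs = []
    for k, _ts in enumerate(u.trajectory):
        box = _check_orthorhombic(u.dimensions)
        configs.append(
            Configuration(
                positions=u.atoms.positions.astype(float) / ANGSTROM_PER_NM,
                roles=roles,
                box=box,
                elements=elements,
                vdw_radii=radii,
                masses=masses,
                molecule_ids=molecule_ids,
                frame_index=k,
            )
        )
    return configs


def _radii_and_masses(elements) -> tuple[np.ndarray, np.ndarray]:
    """Bondi radii / IUPAC masses with a carbon fallback for unknown species
    (coarse-grained bead labels etc.); the fallback is warned about once."""
    unknown = sorted({e for e in elements if e.upper() not in ATOMIC_MASSES})
    if unknown:
        warnings.warn(
            f"unknown species {unknown}: using carbon vdW radius and mass; "
            "supply per-atom values to override"
        )
    radii = np.array(
        [BONDI_RADII.get(e.upper(), BONDI_RADII["C"]) for e in elements]
    )
    masses = np.array(
        [ATOMIC_MASSES.get(e.upper(), ATOMIC_MASSES["C"]) for e in elements]
    )
    return radii, masses


def read_configuration(path: str, **kwargs) -> Configuration:
    """Read the first (usually only) frame of a configuration file."""
    return read_configurations(path, **kwargs)[0]


# ---------------------------------------------------------------------------
# extended XYZ

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _read_extxyz(path: str, water_resnames) -> list[Configuration]:
    configs: list[Configuration] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise ValueError(f"{path}: frame {frame} lacks a Lattice=\"...\" box spec")
        cell = np.array([float(x) for x in m.group(1).split()], dtype=float).reshape(3, 3)
        if not np.allclose(cell, np.diag(np.diag(cell)), atol=1e-8):
            raise ValueError(f"{path}: triclinic Lattice is not supported")
        box = Box(tuple(np.diag(cell) / ANGSTROM_PER_NM))
        elements, positions, resnames = [], [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            elements.append(parts[0])
            positions.append([float(x) for x in parts[1:4]])
            resnames.append(parts[4] if len(parts) > 4 else "UNK")
        roles = _roles_from(resnames, elements, water_resnames)
        mol_ids = _water_molecule_ids(roles)
        radii, masses = _radii_and_masses(elements)
        configs.append(
            Configuration(
                positions=np.asarray(positions) / ANGSTROM_PER_NM,
                roles=roles,
                box=box,
                elements=elements,
                vdw_radii=radii,
                masses=masses,
                molecule_ids=mol_ids,
                frame_index=frame,
            )
        )
        i += 2 + n
        frame += 1
    if not configs:
        raise ValueError(f"{path}: empty extended-XYZ file")
    return configs


def _water_molecule_ids(roles: np.ndarray) -> np.ndarray:
    """Sequential molecule ids assuming O,H,H water ordering (XYZ has no resids)."""
    ids = np.zeros(len(roles), dtype=np.int64)
    mol = 0
    for i, r in enumerate(roles):
        if r == int(Role.WATER_O):
            mol += 1
        ids[i] = mol if r != int(Role.POLYMER) else 0
    return ids


# ---------------------------------------------------------------------------
# writing


def write_configuration(config: Configuration, path: str) -> None:
    """Write a configuration to GRO, PDB or extended XYZ (by extension).

    Water molecules get residue name SOL, polymer atoms residue AGX, so
    files round-trip through :func:`read_configuration` with default
    role mapping.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".xyz", ".extxyz"):
        _write_extxyz(config, path)
        return
    if ext not in (".gro", ".pdb"):
        raise ValueError(f"unsupported output format {ext!r}")

    import MDAnalysis as mda

    n = config.n_atoms
    polymer = config.polymer_mask
    # one residue for the polymer, one per water molecule_id
    keys = [
        (0, 0) if polymer[i] else (1, int(config.molecule_ids[i]))
        for i in range(n)
    ]
    uniq = sorted(set(keys))
    uniq_index = {k: j for j, k in enumerate(uniq)}
    resindex = np.array([uniq_index[k] for k in keys])
    n_res = len(uniq)
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    names = [
        f"{config.elements[i]}{i % 1000}" if polymer[i] else
        ("OW" if config.roles[i] == int(Role.WATER_O) else "HW")
        for i in range(n)
    ]
    u.add_TopologyAttr("names", names)
    res_names = ["AGX" if k[0] == 0 else "SOL" for k in uniq]
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("elements", [e.capitalize() for e in config.elements])
    u.atoms.positions = config.positions * ANGSTROM_PER_NM
    u.dimensions = [
        config.box.lengths[0] * ANGSTROM_PER_NM,
        config.box.lengths[1] * ANGSTROM_PER_NM,
        config.box.lengths[2] * ANGSTROM_PER_NM,
        90.0,
        90.0,
        90.0,
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def _write_extxyz(config: Configuration, path: str) -> None:
    L = config.box.lengths_array * ANGSTROM_PER_NM
    lattice = f'Lattice="{L[0]} 0.0 0.0 0.0 {L[1]} 0.0 0.0 0.0 {L[2]}"'
    polymer = config.polymer_mask
    with open(path, "w") as fh:
        fh.write(f"{config.n_atoms}\n")
        fh.write(f"{lattice} Properties=species:S:1:pos:R:3\n")
        for i in range(config.n_atoms):
            x, y, z = config.positions[i] * ANGSTROM_PER_NM
            resname = "AGX" if polymer[i] else "SOL"
            fh.write(
                f"{config.elements[i]} {x:.6f} {y:.6f} {z:.6f} {resname}\n"
            )
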