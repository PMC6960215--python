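"""Periodic-box geometry and the atomistic data model.

Everything downstream (hydrogen bonds, hydration layers, surface areas)
works on a :class:`Configuration`: a flat array-of-atoms view of one frame
of a polymer + water system in an orthorhombic periodic box.  Internal
length unit is nanometre throughout; presentation layers convert to
ångström where the field quotes Å (hydration-shell distances).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Role",
    "Atom",
    "Box",
    "Configuration",
    "minimum_image_displacement",
    "minimum_image_distance",
    "moisture_content_of",
    "neighbor_pairs",
    "ATOMIC_MASSES",
    "BONDI_RADII",
    "WATER_MOLAR_MASS",
]

#: Standard atomic masses, g/mol (IUPAC 2021 conventional values).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
}

#: Bondi van der Waals radii, nm.
BONDI_RADII: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "NA": 0.227,
    "MG": 0.173,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
    "K": 0.275,
    "CA": 0.231,
}

#: Molar mass of one water molecule, g/mol (O + 2 H from the table above).
WATER_MOLAR_MASS = 18.015


class Role(enum.IntEnum):
    """What an atom is, for the purposes of the hydration analysis."""

    POLYMER = 0
    WATER_O = 1
    WATER_H = 2


@dataclass(frozen=True)
class Atom:
    """One atom: position (nm), analysis role, element and bookkeeping ids.

    ``vdw_radius`` and ``mass`` default from the Bondi and IUPAC tables by
    element; both can be overridden per atom (coarse-grained beads must
    override, since a bead is not an element).
    """

    position: tuple[float, float, float]
    role: Role
    element: str = "C"
    vdw_radius: float | None = None
    molecule_id: int = 0
    mass: float | None = None

    def resolved_radius(self) -> float:
        r = self.vdw_radius
        if r is None:
            r = BONDI_RADII.get(self.element.upper())
        if r is None or r <= 0:
            raise ValueError(
                f"no positive vdW radius for element {self.element!r}; "
                "supply vdw_radius explicitly"
            )
        return float(r)

    def resolved_mass(self) -> float:
        m = self.mass
        if m is None:
            m = ATOMIC_MASSES.get(self.element.upper())
        if m is None or m <= 0:
            raise ValueError(
                f"no positive mass for element {self.element!r}; "
                "supply mass explicitly"
            )
        return float(m)


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with per-axis periodicity flags."""

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        L = np.asarray(self.lengths, dtype=float)
        if L.shape != (3,):
            raise ValueError("box lengths must be a 3-vector")
        if not np.all(np.isfinite(L)) or np.any(L <= 0):
            raise ValueError(f"box lengths must be positive and finite, got {self.lengths}")
        object.__setattr__(self, "lengths", tuple(float(x) for x in L))
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))

    @property
    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def fully_periodic(self) -> bool:
        return all(self.periodic)

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) on periodic axes."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        L = self.lengths_array
        for ax in range(3):
            if self.periodic[ax]:
                pts[:, ax] %= L[ax]
        return pts if np.asarray(points).ndim == 2 else pts[0]


def _check_finite(p: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} contains non-finite coordinates (corrupt input?)")


def minimum_image_displacement(
    p1: np.ndarray, p2: np.ndarray, box: Box
) -> np.ndarray:
    """Shortest displacement vector(s) p2 - p1 over all periodic images.

    Broadcasts over leading axes; the last axis must be length 3.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    _check_finite(a, "p1")
    _check_finite(b, "p2")
    d = b - a
    L = box.lengths_array
    for ax in range(3):
        if box.periodic[ax]:
            d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
    return d


def minimum_image_distance(p1, p2, box: Box) -> float:
    """Shortest distance between two points under the minimum-image convention."""
    d = minimum_image_displacement(p1, p2, box)
    return float(np.linalg.norm(d, axis=-1))


class Configuration:
    """One frame of a polymer + water system.

    Stores per-atom arrays (positions nm, roles, elements, vdW radii nm,
    masses g/mol, molecule ids) plus the periodic box.  ``moisture_content``
    is always computed from the atom masses, so it cannot drift from the
    atomistic content.
    """

    def __init__(
        self,
        positions: np.ndarray,
        roles: np.ndarray,
        box: Box,
        *,
        elements: Sequence[str] | None = None,
        vdw_radii: np.ndarray | None = None,
        masses: np.ndarray | None = None,
        molecule_ids: np.ndarray | None = None,
        frame_index: int = 0,
        wrap: bool = True,
    ) -> None:
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        _check_finite(positions, "positions")
        n = len(positions)
        roles = np.asarray(roles, dtype=np.int8).reshape(n)
        if elements is None:
            elements = ["C"] * n
        elements = [str(e) for e in elements]
        if len(elements) != n:
            raise ValueError("elements length mismatch")

        if vdw_radii is None:
            vdw_radii = np.array(
                [_lookup(BONDI_RADII, e, "vdW radius") for e in elements]
            )
        vdw_radii = np.asarray(vdw_radii, dtype=float).reshape(n)
        if np.any(vdw_radii <= 0):
            raise ValueError("all vdW radii must be positive")

        if masses is None:
            masses = np.array([_lookup(ATOMIC_MASSES, e, "mass") for e in elements])
        masses = np.asarray(masses, dtype=float).reshape(n)
        if np.any(masses <= 0):
            raise ValueError("all masses must be positive")

        if molecule_ids is None:
            molecule_ids = np.zeros(n, dtype=np.int64)
        molecule_ids = np.asarray(molecule_ids, dtype=np.int64).reshape(n)

        self.box = box
        self.positions = box.wrap(positions) if wrap else positions
        self.roles = roles
        self.elements = elements
        self.vdw_radii = vdw_radii
        self.masses = masses
        self.molecule_ids = molecule_ids
        self.frame_index = int(frame_index)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_atoms(
        cls, atoms: Iterable[Atom], box: Box, frame_index: int = 0
    ) -> "Configuration":
        atoms = list(atoms)
        return cls(
            positions=np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            roles=np.array([int(a.role) for a in atoms], dtype=np.int8),
            box=box,
            elements=[a.element for a in atoms],
            vdw_radii=np.array([a.resolved_radius() for a in atoms]),
            masses=np.array([a.resolved_mass() for a in atoms]),
            molecule_ids=np.array([a.molecule_id for a in atoms], dtype=np.int64),
            frame_index=frame_index,
        )

    def iter_atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                position=tuple(self.positions[i]),
                role=Role(int(self.roles[i])),
                element=self.elements[i],
                vdw_radius=float(self.vdw_radii[i]),
                molecule_id=int(self.molecule_ids[i]),
                mass=float(self.masses[i]),
            )

    # -- masks ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def polymer_mask(self) -> np.ndarray:
        return self.roles == int(Role.POLYMER)

    @property
    def water_mask(self) -> np.ndarray:
        return self.roles != int(Role.POLYMER)

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == int(Role.WATER_O))

    @property
    def water_hydrogen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == int(Role.WATER_H))

    @property
    def n_water_molecules(self) -> int:
        return int(len(self.water_oxygen_indices))

    # -- masses --------------------------------------------------------
    @property
    def polymer_mass(self) -> float:
        return float(self.masses[self.polymer_mask].sum())

    @property
    def water_mass(self) -> float:
        return float(self.masses[self.water_mask].sum())

    @property
    def moisture_content(self) -> float:
        return moisture_content_of(self)

    # -- transforms ----------------------------------------------------
    def translated(self, shift) -> "Configuration":
        """Rigidly translated copy (re-wrapped into the box)."""
        return Configuration(
            self.positions + np.asarray(shift, dtype=float),
            self.roles.copy(),
            self.box,
            elements=list(self.elements),
            vdw_radii=self.vdw_radii.copy(),
            masses=self.masses.copy(),
            molecule_ids=self.molecule_ids.copy(),
            frame_index=self.frame_index,
        )

    def subset(self, mask: np.ndarray) -> "Configuration":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return Configuration(
            self.positions[idx],
            self.roles[idx],
            self.box,
            elements=[self.elements[i] for i in idx],
            vdw_radii=self.vdw_radii[idx],
            masses=self.masses[idx],
            molecule_ids=self.molecule_ids[idx],
            frame_index=self.frame_index,
            wrap=False,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Configuration(n_atoms={self.n_atoms}, "
            f"n_water={self.n_water_molecules}, m={self.moisture_content:.4f}, "
            f"box={self.box.lengths})"
        )


def _lookup(table: dict[str, float], element: str, what: str) -> float:
    try:
        return table[element.upper()]
    except KeyError:
        raise KeyError(
            f"no tabulated {what} for element {element!r}; supply it explicitly"
        ) from None


def moisture_content_of(config: Configuration) -> float:
    """Moisture content m = (water mass)/(dry polymer mass).

    Dimensionless mass ratio; multiply by 100 for wt%.
    """
    mp = config.polymer_mass
    if mp <= 0:
        raise ValueError("configuration has no polymer mass; m is undefined")
    return config.water_mass / mp


def neighbor_pairs(
    points: np.ndarray, cutoff: float, box: Box
) -> np.ndarray:
    """Index pairs (i < j) with minimum-image distance < cutoff.

    Uses a periodic KD-tree when the box is fully periodic, otherwise an
    O(n^2) sweep (non-periodic boxes only arise for small imported systems).
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    if box.fully_periodic:
        L = box.lengths_array
        if cutoff >= L.min() / 2:
            # KD-tree periodic queries are only valid below half the box edge
            return _brute_pairs(pts, cutoff, box)
        tree = cKDTree(np.mod(pts, L), boxsize=L)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs.astype(np.int64)
    return _brute_pairs(pts, cutoff, box)


def _brute_pairs(pts: np.ndarray, cutoff: float, box: Box) -> np.ndarray:
    d = minimum_image_displacement(pts[:, None, :], pts[None, :, :], box)
    dist = np.linalg.norm(d, axis=-1)
    iu, ju = np.triu_indices(len(pts), k=1)
    keep = dist[iu, ju] < cutoff
    return np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)
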