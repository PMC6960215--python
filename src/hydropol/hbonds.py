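"""Geometric hydrogen-bond detection and class-resolved densities.

A hydrogen bond is declared for a (donor O–H, acceptor O) triple when the
donor-oxygen–acceptor-oxygen distance r is below ``r_max`` (default
0.35 nm) and the angle α at the donor oxygen — between the O→acceptor-O
and O→H vectors — is below ``alpha_max`` (default 30°).  Note the angle
is oxygen-centred, not the H-centred angle many trajectory tools use.

Both polymer hydroxyl/acid oxygens and water oxygens may donate and
accept; a hydrogen is donatable when it is covalently bound to an oxygen
(O–H distance < 0.12 nm when no explicit topology is supplied).  One
hydrogen may bond to several acceptors; every qualifying triple counts.

Densities are bond counts normalised by the dry-material volume V0, so
curves at different moisture contents share a common denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import Box, Configuration, Role, minimum_image_displacement, neighbor_pairs

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "PairClass",
    "build_donor_map",
    "detect_hbonds",
    "hbond_density",
]

#: Covalent O–H bond cutoff used to infer donatable hydrogens, nm.
COVALENT_OH_CUTOFF = 0.12


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: O–O distance (nm) and donor-O-centred angle (deg)."""

    r_max: float = 0.35
    alpha_max: float = 30.0

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not 0 < self.alpha_max < 180:
            raise ValueError("alpha_max must lie in (0, 180) degrees")


class PairClass(str, enum.Enum):
    POLYMER_POLYMER = "polymer_polymer"
    POLYMER_WATER = "polymer_water"
    WATER_WATER = "water_water"


@dataclass(frozen=True)
class HBondRecord:
    donor_O: int
    donor_H: int
    acceptor_O: int
    pair_class: PairClass
    r: float
    alpha: float


def _oxygen_indices(config: Configuration) -> np.ndarray:
    return np.flatnonzero(
        [
            e.upper() == "O" or r == int(Role.WATER_O)
            for e, r in zip(config.elements, config.roles)
        ]
    )


def _hydrogen_indices(config: Configuration) -> np.ndarray:
    return np.flatnonzero(
        [
            e.upper() == "H" or r == int(Role.WATER_H)
            for e, r in zip(config.elements, config.roles)
        ]
    )


def build_donor_map(
    config: Configuration, oh_cutoff: float = COVALENT_OH_CUTOFF
) -> dict[int, int]:
    """Map each donatable hydrogen index to its covalently bound oxygen.

    The bound oxygen is the nearest oxygen of the same molecule within
    ``oh_cutoff`` (minimum image), falling back to the nearest oxygen of
    any molecule; hydrogens with no oxygen that close are not donors
    (e.g. CH hydrogens) and are simply omitted.
    """
    o_idx = _oxygen_indices(config)
    h_idx = _hydrogen_indices(config)
    donor_map: dict[int, int] = {}
    if len(o_idx) == 0 or len(h_idx) == 0:
        return donor_map
    d = minimum_image_displacement(
        config.positions[h_idx][:, None, :],
        config.positions[o_idx][None, :, :],
        config.box,
    )
    dist = np.linalg.norm(d, axis=-1)
    o_mol = config.molecule_ids[o_idx]
    for k, h in enumerate(h_idx):
        same = dist[k].copy()
        same[o_mol != config.molecule_ids[h]] = np.inf
        col = int(np.argmin(same))
        if not np.isfinite(same[col]) or same[col] >= oh_cutoff:
            col = int(np.argmin(dist[k]))  # fall back across molecules
        if dist[k, col] < oh_cutoff:
            donor_map[int(h)] = int(o_idx[col])
    return donor_map


def _pair_class(role_a: int, role_b: int) -> PairClass:
    a_water = role_a != int(Role.POLYMER)
    b_water = role_b != int(Role.POLYMER)
    if a_water and b_water:
        return PairClass.WATER_WATER
    if a_water or b_water:
        return PairClass.POLYMER_WATER
    return PairClass.POLYMER_POLYMER


def detect_hbonds(
    config: Configuration,
    criteria: HBondCriteria = HBondCriteria(),
    donor_map: Mapping[int, int] | None = None,
) -> list[HBondRecord]:
    """All hydrogen bonds of a configuration under the geometric criteria.

    Uses a periodic neighbour search over oxygen pairs, then tests the
    donor-oxygen-centred angle for every hydrogen covalently bound to
    either oxygen of a candidate pair.  Each physical (donor O, H,
    acceptor O) triple is reported once.
    """
    if donor_map is None:
        donor_map = build_donor_map(config)
    else:
        for h, o in donor_map.items():
            if not (0 <= o < config.n_atoms) or not (0 <= h < config.n_atoms):
                raise ValueError(f"donor map entry H{h}->O{o} is out of range")
            if config.elements[o].upper() != "O" and config.roles[o] != int(Role.WATER_O):
                raise ValueError(f"donor map maps H{h} to non-oxygen atom {o}")

    # hydrogens grouped by their oxygen
    h_by_o: dict[int, list[int]] = {}
    for h, o in donor_map.items():
        h_by_o.setdefault(o, []).append(h)

    o_idx = _oxygen_indices(config)
    if len(o_idx) < 2:
        return []
    pos = config.positions
    box = config.box
    pairs = neighbor_pairs(pos[o_idx], criteria.r_max, box)
    cos_max = np.cos(np.deg2rad(criteria.alpha_max))

    records: list[HBondRecord] = []
    for a_loc, b_loc in pairs:
        oa, ob = int(o_idx[a_loc]), int(o_idx[b_loc])
        d_ab = minimum_image_displacement(pos[oa], pos[ob], box)
        r = float(np.linalg.norm(d_ab))
        if r >= criteria.r_max or r == 0.0:
            continue
        for donor, acceptor, d_da in ((oa, ob, d_ab), (ob, oa, -d_ab)):
            for h in h_by_o.get(donor, ()):
                d_dh = minimum_image_displacement(pos[donor], pos[h], box)
                nh = np.linalg.norm(d_dh)
                if nh == 0:
                    continue
                cosa = float(np.dot(d_da, d_dh) / (r * nh))
                cosa = max(-1.0, min(1.0, cosa))
                if cosa > cos_max:
                    records.append(
                        HBondRecord(
                            donor_O=donor,
                            donor_H=int(h),
                            acceptor_O=acceptor,
                            pair_class=_pair_class(
                                int(config.roles[donor]), int(config.roles[acceptor])
                            ),
                            r=r,
                            alpha=float(np.rad2deg(np.arccos(cosa))),
                        )
                    )
    return records


def hbond_density(
    bonds: Sequence[HBondRecord] | Sequence[Sequence[HBondRecord]],
    pair_class: PairClass,
    V0: float,
) -> float:
    """Bond count of one class per unit dry volume (nm^-3).

    ``bonds`` is either one frame's records or a sequence of per-frame
    record lists, in which case the time-averaged count is used.
    """
    if V0 <= 0:
        raise ValueError("dry volume V0 must be positive")
    bonds = list(bonds)
    if bonds and isinstance(bonds[0], HBondRecord):
        frames: list[Sequence[HBondRecord]] = [bonds]  # type: ignore[list-item]
    else:
        frames = [list(f) for f in bonds]  # type: ignore[union-attr]
        if not frames:
            frames = [[]]
    counts = [sum(1 for b in frame if b.pair_class == pair_class) for frame in frames]
    return float(np.mean(counts)) / V0
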