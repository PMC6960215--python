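"""Rolling-ball (Shrake–Rupley) surface areas under periodic boundaries.

The accessible surface of a group of atoms is sampled by distributing
quasi-uniform points (golden-spiral construction, deterministic) on each
atom's expanded sphere of radius r_vdw + probe and testing each point for
burial inside any other expanded sphere, including periodic images.  The
polymer–water contact area is the inclusion–exclusion combination

    A_contact = A_polymer + A_water − A_system ,

which vanishes when the two groups do not touch and saturates when newly
added water no longer creates polymer–water interface.

The probe radius defaults to 0.1 nm (1 Å), the rolling-ball radius used
for hydrated-polysaccharide contact-area analysis, rather than the
conventional 0.14 nm water probe; both are free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Box, Configuration, minimum_image_displacement

__all__ = [
    "SurfaceAreas",
    "sphere_points",
    "shrake_rupley_area",
    "contact_area",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_SPHERE_POINTS",
]

DEFAULT_PROBE_RADIUS = 0.1
DEFAULT_SPHERE_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors via the golden-spiral lattice."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_area(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    box: Box | None = None,
) -> float:
    """Total accessible area (nm²) of a group of spheres.

    A point on atom i's expanded sphere (radius r_i + probe) is exposed if
    it lies outside every other atom's expanded sphere; distances use the
    minimum image when ``box`` is periodic.  Area is
    Σ_i 4π(r_i+probe)² · exposed_fraction_i.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if n_sphere_points < 12:
        raise ValueError("n_sphere_points must be at least 12")
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n == 0:
        warnings.warn("surface area of an empty atom group is 0")
        return 0.0
    R = np.asarray(radii, dtype=float).reshape(n) + probe_radius
    if np.any(R <= 0):
        raise ValueError("expanded radii must be positive")

    unit = sphere_points(n_sphere_points)
    neighbors = _neighbor_lists(pos, R, box)

    total = 0.0
    for i in range(n):
        pts = pos[i] + R[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors[i]:
            if not exposed.any():
                break
            if box is not None:
                d = minimum_image_displacement(pts[exposed], pos[j], box)
            else:
                d = pos[j] - pts[exposed]
            buried = np.einsum("ij,ij->i", d, d) < R[j] ** 2
            idx = np.flatnonzero(exposed)
            exposed[idx[buried]] = False
        total += 4.0 * np.pi * R[i] ** 2 * exposed.mean()
    return float(total)


def _neighbor_lists(pos: np.ndarray, R: np.ndarray, box: Box | None):
    """Per-atom candidate occluders: atoms within R_i + R_j."""
    from scipy.spatial import cKDTree

    n = len(pos)
    rmax = float(R.max())
    cutoff = 2.0 * rmax
    if box is not None and box.fully_periodic and cutoff < min(box.lengths) / 2:
        L = box.lengths_array
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    elif box is None:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    else:
        disp = minimum_image_displacement(pos[:, None, :], pos[None, :, :], box)
        dist = np.linalg.norm(disp, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        keep = dist[iu, ju] < cutoff
        pairs = np.stack([iu[keep], ju[keep]], axis=1)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        # only pairs whose expanded spheres can actually intersect matter,
        # but the loose 2*rmax cutoff is cheap and safe
        neighbors[int(i)].append(int(j))
        neighbors[int(j)].append(int(i))
    return neighbors


@dataclass(frozen=True)
class SurfaceAreas:
    """Group areas (nm²) and the contact area they imply."""

    A_polymer: float
    A_water: float
    A_system: float
    probe_radius: float
    n_sphere_points: int

    @property
    def A_contact(self) -> float:
        return self.A_polymer + self.A_water - self.A_system

    def to_dict(self) -> dict:
        return {
            "A_polymer_nm2": self.A_polymer,
            "A_water_nm2": self.A_water,
            "A_system_nm2": self.A_system,
            "A_contact_nm2": self.A_contact,
            "probe_radius_nm": self.probe_radius,
            "n_sphere_points": self.n_sphere_points,
        }


def contact_area(
    config: Configuration,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> SurfaceAreas:
    """Polymer, water and whole-system areas plus their contact area."""
    box = config.box
    polymer = config.subset(config.polymer_mask)
    water = config.subset(config.water_mask)

    def area(c: Configuration) -> float:
        if c.n_atoms == 0:
            return 0.0
        return shrake_rupley_area(
            c.positions, c.vdw_radii, probe_radius, n_sphere_points, box
        )

    A_p = area(polymer)
    A_w = area(water)
    A_s = shrake_rupley_area(
        config.positions, config.vdw_radii, probe_radius, n_sphere_points, box
    ) if config.n_atoms else 0.0
    return SurfaceAreas(A_p, A_w, A_s, probe_radius, n_sphere_points)
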