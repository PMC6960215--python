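"""Rolling-ball surface areas: analytic cases, oracle, convergence."""

import numpy as np
import pytest

from hydropol.geometry import Atom, Box, Role, minimum_image_displacement
from hydropol.sasa import contact_area, shrake_rupley_area, sphere_points
from tests.conftest import config_from_atoms, water_molecule

BOX = Box((10.0, 10.0, 10.0))


def dense_point_oracle(positions, radii, probe, box, n_points=20000, seed=0):
    """Independent Monte-Carlo implementation: random (not lattice) points."""
    rng = np.random.default_rng(seed)
    pos = np.asarray(positions, dtype=float)
    R = np.asarray(radii, dtype=float) + probe
    total = 0.0
    for i in range(len(pos)):
        u = rng.normal(size=(n_points, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts = pos[i] + R[i] * u
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(pos)):
            if j == i:
                continue
            d = minimum_image_displacement(pts, pos[j], box)
            exposed &= np.einsum("ij,ij->i", d, d) >= R[j] ** 2
        total += 4 * np.pi * R[i] ** 2 * exposed.mean()
    return total


def test_sphere_points_are_unit_and_spread():
    pts = sphere_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-2  # balanced lattice


class TestSingleSphere:
    def test_analytic_area(self):
        area = shrake_rupley_area(
            [[5, 5, 5]], [0.15], probe_radius=0.1, n_sphere_points=960, box=BOX
        )
        assert area == pytest.approx(4 * np.pi * 0.25**2, rel=1e-12)
        assert area == pytest.approx(0.7854, abs=1e-4)

    @pytest.mark.parametrize("n_points, rtol", [(960, 0.01), (10000, 0.001)])
    def test_precision_scaling(self, n_points, rtol):
        # exactness holds trivially for one atom; perturb with a barely
        # overlapping neighbour so quadrature error is exercised
        area = shrake_rupley_area(
            [[5, 5, 5], [5.49, 5, 5]], [0.15, 0.15], 0.1, n_points, BOX
        )
        oracle = dense_point_oracle(
            [[5, 5, 5], [5.49, 5, 5]], [0.15, 0.15], 0.1, BOX, n_points=200000
        )
        assert area == pytest.approx(oracle, rel=rtol)


class TestMultiSphere:
    def test_disjoint_additivity(self):
        one = shrake_rupley_area([[2, 2, 2]], [0.15], 0.1, 960, BOX)
        two = shrake_rupley_area(
            [[2, 2, 2], [7, 7, 7]], [0.15, 0.15], 0.1, 960, BOX
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_fully_buried_atom(self):
        # central atom caged by 26 overlapping neighbours on a cubic shell
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        pos = [[5, 5, 5]] + [[5 + 0.12 * i, 5 + 0.12 * j, 5 + 0.12 * k]
                             for i, j, k in offsets]
        radii = [0.05] + [0.15] * 26
        area_all = shrake_rupley_area(pos, radii, 0.05, 960, BOX)
        area_shell = shrake_rupley_area(pos[1:], radii[1:], 0.05, 960, BOX)
        assert area_all == pytest.approx(area_shell, rel=1e-12)  # core adds 0

    def test_periodic_wrap_invariance(self):
        pos = np.array([[0.05, 5, 5], [9.95, 5, 5]])  # overlap across the face
        a = shrake_rupley_area(pos, [0.15, 0.15], 0.1, 960, BOX)
        b = shrake_rupley_area(pos + 3.21, [0.15, 0.15], 0.1, 960, BOX)
        assert a == pytest.approx(b, rel=1e-12)
        isolated = 2 * shrake_rupley_area([[5, 5, 5]], [0.15], 0.1, 960, BOX)
        assert a < isolated  # images do occlude

    def test_convergence_960_vs_3840(self, hydrated_small):
        sub = hydrated_small.subset(np.arange(60))
        a = shrake_rupley_area(sub.positions, sub.vdw_radii, 0.1, 960, sub.box)
        b = shrake_rupley_area(sub.positions, sub.vdw_radii, 0.1, 3840, sub.box)
        assert a == pytest.approx(b, rel=0.01)

    def test_oracle_equivalence_small_system(self):
        rng = np.random.default_rng(8)
        pos = 4.0 + rng.random((30, 3)) * 1.2
        radii = rng.uniform(0.12, 0.2, 30)
        mine = shrake_rupley_area(pos, radii, 0.1, 3840, BOX)
        oracle = dense_point_oracle(pos, radii, 0.1, BOX, n_points=60000)
        assert mine == pytest.approx(oracle, rel=0.005)

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning):
            assert shrake_rupley_area(np.empty((0, 3)), np.empty(0), 0.1, 960, BOX) == 0.0


class TestContactArea:
    def test_disjoint_groups_zero_contact(self):
        atoms = [Atom((1.0, 1, 1), Role.POLYMER, "C", molecule_id=0)]
        atoms += water_molecule((6.0, 6, 6), (6.1, 6, 6), (6, 6.1, 6), 1)
        areas = contact_area(config_from_atoms(atoms, (10, 10, 10)))
        assert areas.A_contact == pytest.approx(0.0, abs=1e-9)
        assert areas.A_system == pytest.approx(
            areas.A_polymer + areas.A_water, rel=1e-12
        )

    def test_water_free_configuration(self, polymer_small):
        areas = contact_area(polymer_small, n_sphere_points=96)
        assert areas.A_water == 0.0
        assert areas.A_contact == pytest.approx(0.0, abs=1e-9)

    def test_contact_area_nonnegative_on_mixed_system(self, hydrated_small):
        sub_mask = np.zeros(hydrated_small.n_atoms, dtype=bool)
        sub_mask[:80] = True  # polymer beads
        sub_mask[-90:] = True  # 30 waters
        cfg = hydrated_small.subset(sub_mask)
        areas = contact_area(cfg, n_sphere_points=240)
        assert areas.A_contact >= -1e-6
        assert areas.A_contact > 0  # these waters sit on the polymer

def _merge(a, b_waters):
    """Configuration holding a's atoms plus b's water atoms."""
    from hydropol.geometry import Configuration

    wm = b_waters.water_mask
    idx = np.flatnonzero(wm)
    return Configuration(
        np.vstack([a.positions, b_waters.positions[idx]]),
        np.concatenate([a.roles, b_waters.roles[idx]]),
        a.box,
        elements=list(a.elements) + [b_waters.elements[i] for i in idx],
        vdw_radii=np.concatenate([a.vdw_radii, b_waters.vdw_radii[idx]]),
        masses=np.concatenate([a.masses, b_waters.masses[idx]]),
        molecule_ids=np.concatenate(
            [a.molecule_ids, b_waters.molecule_ids[idx] + a.molecule_ids.max() + 1]
        ),
    )


def test_contact_area_growth_then_plateau(polymer_small):
    """Contact area grows while new water binds the polymer (first shell
    filling) and stops growing when additional water only joins the far
    shell — the saturation signature of double-layer adsorption."""
    from hydropol.synthetic import ShellMixtureParams, generate_hydrated_configuration

    near = ShellMixtureParams(0.28, 0.04, 0.60, 0.08, weight1=1.0)
    far = ShellMixtureParams(0.28, 0.04, 0.70, 0.03, weight1=0.0)
    areas = []
    for m in (0.05, 0.15):
        hyd = generate_hydrated_configuration(polymer_small, m, near, seed=6)
        areas.append(contact_area(hyd, n_sphere_points=240).A_contact)
    assert 0 < areas[0] < areas[1]  # filling the first shell grows contact

    base = generate_hydrated_configuration(polymer_small, 0.15, near, seed=6)
    extra_far = generate_hydrated_configuration(polymer_small, 0.10, far, seed=9)
    merged = _merge(base, extra_far)
    a_base = contact_area(base, n_sphere_points=240).A_contact
    a_plateau = contact_area(merged, n_sphere_points=240).A_contact
    assert a_plateau == pytest.approx(a_base, rel=0.05)  # far water adds none
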