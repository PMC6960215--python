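"""The synthetic-data generators: determinism, density, shell structure."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from hydropol.curves import WATER_MOLECULAR_VOLUME_NM3
from hydropol.geometry import WATER_MOLAR_MASS, Role
from hydropol.layers import assign_layers, polymer_water_distances
from hydropol.synthetic import (
    AVOGADRO,
    NM3_PER_CM3,
    HydrationReport,
    PackingError,
    ShellMixtureParams,
    generate_fraction_schedule,
    generate_hydrated_configuration,
    generate_linear_series,
    generate_polymer_configuration,
    generate_property_curve,
)


def measured_density(cfg) -> float:
    """g/cm^3 from total mass and box volume."""
    grams = cfg.masses.sum() / AVOGADRO
    return grams / (cfg.box.volume / NM3_PER_CM3)


class TestPolymerGenerator:
    def test_density_matches_target(self, polymer_standard):
        assert measured_density(polymer_standard) == pytest.approx(1.3, rel=1e-3)
        assert polymer_standard.n_atoms == 500
        assert np.all(polymer_standard.roles == int(Role.POLYMER))

    def test_deterministic_for_fixed_seed(self):
        a = generate_polymer_configuration(2, 30, seed=42)
        b = generate_polymer_configuration(2, 30, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        c = generate_polymer_configuration(2, 30, seed=43)
        assert not np.array_equal(a.positions, c.positions)

    def test_halving_density_scales_edge_by_cbrt2(self):
        a = generate_polymer_configuration(2, 30, target_density=1.3, seed=1)
        b = generate_polymer_configuration(2, 30, target_density=0.65, seed=1)
        assert b.box.lengths[0] / a.box.lengths[0] == pytest.approx(
            2 ** (1 / 3), rel=1e-12
        )

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_polymer_configuration(5, 100, target_density=40.0, seed=0)

    def test_bonded_beads_at_bond_length(self, polymer_small):
        from hydropol.geometry import minimum_image_distance

        ids = polymer_small.molecule_ids
        same = np.flatnonzero(ids[:-1] == ids[1:])
        for i in same[:20]:
            d = minimum_image_distance(
                polymer_small.positions[i],
                polymer_small.positions[i + 1],
                polymer_small.box,
            )
            assert d == pytest.approx(0.4, abs=1e-9)


class TestHydrationGenerator:
    def test_zero_moisture_returns_polymer(self, polymer_small):
        assert generate_hydrated_configuration(polymer_small, 0.0) is polymer_small

    def test_moisture_content_within_one_molecule(self, polymer_small):
        m = 0.21
        hyd = generate_hydrated_configuration(polymer_small, m, seed=3)
        tol = WATER_MOLAR_MASS / polymer_small.polymer_mass
        assert abs(hyd.moisture_content - m) <= tol

    def test_deterministic(self, polymer_small):
        a = generate_hydrated_configuration(polymer_small, 0.1, seed=9)
        b = generate_hydrated_configuration(polymer_small, 0.1, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_water_topology(self, hydrated_small):
        wo = hydrated_small.water_oxygen_indices
        wh = hydrated_small.water_hydrogen_indices
        assert len(wh) == 2 * len(wo)
        # each water molecule id owns exactly one O and two H
        for i in wo[:10]:
            mid = hydrated_small.molecule_ids[i]
            members = np.flatnonzero(hydrated_small.molecule_ids == mid)
            roles = sorted(hydrated_small.roles[members])
            assert roles == [int(Role.WATER_O), int(Role.WATER_H), int(Role.WATER_H)]

    def test_degenerate_mixture_all_in_first_layer(self, polymer_small):
        shells = ShellMixtureParams(0.28, 0.003, 0.56, 0.15, weight1=1.0)
        hyd = generate_hydrated_configuration(polymer_small, 0.1, shells, seed=2)
        d = polymer_water_distances(hyd)
        part = assign_layers(d)
        assert part.n_w2 == 0 and part.n_beyond == 0
        assert part.n_w1 == hyd.n_water_molecules

    def test_realized_distances_follow_requested_mixture(self, polymer_standard):
        """KS distance between realized d_pw and the requested mixture is
        small once truncation (unreachable voids) is accounted for."""
        shells = ShellMixtureParams()
        rep = HydrationReport()
        hyd = generate_hydrated_configuration(
            polymer_standard, 0.3, shells, seed=17, report=rep
        )
        d = polymer_water_distances(hyd)
        ref = np.abs(shells.sample(np.random.default_rng(123), 100_000))
        cap = d.max() + 1e-9  # geometric truncation of the far tail
        stat = ks_2samp(d, ref[ref <= cap]).statistic
        assert stat < 0.06
        assert rep.n_redrawn < 0.05 * rep.n_water


class TestFractionSchedule:
    def test_endpoints_and_saturation(self):
        m = np.linspace(0.0, 0.6, 25)
        s = generate_fraction_schedule(m, m_sat=0.3, f_w1_max=0.2)
        assert (s.f_p[0], s.f_w1[0], s.f_w2[0]) == (1.0, 0.0, 0.0)
        i_sat = np.argmin(np.abs(m - 0.3))
        assert s.f_w1[i_sat] == pytest.approx(0.2, abs=1e-12)
        assert np.all(np.abs(s.f_p + s.f_w1 + s.f_w2 - 1) < 1e-9)

    def test_first_layer_monotone_then_constant(self):
        m = np.linspace(0.0, 0.6, 49)
        s = generate_fraction_schedule(m, 0.3, 0.2)
        assert np.all(np.diff(s.f_w1) >= -1e-15)
        after = s.f_w1[m >= 0.3]
        np.testing.assert_allclose(after, after[0], atol=1e-12)

    def test_unphysical_schedule_raises(self):
        with pytest.raises(ValueError):
            generate_fraction_schedule(np.linspace(0, 0.3, 10), 0.3, f_w1_max=0.9)
        with pytest.raises(ValueError, match="increasing"):
            generate_fraction_schedule([0.2, 0.1], 0.3, 0.2)


class TestPropertyCurves:
    def setup_method(self):
        self.sched = generate_fraction_schedule(np.linspace(0, 0.6, 25), 0.3, 0.2)

    def test_noise_free_matches_model_and_round_trips(self):
        from hydropol.composite import composite_predict, fit_composite

        for kind, X in [("mixture", (2.6, 4.6, 4.4)), ("series", (4.0, 2.0, 2.0))]:
            curve = generate_property_curve(kind, *X, self.sched, noise_sd=0.0)
            expected = composite_predict(
                kind, *X, self.sched.f_p, self.sched.f_w1, self.sched.f_w2
            )
            np.testing.assert_allclose(curve.values, expected, rtol=1e-12)
            fit = fit_composite(kind, curve)
            np.testing.assert_allclose(fit.params, X, rtol=1e-7)

    def test_series_with_zero_property_raises(self):
        with pytest.raises(ValueError):
            generate_property_curve("series", 4.0, 0.0, 2.0, self.sched)

    def test_noise_is_seeded(self):
        a = generate_property_curve("mixture", 3, 2, 1, self.sched, 0.1, seed=5)
        b = generate_property_curve("mixture", 3, 2, 1, self.sched, 0.1, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


def test_linear_series():
    x, y = generate_linear_series(0.0, 2.5, np.arange(5), noise_sd=0.0)
    np.testing.assert_allclose(y, 2.5)
    x, y = generate_linear_series(1.7, -0.2, np.linspace(0, 1, 20), noise_sd=0.0)
    slope = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(1.7, rel=1e-12)
    _, y1 = generate_linear_series(1.0, 0.0, np.arange(9), 0.3, seed=8)
    _, y2 = generate_linear_series(1.0, 0.0, np.arange(9), 0.3, seed=8)
    np.testing.assert_array_equal(y1, y2)
    with pytest.raises(ValueError):
        generate_linear_series(1.0, 0.0, [], 0.0)
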