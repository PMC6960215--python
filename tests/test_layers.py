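"""Hydration-layer statistics: d_pw, histograms, DGD, partitions, fractions."""

import numpy as np
import pytest

from hydropol.geometry import Atom, Role
from hydropol.layers import (
    DistanceHistogram,
    assign_layers,
    fit_double_gaussian,
    layer_volume_fractions,
    polymer_water_distances,
    population_histogram,
)
from tests.conftest import config_from_atoms, water_molecule


def _simple_config(polymer_positions, water_o_positions, box=(5, 5, 5)):
    atoms = [
        Atom(tuple(p), Role.POLYMER, "C", molecule_id=0) for p in polymer_positions
    ]
    for k, o in enumerate(water_o_positions):
        o = np.asarray(o, dtype=float)
        atoms += water_molecule(o, o + (0.1, 0, 0), o + (0, 0.1, 0), k + 1)
    return config_from_atoms(atoms, box)


class TestDistances:
    def test_nearest_of_two(self):
        cfg = _simple_config([(0, 0, 0), (0.5, 0, 0)], [(1.0, 0, 0)])
        assert polymer_water_distances(cfg)[0] == pytest.approx(0.5, abs=1e-12)

    def test_coincident_is_zero(self):
        cfg = _simple_config([(1.0, 1.0, 1.0)], [(1.0, 1.0, 1.0)])
        assert polymer_water_distances(cfg)[0] == pytest.approx(0.0, abs=1e-12)

    def test_minimum_image_applies(self):
        cfg = _simple_config([(4.9, 0, 0)], [(0.05, 0, 0)])
        assert polymer_water_distances(cfg)[0] == pytest.approx(0.15, abs=1e-9)

    def test_requires_polymer(self):
        cfg = config_from_atoms(water_molecule((1, 1, 1), (1.1, 1, 1), (1, 1.1, 1), 1))
        with pytest.raises(ValueError, match="polymer"):
            polymer_water_distances(cfg)

    def test_heavy_atom_restriction(self):
        atoms = [
            Atom((1.0, 1, 1), Role.POLYMER, "H", molecule_id=0),
            Atom((2.0, 1, 1), Role.POLYMER, "O", molecule_id=0),
        ]
        o = np.array([1.3, 1, 1])
        atoms += water_molecule(o, o + (0.1, 0, 0), o + (0, 0.1, 0), 1)
        cfg = config_from_atoms(atoms)
        assert polymer_water_distances(cfg)[0] == pytest.approx(0.3)
        assert polymer_water_distances(cfg, include_hydrogens=False)[0] == (
            pytest.approx(0.7)
        )

    def test_translation_invariance_of_partition(self, hydrated_small):
        d0 = polymer_water_distances(hydrated_small)
        shifted = hydrated_small.translated((0.77, -1.3, 2.9))
        d1 = polymer_water_distances(shifted)
        np.testing.assert_allclose(np.sort(d0), np.sort(d1), atol=1e-9)
        p0, p1 = assign_layers(d0), assign_layers(d1)
        assert (p0.n_w1, p0.n_w2, p0.n_beyond) == (p1.n_w1, p1.n_w2, p1.n_beyond)


class TestHistogram:
    def test_half_open_binning(self):
        h = population_histogram(np.array([0.27, 0.29]), bin_width=0.05, d_max=2.0)
        i = np.searchsorted(h.bin_edges, 0.25)
        assert h.bin_edges[i] == pytest.approx(0.25)
        assert h.population[i] == 2

    def test_time_average_idempotent(self):
        frame = np.array([0.1, 0.2, 0.3, 0.55])
        h1 = population_histogram(frame)
        h2 = population_histogram([frame, frame])
        np.testing.assert_array_equal(h1.population, h2.population)
        assert h2.n_frames == 2

    def test_mass_conservation_with_truncation_report(self):
        frame = np.array([0.1, 0.5, 1.0, 2.5, 3.0])
        h = population_histogram(frame, d_max=2.0)
        assert h.total + h.n_truncated == len(frame)
        assert h.n_truncated == 2

    def test_all_beyond_dmax_warns(self):
        with pytest.warns(UserWarning, match="beyond d_max"):
            h = population_histogram(np.array([3.0, 4.0]), d_max=2.0)
        assert h.total == 0


class TestDoubleGaussian:
    def _exact_hist(self, a1=120, m1=0.28, s1=0.05, a2=40, m2=0.56, s2=0.15):
        edges = np.arange(0, 2.0001, 0.01)
        x = 0.5 * (edges[:-1] + edges[1:])
        y = a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
            -0.5 * ((x - m2) / s2) ** 2
        )
        return DistanceHistogram(edges, y)

    def test_exact_recovery(self):
        fit = fit_double_gaussian(self._exact_hist())
        assert fit.mean1 == pytest.approx(0.28, abs=1e-3)
        assert fit.mean2 == pytest.approx(0.56, abs=1e-3)
        assert fit.sd1 == pytest.approx(0.05, abs=1e-3)
        assert fit.rss < 1e-12

    def test_single_peak_flags_degenerate(self):
        fit = fit_double_gaussian(self._exact_hist(a2=0.0))
        assert fit.degenerate
        assert fit.mean1 <= fit.mean2
        # the dominant component still sits on the real peak
        dominant = fit.mean1 if fit.amp1 > fit.amp2 else fit.mean2
        assert dominant == pytest.approx(0.28, abs=1e-3)

    def test_initial_mean_permutation_gives_same_ordered_result(self):
        hist = self._exact_hist()
        init_a = np.array([100.0, 0.30, 0.05, 50.0, 0.55, 0.1])
        init_b = np.array([50.0, 0.55, 0.1, 100.0, 0.30, 0.05])
        fa = fit_double_gaussian(hist, init_a)
        fb = fit_double_gaussian(hist, init_b)
        assert fa.mean1 == pytest.approx(fb.mean1, abs=1e-9)
        assert fa.mean2 == pytest.approx(fb.mean2, abs=1e-9)
        assert fa.mean1 < fa.mean2

    def test_too_few_bins_rejected(self):
        edges = np.arange(0, 0.06, 0.01)
        hist = DistanceHistogram(edges, np.array([1.0, 2.0, 1.0, 0, 0]))
        with pytest.raises(ValueError, match="nonzero bins"):
            fit_double_gaussian(hist)


class TestPartitionAndFractions:
    def test_shell_positions_fall_in_expected_layers(self):
        part = assign_layers(np.array([0.28, 0.56, 2.5]))
        assert (part.n_w1, part.n_w2, part.n_beyond) == (1, 1, 1)

    def test_counts_partition_the_water_set(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 3.0, 500)
        part = assign_layers(d)
        assert part.n_w1 + part.n_w2 + part.n_beyond == 500

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            assign_layers(np.array([0.3]), cutoff_12=2.0, cutoff_2end=0.45)

    def test_fraction_arithmetic(self):
        part = assign_layers(np.full(100, 0.3))  # all in layer 1
        f_p, f_w1, f_w2 = layer_volume_fractions(part, 125.0, 0.0299)
        assert f_w1 == pytest.approx(100 * 0.0299 / 125.0, rel=1e-12)
        assert f_w1 == pytest.approx(0.02392, abs=1e-5)
        assert f_w2 == 0.0
        assert f_p + f_w1 + f_w2 == pytest.approx(1.0, abs=1e-15)

    def test_no_water_gives_pure_polymer(self):
        part = assign_layers(np.empty(0))
        assert layer_volume_fractions(part, 50.0) == (1.0, 0.0, 0.0)

    def test_unphysical_water_volume_raises(self):
        part = assign_layers(np.full(10000, 0.3))
        with pytest.raises(ValueError, match="exceeds"):
            layer_volume_fractions(part, 1.0, 0.0299)


def test_shell_recovery_from_generated_configuration(polymer_standard):
    """Generator -> histogram -> DGD recovers the requested well-separated
    shell centers to 0.01 nm at ~2000 molecules."""
    from hydropol.synthetic import ShellMixtureParams, generate_hydrated_configuration

    shells = ShellMixtureParams(0.28, 0.04, 0.60, 0.06, weight1=0.55)
    hyd = generate_hydrated_configuration(polymer_standard, 0.55, shells, seed=21)
    assert hyd.n_water_molecules >= 2000
    d = polymer_water_distances(hyd)
    fit = fit_double_gaussian(population_histogram(d, 0.01, 2.0))
    assert fit.mean1 == pytest.approx(0.28, abs=0.01)
    assert fit.mean2 == pytest.approx(0.60, abs=0.01)
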