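"""Ensemble observables: Rg, shape factor, Flory fits, scattering, contacts."""

import math

import numpy as np
import pytest

from glutencg import (
    contact_map,
    cys_contact_network,
    debye_scattering,
    flory_fit,
    generate_ideal_ensemble,
    generate_rod,
    generate_saw_chain,
    radius_of_gyration,
    rg_distribution,
    shape_factor,
)


def brute_force_rg(coords):
    """Rg via the pair-distance identity Rg^2 = (1/2N^2) sum_ij r_ij^2."""
    n = len(coords)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            d = coords[i] - coords[j]
            acc += float(d @ d)
    return math.sqrt(acc / (2 * n * n))


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_beads_half_separation(self):
        assert radius_of_gyration(
            np.array([[0.0, 0, 0], [4.1, 0, 0]])
        ) == pytest.approx(2.05)

    def test_rod_matches_moment_formula(self):
        rod = generate_rod(100, 1.0)
        expected = math.sqrt((100**2 - 1) / 12)
        assert radius_of_gyration(rod) == pytest.approx(expected, rel=1e-12)

    def test_matches_pair_distance_oracle_on_random_frames(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            coords = rng.normal(size=(17, 3)) * 10
            assert radius_of_gyration(coords) == pytest.approx(
                brute_force_rg(coords), rel=1e-12
            )

    def test_empty_configuration_errors(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)))


class TestShapeFactor:
    def test_long_rod_approaches_twelve(self):
        rod = generate_rod(10000, 1.0)
        assert shape_factor(rod.coordinates[None]).r_shape == pytest.approx(12, rel=0.001)

    def test_ideal_ensemble_approaches_six(self):
        coords = generate_ideal_ensemble(200, 1.0, n_chains=3000, seed=8)
        assert shape_factor(coords).r_shape == pytest.approx(6.0, rel=0.05)

    def test_two_bead_configuration_closed_form(self):
        conf = np.array([[[0.0, 0, 0], [3.0, 0, 0]]])
        assert shape_factor(conf).r_shape == pytest.approx(4.0)

    def test_single_bead_chain_undefined(self):
        with pytest.raises(ValueError):
            shape_factor(np.zeros((5, 1, 3)))


class TestFloryFit:
    @pytest.mark.parametrize("nu", [1 / 3, 1 / 2, 3 / 5])
    def test_inverts_constructed_power_law(self, nu):
        r0 = 2.0
        # single-point inversion
        assert flory_fit((r0 * 200**nu, 200), r0=r0) == pytest.approx(nu, abs=1e-12)
        # regression, both intercept conventions
        pairs = [(n, r0 * n**nu) for n in (50, 100, 200, 400)]
        assert flory_fit(pairs, r0=r0, fix_prefactor=True) == pytest.approx(nu, abs=1e-12)
        assert flory_fit(pairs) == pytest.approx(nu, abs=1e-12)

    def test_free_intercept_ignores_prefactor_mismatch(self):
        pairs = [(n, 5.0 * n**0.5) for n in (50, 100, 200)]
        assert flory_fit(pairs) == pytest.approx(0.5, abs=1e-12)

    def test_subunity_rg_warns_not_raises(self):
        with pytest.warns(UserWarning):
            nu = flory_fit((1.0, 100), r0=2.0)
        assert nu < 0

    def test_regression_needs_three_lengths(self):
        with pytest.raises(ValueError):
            flory_fit([(50, 10.0), (100, 15.0)])


class TestRgDistribution:
    def test_identical_frames_degenerate(self):
        frames = np.tile(generate_rod(10, 1.0).coordinates, (20, 1, 1))
        dist = rg_distribution(frames)
        assert dist.variance == 0.0
        assert len(dist.density) == 1

    def test_moments_match_sample_moments(self):
        coords = generate_ideal_ensemble(50, 1.0, n_chains=200, seed=2)
        rg = np.array([radius_of_gyration(f) for f in coords])
        dist = rg_distribution(coords, n_bins=20)
        assert dist.mean == pytest.approx(rg.mean())
        assert dist.variance == pytest.approx(rg.var())
        # density integrates to one
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0)

    def test_second_moment_matches_ideal_chain_theory(self):
        n, b = 100, 1.0
        coords = generate_ideal_ensemble(n, b, n_chains=4000, seed=3)
        dist = rg_distribution(coords)
        mean_sq = dist.mean**2 + dist.variance
        expected = (n**2 - 1) * b**2 / (6 * n)
        assert mean_sq == pytest.approx(expected, rel=0.03)


class TestDebyeScattering:
    def test_forward_intensity_is_n_squared(self):
        coords = generate_rod(7, 2.0).coordinates[None]
        curve = debye_scattering(coords, [0.0, 0.1])
        assert curve.intensity[0] == pytest.approx(49.0)
        assert curve.i0 == 49.0
        assert curve.kratky_y[0] == 0.0

    def test_single_bead_flat_unity(self):
        curve = debye_scattering(np.zeros((1, 1, 3)), np.linspace(0, 1, 11))
        assert np.allclose(curve.intensity, 1.0)

    def test_two_bead_closed_form(self):
        d = 3.7
        coords = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        q = np.linspace(0.01, 2.0, 40)
        curve = debye_scattering(coords, q)
        expected = 2 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(curve.intensity, expected, rtol=1e-10)

    def test_guinier_recovers_rg(self):
        conf = generate_saw_chain(80, 3.8, radius=1.5, seed=4)
        rg = radius_of_gyration(conf)
        q = np.linspace(0.001, 1.2 / rg, 30)
        curve = debye_scattering(conf.coordinates[None], q)
        assert curve.guinier_rg() == pytest.approx(rg, rel=0.05)

    def test_kratky_plateau_of_ideal_chains(self):
        # chain long enough that q stays below the bond scale across the
        # plateau window (q*b < 1.3), where the Gaussian Debye limit holds;
        # normalize with the closed-form <Rg^2> = (n^2-1) b^2 / 6n of the
        # freely-jointed chain so the plateau is not blurred by the
        # finite-ensemble noise of the sampled Rg
        n = 800
        coords = generate_ideal_ensemble(n, 1.0, n_chains=120, seed=5)
        rg = math.sqrt((n**2 - 1) / (6 * n))
        q = np.linspace(5 / rg, 15 / rg, 5)
        curve = debye_scattering(coords, q)
        # Debye function plateau: (qRg)^2 I/I0 -> 2 for ideal chains
        plateau = (q * rg) ** 2 * curve.intensity / curve.i0
        assert np.all(np.abs(plateau - 2.0) < 0.2)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            debye_scattering(np.zeros((1, 2, 3)), [-0.1])


class TestContactMap:
    def test_rod_with_wide_spacing_has_empty_map(self):
        rod = generate_rod(20, 4.1)
        cmap = contact_map(rod.coordinates[None], cutoff=8.0, exclusion=1)
        assert cmap.frequencies.sum() == 0.0

    def test_map_is_symmetric(self, restrained_run):
        cmap = contact_map(restrained_run, cutoff=8.0)
        assert np.array_equal(cmap.frequencies, cmap.frequencies.T)

    def test_constructed_permanent_contact_scores_one(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(15, 60, 3)) * 50
        frames[:, 49] = frames[:, 4] + 1.0  # beads 5 and 50 always in contact
        cmap = contact_map(frames, cutoff=8.0)
        assert cmap.frequencies[4, 49] == 1.0

    def test_exclusion_band_zeroed(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(size=(5, 30, 3))
        cmap = contact_map(frames, cutoff=100.0, exclusion=2)
        ii, jj = np.indices(cmap.frequencies.shape)
        band = np.abs(ii - jj) <= 2
        assert cmap.frequencies[band].sum() == 0.0
        assert np.all(cmap.frequencies[~band] == 1.0)

    def test_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(size=(10, 12, 3)) * 4
        cmap = contact_map(frames, cutoff=5.0, exclusion=1)
        for i in range(12):
            for j in range(12):
                if abs(i - j) <= 1:
                    continue
                freq = np.mean(
                    [np.linalg.norm(f[i] - f[j]) < 5.0 for f in frames]
                )
                assert cmap.frequencies[i, j] == pytest.approx(freq)


class TestCysContactNetwork:
    def test_no_cysteines_empty(self):
        frames = np.zeros((3, 10, 3)) + np.arange(10)[None, :, None] * 5
        net = cys_contact_network(frames, [], cutoff=8.0)
        assert net.frequencies == {}

    def test_vicinal_pair_excluded(self):
        frames = np.zeros((3, 10, 3)) + np.arange(10)[None, :, None] * 5
        net = cys_contact_network(frames, [4, 5], cutoff=8.0)
        assert net.frequencies == {}

    def test_restrained_pair_in_permanent_contact(self, restrained_run, gluten_seq,
                                                  restraint_pairs):
        net = cys_contact_network(
            restrained_run, gluten_seq.cys_positions, cutoff=8.0
        )
        for i, j in restraint_pairs:
            assert net.frequencies[(min(i, j), max(i, j))] == pytest.approx(1.0)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            cys_contact_network(np.zeros((2, 5, 3)), [9])
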