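"""Smoothing, density estimation, Hellinger distances, and classical MDS."""

import numpy as np
import pytest

from varcog.geometry import (
    DENSITY_GRID_SIZE,
    HomogeneityDensity,
    SmoothedProfile,
    classical_mds,
    estimate_density,
    hellinger_distance,
    hellinger_matrix,
    smooth_profile,
)

from oracles import oracle_smooth


def density(mass, family_id="d"):
    mass = np.asarray(mass, dtype=float)
    return HomogeneityDensity(
        family_id, np.linspace(0, 1, mass.size), mass / mass.sum()
    )


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        sp = smooth_profile([0.5] * 100)
        assert np.allclose(sp.h_smooth, 0.5, atol=1e-12)

    def test_length_one_profile_unchanged(self):
        assert smooth_profile([0.3]).h_smooth[0] == pytest.approx(0.3)

    def test_unit_spike_matches_double_loop_oracle(self):
        h = [0.0] * 41
        h[20] = 1.0
        sp = smooth_profile(h, b=20)
        expected = oracle_smooth(h, 20)
        assert np.allclose(sp.h_smooth, expected, atol=1e-12)

    def test_random_profile_matches_oracle(self, rng):
        h = rng.random(80)
        sp = smooth_profile(h, b=20)
        assert np.allclose(sp.h_smooth, oracle_smooth(list(h), 20), atol=1e-12)

    def test_output_within_input_range(self, rng):
        h = rng.random(200)
        sp = smooth_profile(h, b=20)
        assert sp.h_smooth.min() >= h.min() - 1e-12
        assert sp.h_smooth.max() <= h.max() + 1e-12

    def test_masked_positions_excluded(self):
        h = np.array([0.2, np.nan, 0.2, 0.2])
        sp = smooth_profile(h, b=5)
        valid = ~np.isnan(sp.h_smooth)
        assert np.allclose(sp.h_smooth[valid], 0.2, atol=1e-12)
        assert np.isnan(sp.h_smooth[1])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile([])


class TestDensity:
    def test_degenerate_values_give_unit_spike(self):
        d = estimate_density(SmoothedProfile("f", np.full(50, 0.5)))
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.mass[50] == 1.0  # grid point exactly at 0.5

    def test_grid_has_101_points_and_unit_mass(self, rng):
        d = estimate_density(SmoothedProfile("f", rng.random(100)))
        assert d.grid.size == DENSITY_GRID_SIZE
        assert d.grid[0] == 0.0 and d.grid[-1] == 1.0
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(d.mass >= 0)

    def test_bimodal_values_give_two_modes(self, rng):
        # Clusters far enough from the support boundary that Silverman's
        # (global) bandwidth resolves them as interior modes.
        values = np.concatenate(
            [0.25 + 0.01 * rng.standard_normal(50), 0.75 + 0.01 * rng.standard_normal(50)]
        ).clip(0, 1)
        d = estimate_density(SmoothedProfile("f", values))
        low = d.mass[d.grid < 0.5]
        high = d.mass[d.grid >= 0.5]
        grid_mode_low = d.grid[d.grid < 0.5][np.argmax(low)]
        grid_mode_high = d.grid[d.grid >= 0.5][np.argmax(high)]
        assert abs(grid_mode_low - 0.25) < 0.07
        assert abs(grid_mode_high - 0.75) < 0.07

    def test_matches_independent_kde_oracle(self):
        # Direct double-loop Gaussian KDE with Silverman's bandwidth and
        # boundary reflection, sharing no code with the implementation.
        values = np.array([0.1] * 50 + [0.9] * 50)
        d = estimate_density(SmoothedProfile("f", values))
        n = values.size
        bw = values.std(ddof=1) * (n * 3.0 / 4.0) ** (-1.0 / 5.0)
        grid = np.linspace(0, 1, 101)
        dens = np.zeros(101)
        for i, g in enumerate(grid):
            for x in values:
                for center in (x, -x, 2 - x):
                    dens[i] += np.exp(-((g - center) ** 2) / (2 * bw * bw))
        expected = dens / dens.sum()
        assert np.allclose(d.mass, expected, atol=1e-12)


class TestHellinger:
    def test_identity(self, rng):
        p = density(rng.random(101))
        assert hellinger_distance(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_give_one(self):
        p = density([1, 0, 0, 0])
        q = density([0, 0, 0, 1])
        assert hellinger_distance(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_value(self):
        p = density([0.5, 0.5])
        q = density([0.9, 0.1])
        expected = np.sqrt(1 - (np.sqrt(0.45) + np.sqrt(0.05)))
        assert hellinger_distance(p, q) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3249197, abs=1e-7)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(100):
            p, q, r = (density(rng.random(101) + 1e-12) for _ in range(3))
            dpq = hellinger_distance(p, q)
            dqr = hellinger_distance(q, r)
            dpr = hellinger_distance(p, r)
            assert dpq == pytest.approx(hellinger_distance(q, p), abs=1e-12)
            assert 0.0 <= dpq <= 1.0
            assert dpr <= dpq + dqr + 1e-12

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hellinger_distance(density([1, 1]), density([1, 1, 1]))


class TestClassicalMds:
    def test_all_zero_distances_give_zero_coordinates(self):
        res = classical_mds(np.zeros((4, 4)))
        assert np.allclose(res.coordinates, 0.0)

    def test_unit_square_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = classical_mds(d, dims=2)
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        assert np.allclose(rec, d, atol=1e-8)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_collinear_points_have_one_dominant_eigenvalue(self):
        pts = np.array([0.0, 1.0, 2.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = classical_mds(d, dims=2)
        assert res.eigenvalues[0] > 1.0
        assert abs(res.eigenvalues[1]) < 1e-9

    def test_planted_2d_configurations_recovered(self, rng):
        for _ in range(5):
            pts = rng.random((8, 2)) * 3
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            res = classical_mds(d, dims=2)
            rec = np.linalg.norm(
                res.coordinates[:, None] - res.coordinates[None, :], axis=-1
            )
            assert np.allclose(rec, d, atol=1e-6)

    def test_agrees_with_skbio_pcoa(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.random((6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = classical_mds(d, dims=2)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), number_of_dimensions=2
        )
        ref = theirs.samples.to_numpy()
        for axis in range(2):
            assert np.allclose(
                np.abs(ours.coordinates[:, axis]), np.abs(ref[:, axis]), atol=1e-8
            )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            classical_mds(d)


def test_hellinger_matrix_shape_and_symmetry(rng):
    ds = [density(rng.random(101)) for _ in range(4)]
    m = hellinger_matrix(ds)
    assert m.shape == (4, 4)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
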