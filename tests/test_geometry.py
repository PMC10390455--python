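import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from celldosim.geometry import (CellModel, ClusterModel, Compartment,
                                hcp_neighbor_centers, ray_sphere_intersect,
                                ray_sphere_intersect_many, sample_source_points)


class TestHCP:
    def test_twelve_equidistant_neighbors(self):
        c = hcp_neighbor_centers(10.0)
        assert c.shape == (12, 3)
        assert np.allclose(np.linalg.norm(c, axis=1), 10.0)

    def test_minimum_pairwise_distance_equals_spacing(self):
        c = hcp_neighbor_centers(10.0)
        dists = [np.linalg.norm(c[i] - c[j])
                 for i in range(12) for j in range(i + 1, 12)]
        assert min(dists) == pytest.approx(10.0)

    def test_scaling_homogeneity(self):
        assert np.allclose(hcp_neighbor_centers(1.0) * 7.5,
                           hcp_neighbor_centers(7.5))

    def test_cluster_invariants(self, cluster):
        assert len(cluster.cells) == 13
        centers = np.array([c.center for c in cluster.cells])
        assert np.allclose(np.linalg.norm(centers[1:], axis=1), 10.0)

    def test_overlapping_cells_rejected(self):
        cell = CellModel()
        centers = np.vstack([[0, 0, 0], hcp_neighbor_centers(10.0)])
        centers[1] = [0, 0, 1.0]  # overlaps the centre cell
        with pytest.raises(ValueError):
            ClusterModel(tuple(cell.with_center(c) for c in centers), 10.0)


class TestCellModel:
    def test_nucleus_mass_default(self, cell):
        # (4/3)π(4 µm)³ of unit-density water
        assert cell.nucleus_mass_kg == pytest.approx(2.6808e-13, rel=1e-4)

    def test_mass_linear_in_density(self):
        heavy = CellModel(density=2.0)
        assert heavy.nucleus_mass_kg == pytest.approx(2 * CellModel().nucleus_mass_kg)

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            CellModel(cell_radius=4.0, nucleus_radius=5.0)


class TestCompartmentSampling:
    def test_surface_points_on_membrane(self, cell):
        pts = sample_source_points(cell, "cell_surface",
                                   np.random.default_rng(0), 1000)
        assert np.allclose(np.linalg.norm(pts, axis=1), 5.0, atol=1e-9)

    def test_nucleus_mean_radius(self, cell):
        # uniform ball of radius a has mean radius 3a/4
        pts = sample_source_points(cell, "nucleus",
                                   np.random.default_rng(1), 100_000)
        r = np.linalg.norm(pts, axis=1)
        assert r.max() <= 4.0
        assert r.mean() == pytest.approx(3.0, rel=0.01)

    def test_cytoplasm_shell_volume_fraction(self, cell):
        pts = sample_source_points(cell, "cytoplasm",
                                   np.random.default_rng(2), 100_000)
        r = np.linalg.norm(pts, axis=1)
        assert r.min() >= 4.0 and r.max() <= 5.0
        frac = np.mean(r < 4.5)
        assert frac == pytest.approx((4.5**3 - 4**3) / (5**3 - 4**3), abs=0.01)

    @pytest.mark.parametrize("compartment,lo,hi", [
        ("nucleus", 0.0, 4.0),
        ("cytoplasm", 4.0, 5.0),
        ("whole_cell", 0.0, 5.0),
    ])
    def test_radial_uniformity_chisquare(self, cell, compartment, lo, hi):
        """Counts in equal-volume radial shells must be uniform."""
        pts = sample_source_points(cell, compartment,
                                   np.random.default_rng(3), 100_000)
        r = np.linalg.norm(pts, axis=1)
        edges = np.cbrt(np.linspace(lo**3, hi**3, 11))
        counts, _ = np.histogram(r, bins=edges)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_offcentre_cell_sampling(self):
        shifted = CellModel(center=(10.0, 0.0, 0.0))
        pts = sample_source_points(shifted, "whole_cell",
                                   np.random.default_rng(4), 10_000)
        assert np.all(np.linalg.norm(pts - [10, 0, 0], axis=1) <= 5.0)


class TestRaySphere:
    def test_origin_at_centre(self):
        assert ray_sphere_intersect((0, 0, 0), (1, 0, 0), (0, 0, 0), 5.0) == (0.0, 5.0)

    def test_hand_geometry(self):
        s = ray_sphere_intersect((0, 0, 6), (0, 0, -1), (0, 0, 0), 5.0)
        assert s == pytest.approx((1.0, 11.0))

    def test_tangent_is_miss(self):
        assert ray_sphere_intersect((5, 0, -10), (0, 0, 1), (0, 0, 0), 5.0) is None

    def test_backward_sphere_is_miss(self):
        assert ray_sphere_intersect((0, 0, 10), (0, 0, 1), (0, 0, 0), 5.0) is None

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            ray_sphere_intersect((0, 0, 0), (0, 0, 2.0), (0, 0, 0), 5.0)

    def test_against_marching_oracle(self):
        """Entry/exit lengths agree with marching + bisection root finding."""
        rng = np.random.default_rng(5)
        center, radius = np.array([1.0, -2.0, 0.5]), 3.0

        def f(o, d, t):
            return np.linalg.norm(o + t * d - center) - radius

        checked = 0
        for trial in range(300):
            o = rng.uniform(-8, 8, 3)
            if trial % 2:  # aim half the rays near the sphere to get hits
                d = center - o + rng.normal(scale=1.5, size=3)
            else:
                d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts = np.linspace(0.0, 25.0, 5001)
            vals = np.array([f(o, d, t) for t in ts])
            roots = []
            for i in np.flatnonzero(np.diff(np.sign(vals)) != 0):
                a, b = ts[i], ts[i + 1]
                for _ in range(60):
                    m = 0.5 * (a + b)
                    if np.sign(f(o, d, m)) == np.sign(f(o, d, a)):
                        a = m
                    else:
                        b = m
                roots.append(0.5 * (a + b))
            got = ray_sphere_intersect(o, d, center, radius)
            if got is None:
                assert len(roots) == 0
                continue
            s_in, s_out = got
            if f(o, d, 0.0) < 0:  # origin inside: only the exit root exists
                assert s_in == 0.0
                assert s_out == pytest.approx(roots[0], abs=1e-6)
            else:
                assert s_in == pytest.approx(roots[0], abs=1e-6)
                assert s_out == pytest.approx(roots[1], abs=1e-6)
            checked += 1
        assert checked > 100  # the oracle exercised plenty of real hits

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_vectorised_matches_scalar(self, data):
        o = np.array([data.draw(st.floats(-8, 8)) for _ in range(3)])
        v = np.array([data.draw(st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3))
                      for _ in range(3)])
        d = v / np.linalg.norm(v)
        got = ray_sphere_intersect(o, d, (0, 0, 0), 4.0)
        s_in, s_out = ray_sphere_intersect_many(o[None], d[None], (0, 0, 0), 4.0)
        if got is None:
            assert s_out[0] == s_in[0]
        else:
            assert (s_in[0], s_out[0]) == pytest.approx(got)
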