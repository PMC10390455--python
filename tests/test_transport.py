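import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from celldosim import CellModel
from celldosim.nuclides import get_decay_scheme
from celldosim.scoring import MEV_TO_J, VoxelDoseGrid
from celldosim.stopping import StoppingPowerTable
from celldosim.transport import (ParticleTrack, TransportConfig,
                                 deposit_in_sphere, deposit_voxelized,
                                 isotropic_directions, simulate_decays)


class TestIsotropicDirections:
    def test_unit_norm(self):
        v = isotropic_directions(np.random.default_rng(0), 10_000)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_component_means_vanish(self):
        v = isotropic_directions(np.random.default_rng(1), 1_000_000)
        sigma = 1.0 / np.sqrt(3 * len(v))  # var of each component is 1/3
        assert np.all(np.abs(v.mean(axis=0)) < 3 * sigma)

    def test_z_component_uniform(self):
        v = isotropic_directions(np.random.default_rng(2), 200_000)
        p = stats.kstest(v[:, 2], stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.001


class TestDepositInSphere:
    def test_contained_track_deposits_everything(self, alpha_table):
        # 2 MeV alpha has ~11 µm range, well inside a 20 µm sphere
        track = ParticleTrack((0, 0, 0), (0, 0, 1), "alpha", 2.0)
        dep = deposit_in_sphere(track, (0, 0, 0), 20.0, alpha_table)
        assert dep == pytest.approx(2.0, rel=1e-6)

    def test_missing_track_deposits_nothing(self, alpha_table):
        track = ParticleTrack((0, 0, 10), (0, 0, 1), "alpha", 5.8)
        assert deposit_in_sphere(track, (0, 0, 0), 4.0, alpha_table) == 0.0

    def test_chord_against_ode_oracle(self, alpha_table):
        """A 3 µm chord deposit equals the integral of S(E) along the path."""
        def rhs(s, e):
            return [-alpha_table.stopping_power(max(e[0], 1e-3))]

        sol = solve_ivp(rhs, (0, 3.0), [5.8], rtol=1e-9, max_step=0.02)
        expected = 5.8 - sol.y[0, -1]
        track = ParticleTrack((0, 0, 0), (0, 0, 1), "alpha", 5.8)
        got = deposit_in_sphere(track, (0, 0, 1.5), 1.5, alpha_table)
        assert got == pytest.approx(expected, rel=5e-3)


class TestVoxelDeposition:
    def test_energy_conservation_contained(self, alpha_table):
        """Contained alpha tracks leave exactly E0 on the grid."""
        grid = VoxelDoseGrid()
        rng = np.random.default_rng(3)
        n = 200
        dirs = isotropic_directions(rng, n)
        origins = rng.uniform(-2, 2, (n, 3))
        energies = np.full(n, 3.0)  # range ~17 µm, inside the ±40 µm grid
        deposit_voxelized((origins, dirs, energies), grid, alpha_table)
        assert grid.energy_sum.sum() == pytest.approx(n * 3.0, rel=1e-6)

    def test_exiting_track_deposits_partially(self, beta_table):
        grid = VoxelDoseGrid()
        track = ParticleTrack((0, 0, 0), (0, 0, 1), "beta", 0.435)
        deposit_voxelized(track, grid, beta_table)
        total = grid.energy_sum.sum()
        assert 0.0 < total < 0.435  # electron range ≫ grid, most energy leaves

    def test_constant_let_per_voxel(self):
        """With constant S, an axis-aligned track deposits edge·S per voxel."""
        e = np.logspace(-3, 1, 50)
        const = StoppingPowerTable("alpha", e, np.full(50, 1000.0), e / 0.1)
        grid = VoxelDoseGrid()
        track = ParticleTrack((-10.0, 0.4, 0.4), (1, 0, 0), "alpha", 3.0)
        deposit_voxelized(track, grid, const)  # S = 0.1 MeV/µm, range 30 µm
        deps = grid.energy_sum[grid.energy_sum > 0]
        assert grid.energy_sum.sum() == pytest.approx(3.0, rel=1e-6)
        # interior voxels all carry 0.8 µm × 0.1 MeV/µm
        interior = deps[np.abs(deps - 0.08) < 0.01]
        assert len(interior) >= 35
        assert np.allclose(interior, 0.08, rtol=1e-9)

    def test_voxel_traversal_matches_chord_on_commensurate_sphere(self, alpha_table):
        """Region energy sums: DDA traversal vs analytic chords.

        A 12 µm sphere is large against the 0.8 µm voxels (volume mismatch
        of the binary mask ≪ the nucleus case), so the two scorings must
        agree to the 2% discretisation bound.
        """
        from celldosim.scoring import region_mask
        from celldosim.transport import _chord_deposits

        grid = VoxelDoseGrid()
        mask = region_mask(grid, (0, 0, 0), 12.0)
        rng = np.random.default_rng(12)
        n = 20_000
        origins = rng.uniform(-4, 4, (n, 3))
        dirs = isotropic_directions(rng, n)
        energies = np.full(n, 5.8)
        rs, _ = deposit_voxelized((origins, dirs, energies), grid, alpha_table,
                                  mask=mask.astype(np.uint8))
        chord = _chord_deposits(origins, dirs, energies, np.zeros(3), 12.0,
                                alpha_table).sum()
        assert rs == pytest.approx(chord, rel=0.02)

    def test_recoil_scored_at_emission_point(self, alpha_table):
        grid = VoxelDoseGrid()
        t = ParticleTrack((0.4, 0.4, 0.4), (1, 0, 0), "alpha", 3.0)
        deposit_voxelized(t, grid, alpha_table, recoil_mev=np.array([0.1]))
        assert grid.energy_sum.sum() == pytest.approx(3.1, rel=1e-6)


class TestSimulateDecays:
    def test_branch_sampling_fraction(self, cell):
        """The ²¹³Bi alpha branch must be drawn at its 2.2% branching ratio."""
        res = simulate_decays(get_decay_scheme("Bi-213"), cell, "nucleus",
                              TransportConfig(n_histories=100_000, seed=8))
        frac = res.branch_counts[1] / res.n_histories
        sigma = np.sqrt(0.022 * 0.978 / res.n_histories)
        assert abs(frac - 0.022) < 3 * sigma

    def test_seed_reproducibility(self, cell):
        cfg = TransportConfig(n_histories=5_000, seed=42)
        a = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus", cfg)
        b = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus", cfg)
        assert np.array_equal(a.grid.energy_sum, b.grid.energy_sum)
        assert a.region_sum_mev == b.region_sum_mev

    def test_mersenne_twister_option(self, cell):
        cfg = TransportConfig(n_histories=2_000, seed=42, rng_kind="mt19937")
        a = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus", cfg)
        b = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus", cfg)
        assert np.array_equal(a.grid.energy_sum, b.grid.energy_sum)

    def test_independent_seeds_agree_within_3_sigma(self, cell):
        doses = []
        for seed in (101, 202):
            res = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus",
                                  TransportConfig(n_histories=20_000, seed=seed,
                                                  scoring_mode="analytic_chord"))
            rd = res.region_dose("history")
            doses.append((rd.dose_gy / res.n_histories,
                          rd.uncertainty_gy / res.n_histories))
        (s1, u1), (s2, u2) = doses
        assert abs(s1 - s2) < 3 * np.hypot(u1, u2)

    def test_invalid_history_count(self):
        with pytest.raises(ValueError):
            TransportConfig(n_histories=0)

    def test_uncertainty_scales_as_inverse_sqrt_n(self, cell):
        """Relative SE of the nucleus dose must follow 1/√N."""
        ns = [1_000, 10_000, 100_000]
        rel = []
        for n in ns:
            res = simulate_decays(get_decay_scheme("Ac-225"), cell, "nucleus",
                                  TransportConfig(n_histories=n, seed=77,
                                                  scoring_mode="analytic_chord"))
            rel.append(res.region_dose("history").relative_uncertainty)
        slope = np.polyfit(np.log(ns), np.log(rel), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_cluster_per_cell_allocation(self, cluster):
        res = simulate_decays(get_decay_scheme("Ac-225"), cluster, "nucleus",
                              TransportConfig(n_histories=26_000, seed=9,
                                              scoring_mode="analytic_chord"))
        counts = res.per_cell_counts
        assert counts.sum() == 26_000
        assert stats.chisquare(counts).pvalue > 0.001

    def test_neighbors_only_source_selection(self, cluster):
        res = simulate_decays(get_decay_scheme("Ac-225"), cluster, "nucleus",
                              TransportConfig(n_histories=1_300, seed=10,
                                              scoring_mode="analytic_chord",
                                              source_cells="neighbors"))
        assert res.per_cell_counts[0] == 0
        assert res.per_cell_counts[1:].sum() == 1_300
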