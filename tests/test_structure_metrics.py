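"""Ensemble structure analysis: Rg scaling, loops, diffusion maps."""

import numpy as np
import pytest

import chromofold as cf
from chromofold.structure_metrics import NM_PER_UNIT


class TestRadiusOfGyration:
    def test_two_beads(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert cf.radius_of_gyration(coords) == pytest.approx(1.5)

    def test_unit_square_corners(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert cf.radius_of_gyration(coords) == pytest.approx(np.sqrt(0.5))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(15, 3))
        shifted = coords + np.array([5.0, -2.0, 9.0])
        assert cf.radius_of_gyration(coords) == pytest.approx(
            cf.radius_of_gyration(shifted), abs=1e-12)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            cf.radius_of_gyration(np.zeros((5, 3)), (2, 3))


class TestPowerLawFit:
    def test_exact_power_law(self):
        x = np.array([1.0, 2, 5, 10, 30])
        y = 2.0 * x**0.34
        fit = cf.fit_power_law(x, y)
        assert fit.exponent == pytest.approx(0.34, abs=1e-10)
        assert fit.prefactor == pytest.approx(2.0, rel=1e-10)
        assert fit.residual < 1e-12

    def test_constant_data_zero_exponent(self):
        fit = cf.fit_power_law([1.0, 2, 4, 8], [3.0, 3, 3, 3])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_outlier_reports_residual(self):
        x = np.array([1.0, 2, 4, 8])
        y = 2.0 * x**0.5
        y[2] *= 3.0
        assert cf.fit_power_law(x, y).residual > 0.1

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cf.fit_power_law([1.0, 2, 0.0], [1.0, 1, 1])


class TestDomainScaling:
    def test_rigid_rod_exponent_one(self):
        n = 120
        frame = np.zeros((n, 3))
        frame[:, 0] = np.arange(n) * 0.9
        traj = cf.EnsembleTrajectory(frame[None])
        domains = [((0, L), "rod") for L in (10, 20, 40, 80, 120)]
        fit = cf.domain_scaling(traj, domains)["rod"][0]
        assert fit.exponent == pytest.approx(1.0, abs=0.02)

    def test_gaussian_chain_exponent_half(self):
        rng = np.random.default_rng(4)
        n, n_frames = 200, 400
        steps = rng.normal(size=(n_frames, n, 3))
        frames = np.cumsum(steps, axis=1)
        traj = cf.EnsembleTrajectory(frames)
        domains = [((0, L), "ideal") for L in (12, 25, 50, 100, 200)]
        fit = cf.domain_scaling(traj, domains)["ideal"][0]
        assert fit.exponent == pytest.approx(0.5, abs=0.05)

    def test_compact_ball_exponent_third(self):
        # beads filling a ball whose volume grows linearly with count
        rng = np.random.default_rng(5)
        sizes = [50, 100, 200, 400, 800]
        nmax = max(sizes)
        pts = rng.normal(size=(nmax, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        radii = rng.random(nmax) ** (1 / 3)
        rgs = []
        for L in sizes:
            ball = pts[:L] * (radii[:L, None] * L ** (1 / 3))
            rgs.append(cf.radius_of_gyration(ball))
        fit = cf.fit_power_law(np.array(sizes, float), np.array(rgs))
        assert fit.exponent == pytest.approx(1 / 3, abs=0.05)

    def test_small_class_skipped(self):
        traj = cf.EnsembleTrajectory(np.random.default_rng(6).normal(
            size=(2, 30, 3)))
        out = cf.domain_scaling(traj, [((0, 10), "tiny"), ((0, 20), "tiny")])
        assert "tiny" not in out


class TestLoopEndToEnd:
    def test_identical_frames_zero_variance(self):
        frame = np.zeros((10, 3))
        frame[7, 0] = 2.0
        traj = cf.EnsembleTrajectory(np.repeat(frame[None], 5, axis=0))
        out = cf.loop_end_to_end(traj, (0, 7))
        assert out["var_nm2"] == 0.0
        assert out["mean_nm"] == pytest.approx(60.0)

    def test_mean_of_open_and_closed_loop(self):
        # 0.08 um and 0.24 um anchor distances average to 0.16 um
        frames = np.zeros((2, 4, 3))
        frames[0, 3, 0] = 80.0 / NM_PER_UNIT
        frames[1, 3, 0] = 240.0 / NM_PER_UNIT
        out = cf.loop_end_to_end(cf.EnsembleTrajectory(frames), (0, 3))
        assert out["mean_nm"] == pytest.approx(160.0)

    def test_histogram_mass_sums_to_one(self):
        rng = np.random.default_rng(7)
        traj = cf.EnsembleTrajectory(rng.normal(size=(50, 6, 3)))
        out = cf.loop_end_to_end(traj, (0, 5))
        assert out["hist"].sum() == pytest.approx(1.0)

    def test_nm_conversion_is_exact(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 2] = 1.75
        out = cf.loop_end_to_end(cf.EnsembleTrajectory(frames), (0, 1))
        assert out["distances_nm"][0] == 1.75 * 30.0


class TestDistanceProbability:
    def test_exact_inverse_quartic(self):
        n = 30
        frames = np.zeros((1, n, 3))
        frames[0, :, 0] = np.cumsum(np.linspace(1.0, 2.0, n))
        traj = cf.EnsembleTrajectory(frames)
        pairs = [(0, j) for j in range(5, 25)]
        r = np.array([frames[0, j, 0] - frames[0, 0, 0] for _, j in pairs])
        m = np.zeros((n, n))
        for (i, j), rr in zip(pairs, r):
            m[i, j] = m[j, i] = rr ** -4.0
        fit = cf.distance_probability_fit(traj, cf.ContactMap(m), pairs)
        assert fit.exponent == pytest.approx(-4.0, abs=1e-10)

    def test_contact_function_tail_exponent(self):
        r = np.linspace(5.0, 40.0, 50)
        fit = cf.fit_power_law(r, cf.contact_function(r))
        assert fit.exponent == pytest.approx(-4.0, abs=1e-10)

    def test_decreasing_data_negative_exponent(self):
        frames = np.zeros((1, 10, 3))
        frames[0, :, 0] = np.arange(10) * 1.3
        traj = cf.EnsembleTrajectory(frames)
        pairs = [(0, j) for j in range(2, 9)]
        m = np.zeros((10, 10))
        for i, j in pairs:
            m[i, j] = m[j, i] = 1.0 / (j + 1)
        fit = cf.distance_probability_fit(traj, cf.ContactMap(m), pairs)
        assert fit.exponent < 0

    def test_constant_distances_rejected(self):
        frames = np.zeros((1, 4, 3))
        frames[0, 1:, 0] = 2.0  # beads 1..3 coincide
        traj = cf.EnsembleTrajectory(frames)
        m = np.full((4, 4), 0.1)
        with pytest.raises(ValueError):
            cf.distance_probability_fit(traj, cf.ContactMap(m),
                                        [(0, 1), (0, 2), (0, 3)])


class TestFrameContactMap:
    def test_pair_at_crossover(self):
        coords = np.array([[0.0, 0, 0], [1.76, 0, 0]])
        m = cf.frame_contact_map(coords)
        assert m[0, 1] == pytest.approx(0.5)

    def test_consistent_with_single_frame_ensemble(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(12, 3)) * 2
        single = cf.frame_contact_map(coords)
        ens = cf.ensemble_contact_map(
            cf.EnsembleTrajectory(coords[None])).matrix
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(single[off], ens[off])

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        m = cf.frame_contact_map(rng.normal(size=(9, 3)))
        assert np.allclose(m, m.T)


class TestDiffusionMap:
    def test_markov_top_eigenvalue_and_constant_mode(self, two_cluster_frames):
        frames, _ = two_cluster_frames
        res = cf.diffusion_map(frames, n_components=2)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_cluster_separation(self, two_cluster_frames):
        frames, labels = two_cluster_frames
        res = cf.diffusion_map(frames, n_components=2)
        c1 = res.coordinates[:, 0]
        sign0 = np.sign(c1[labels == 0])
        sign1 = np.sign(c1[labels == 1])
        assert len(set(sign0)) == 1 and len(set(sign1)) == 1
        assert sign0[0] != sign1[0]

    def test_matches_dense_eigensolver_oracle(self, two_cluster_frames,
                                              oracles):
        frames, _ = two_cluster_frames
        res = cf.diffusion_map(frames, k_scale=10, n_components=2)
        vals_ref, coords_ref = oracles["reference_diffusion_coords"](
            res.distances, 10, 2)
        assert res.eigenvalues[:3] == pytest.approx(vals_ref[:3], abs=1e-8)
        for c in range(2):
            a = res.coordinates[:, c] / np.linalg.norm(res.coordinates[:, c])
            b = coords_ref[:, c] / np.linalg.norm(coords_ref[:, c])
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_kernel_symmetry(self, two_cluster_frames):
        frames, _ = two_cluster_frames
        res = cf.diffusion_map(frames)
        d, eps = res.distances, res.epsilons
        K = np.exp(-(d**2) / np.outer(eps, eps))
        assert np.abs(K - K.T).max() < 1e-12

    def test_frame_reordering_invariance(self, two_cluster_frames):
        frames, _ = two_cluster_frames
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(frames))
        res = cf.diffusion_map(frames, n_components=1)
        res_p = cf.diffusion_map(frames[perm], n_components=1)
        a = res.coordinates[perm, 0]
        b = res_p.coordinates[:, 0]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            cf.diffusion_map(np.zeros((3, 5, 3)), n_components=2)


class TestFreeEnergyProjection:
    def test_minimum_is_exactly_zero(self):
        rng = np.random.default_rng(11)
        out = cf.free_energy_projection(rng.normal(size=(500, 2)), bins=10)
        F = out["free_energy"]
        assert F[np.isfinite(F)].min() == 0.0

    def test_uniform_coordinates_flat_surface(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 1, (20_000, 2))
        out = cf.free_energy_projection(coords, bins=5)
        F = out["free_energy"]
        assert F[np.isfinite(F)].max() < 0.2

    def test_two_cluster_barrier(self, two_cluster_frames):
        frames, _ = two_cluster_frames
        res = cf.diffusion_map(frames, n_components=2)
        out = cf.free_energy_projection(res.coordinates, bins=8)
        # 1-D profile along coordinate 1: minimum over the other axis
        profile = out["free_energy"].min(axis=1)
        finite = np.flatnonzero(np.isfinite(profile))
        lo, hi = finite[0], finite[-1]
        assert hi > lo + 1  # the two basins occupy distinct bins
        barrier = profile[lo + 1:hi].max()  # +inf where bins are empty
        basins = min(profile[lo], profile[hi])
        assert barrier - basins > 1.0


def test_region_mean_maps_partition(two_cluster_frames):
    frames, labels = two_cluster_frames
    res = cf.diffusion_map(frames, n_components=1)
    c1 = res.coordinates[:, 0]
    lo, hi = c1.min(), c1.max()
    mid = 0.0
    maps = cf.region_mean_maps(frames, res.coordinates,
                               [(lo - 1e-9, mid), (mid, hi + 1e-9)])
    assert maps[0] is not None and maps[1] is not None
    assert not np.allclose(maps[0], maps[1])
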