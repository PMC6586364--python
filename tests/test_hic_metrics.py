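"""Contact-map IO, normalization and comparison metrics."""

import numpy as np
import pytest

import chromofold as cf
from chromofold.hic_metrics import (DEFAULT_C_DIAG, LogEigenResult,
                                    eigenvector_similarity, top_pairs,
                                    write_contact_matrix)


def random_probability_map(n=60, seed=0, bin_size=5000):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.01, 0.9, (n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return cf.ContactMap(m, bin_size=bin_size)


class TestIO:
    def test_triplet_symmetric_completion(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("0 1 4\n")
        m = cf.read_contact_matrix(p, format="triplet", n_bins=3)
        assert m[0, 1] == m[1, 0] == 4
        assert m.sum() == 8

    def test_dense_round_trip(self, tmp_path):
        m = random_probability_map(10, seed=1).matrix
        p = tmp_path / "m.tsv"
        write_contact_matrix(m, p)
        back = cf.read_contact_matrix(p, format="dense_tsv")
        p2 = tmp_path / "m2.tsv"
        write_contact_matrix(back, p2)
        assert p.read_text() == p2.read_text()

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1 4\n2 x 1\n")
        with pytest.raises(ValueError, match="line 2"):
            cf.read_contact_matrix(p, format="triplet")

    def test_asymmetric_dense_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        np.savetxt(p, np.array([[1.0, 5.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric|asymmetric"):
            cf.read_contact_matrix(p, format="dense_tsv")

    def test_out_of_range_triplet_index(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("0 5 1\n")
        with pytest.raises(ValueError, match="out of range"):
            cf.read_contact_matrix(p, format="triplet", n_bins=3)


class TestNormalization:
    def test_unit_vector_is_identity(self):
        raw = random_probability_map(8, 2).matrix
        out, mask = cf.apply_normalization(raw, np.ones(8))
        assert np.allclose(out, raw)
        assert mask.all()

    def test_vector_scaling(self):
        raw = np.array([[0.0, 8.0], [8.0, 0.0]])
        out, _ = cf.apply_normalization(raw, np.array([2.0, 2.0]))
        assert out[0, 1] == pytest.approx(2.0)

    def test_bad_entries_masked(self):
        raw = random_probability_map(5, 3).matrix
        v = np.array([1.0, 1.0, 0.0, 1.0, np.nan])
        out, mask = cf.apply_normalization(raw, v)
        assert list(mask) == [True, True, False, True, False]
        assert np.isnan(out[2]).all() and np.isnan(out[:, 4]).all()

    def test_masked_bins_excluded_from_metrics(self):
        raw = random_probability_map(30, 4).matrix * 100
        v = np.ones(30)
        v[7] = 0.0
        balanced, mask = cf.apply_normalization(raw, v)
        cmap = cf.to_probability(balanced, c_diag=100.0, mask=mask)
        full = cf.to_probability(raw, c_diag=100.0)
        # global PCC ignores the masked bin entirely
        sub = np.delete(np.delete(raw, 7, 0), 7, 1)
        submap = cf.to_probability(sub, c_diag=100.0)
        assert cf.pcc_maps(cmap, cmap) == pytest.approx(1.0)
        assert cf.pcc_maps(submap, submap) == pytest.approx(1.0)


class TestProbabilityConversion:
    def test_reference_diagonal_level(self):
        n = 10
        raw = np.full((n, n), 100.0)
        np.fill_diagonal(raw, DEFAULT_C_DIAG)
        cmap = cf.to_probability(raw)  # c_diag from the data diagonal
        assert np.allclose(np.diag(cmap.matrix), 1.0)

    def test_unit_divisor_is_identity(self):
        m = random_probability_map(6, 5).matrix
        cmap = cf.to_probability(m, c_diag=1.0)
        assert np.allclose(cmap.matrix, np.minimum(m, 1.0))

    def test_values_capped_at_one(self):
        raw = np.array([[1035.0, 2070.0], [2070.0, 1035.0]])
        cmap = cf.to_probability(raw, c_diag=1035.0)
        assert cmap.matrix[0, 1] == 1.0


class TestCorrelations:
    def test_self_correlation_is_one(self):
        m = random_probability_map(40, 6)
        assert cf.pcc_maps(m, m) == pytest.approx(1.0)

    def test_scale_invariance(self):
        m = random_probability_map(40, 7)
        doubled = cf.ContactMap(2 * m.matrix, bin_size=m.bin_size)
        assert cf.pcc_maps(m, doubled) == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        a = random_probability_map(30, 8)
        b = random_probability_map(30, 9)
        assert cf.pcc_maps(a, b) == pytest.approx(cf.pcc_maps(b, a))
        assert cf.scc(a, b) == pytest.approx(cf.scc(b, a))

    def test_hand_computed_four_bin_example(self):
        m1 = np.array([[1.0, 0.2, 0.1, 0.05],
                       [0.2, 1.0, 0.3, 0.1],
                       [0.1, 0.3, 1.0, 0.2],
                       [0.05, 0.1, 0.2, 1.0]])
        m2 = np.array([[1.0, 0.25, 0.15, 0.02],
                       [0.25, 1.0, 0.2, 0.15],
                       [0.15, 0.2, 1.0, 0.3],
                       [0.02, 0.15, 0.3, 1.0]])
        x = m1[np.triu_indices(4, 1)]
        y = m2[np.triu_indices(4, 1)]
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        got = cf.pcc_maps(cf.ContactMap(m1), cf.ContactMap(m2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_by_distance_strata(self):
        a = random_probability_map(30, 10)
        out = cf.pcc_maps(a, a, mode="by_distance")
        valid = np.isfinite(out)
        assert valid.sum() > 10
        assert np.allclose(out[valid], 1.0)

    def test_scc_identity_any_smoothing(self):
        m = random_probability_map(50, 11)
        for h in (0, 1, 3):
            assert cf.scc(m, m, h=h) == pytest.approx(1.0)

    def test_scc_null_for_independent_noise(self):
        rng = np.random.default_rng(12)
        n = 80
        a = rng.uniform(0.1, 0.9, (n, n))
        b = rng.uniform(0.1, 0.9, (n, n))
        a = cf.ContactMap(0.5 * (a + a.T))
        b = cf.ContactMap(0.5 * (b + b.T))
        assert abs(cf.scc(a, b, h=0)) < 0.1


class TestInsulation:
    def test_uniform_map_constant_profile(self):
        m = cf.ContactMap(np.full((50, 50), 0.3), bin_size=5000)
        prof = cf.insulation_profile(m, window_bp=50_000)
        vals = prof.scores[prof.valid]
        assert np.allclose(vals, 0.3)

    def test_two_block_minimum_at_boundary(self):
        n = 60
        block = np.full((n, n), 0.05)
        block[:30, :30] = 0.8
        block[30:, 30:] = 0.8
        m = cf.ContactMap(block, bin_size=5000)
        prof = cf.insulation_profile(m, window_bp=50_000)
        assert np.nanargmin(prof.scores) == 30

    def test_matches_naive_double_loop(self):
        m = random_probability_map(50, 13)
        w = 8
        prof = cf.insulation_profile(m, window_bp=w * m.bin_size)
        for b in range(w, 50 - w + 1):
            ref = m.matrix[b - w:b, b:b + w].mean()
            assert prof.scores[b] == pytest.approx(ref, abs=1e-12)

    def test_window_granularity_enforced(self):
        m = random_probability_map(50, 14)
        with pytest.raises(ValueError):
            cf.insulation_profile(m, window_bp=7_503)


class TestBoundaries:
    def test_monotone_profile_has_none(self):
        prof = cf.InsulationProfile(np.linspace(1, 0.2, 40), window_bins=5)
        assert len(cf.detect_boundaries(prof)) == 0

    def test_planted_two_boundary_toy(self):
        scores = np.full(60, 0.5)
        scores[20] = 0.1
        scores[40] = 0.15
        prof = cf.InsulationProfile(scores, window_bins=5)
        got = cf.detect_boundaries(prof, prominence=0.2)
        assert list(got) == [20, 40]

    def test_plateau_reports_leftmost(self):
        scores = np.full(30, 0.5)
        scores[10:13] = 0.1
        prof = cf.InsulationProfile(scores, window_bins=3)
        got = cf.detect_boundaries(prof, prominence=0.2)
        assert list(got) == [10]


class TestMatchingScore:
    def test_identical_lists(self):
        assert cf.matching_score([(1, 5), (10, 20)],
                                 [(1, 5), (10, 20)], 0) == 1.0

    def test_disjoint_lists(self):
        assert cf.matching_score([1, 2], [500, 600], 10) == 0.0

    def test_tolerance_semantics_for_pairs(self):
        assert cf.matching_score([(10, 20)], [(11, 19)], 1) == 1.0
        assert cf.matching_score([(10, 20)], [(11, 19)], 0) == 0.0

    def test_one_to_one_greedy(self):
        # two reference items cannot both claim the single candidate
        assert cf.matching_score([5, 6], [5], 2) == 0.5

    def test_empty_reference_flagged(self):
        with pytest.raises(ValueError):
            cf.matching_score([], [1], 1)


class TestEnhancement:
    def test_uniform_map_ratio_one(self):
        m = cf.ContactMap(np.full((30, 30), 0.4))
        assert cf.contact_enhancement(m, (5, 20)) == pytest.approx(1.0)

    def test_constructed_patch_ratio(self):
        n = 23
        m = np.full((n, n), 0.1)
        m[11, 17] = m[17, 11] = 0.9
        got = cf.contact_enhancement(cf.ContactMap(m), (11, 17),
                                     background_half_width=5)
        assert got == pytest.approx(9.0)

    def test_zero_background_flagged(self):
        m = np.zeros((30, 30))
        m[5, 20] = m[20, 5] = 0.0
        out = cf.contact_enhancement(cf.ContactMap(m), (5, 20))
        assert np.isnan(out)

    def test_random_background_constant_map(self):
        m = cf.ContactMap(np.full((60, 60), 0.2))
        vals, thr = cf.random_pair_background(m, [(10, 30)], n=50, seed=0)
        assert thr == pytest.approx(1.0)

    def test_random_background_matches_separations(self):
        m = random_probability_map(80, 15)
        ref = [(10, 20), (30, 55), (5, 45)]
        rng_sep = {10, 25, 40}
        vals, _ = cf.random_pair_background(m, ref, n=300, seed=1)
        assert len(vals) == 300

    def test_random_background_deterministic(self):
        m = random_probability_map(60, 16)
        a = cf.random_pair_background(m, [(5, 25)], n=40, seed=9)
        b = cf.random_pair_background(m, [(5, 25)], n=40, seed=9)
        assert np.array_equal(a[0], b[0])


class TestLogEigen:
    def test_full_rank_reconstruction(self):
        m = random_probability_map(25, 17)
        res = cf.log_eigen_analysis(m, k=25)
        logm = np.log(m.matrix + res.pseudocount)
        assert np.abs(res.reconstruction - logm).max() < 1e-8

    def test_rank_one_log_matrix_single_eigenvalue(self):
        # construct a map whose log is exactly rank 1
        v = np.random.default_rng(18).normal(size=10) * 0.3
        m = np.exp(np.outer(v, v))
        res = cf.log_eigen_analysis(cf.ContactMap(m), k=10, pseudocount=0.0)
        assert np.abs(res.eigenvalues[1:]).max() < 1e-10 * np.abs(
            res.eigenvalues[0])

    def test_self_similarity_is_one(self):
        m = random_probability_map(30, 19)
        res = cf.log_eigen_analysis(m, k=5)
        sims = eigenvector_similarity(res, res, k=5)
        assert np.allclose(sims, 1.0)


class TestInteractionMatrices:
    def test_equal_eigenvalues_complexity(self):
        p = cf.EnergyParameters()
        for b in range(p.n_sep_bins):
            p.alpha_cs[b] = np.eye(15)
        out = cf.interaction_matrix_analysis(p, [100])
        comp = out["per_separation"][100]["complexity"]
        assert comp[0] == pytest.approx(1 / 15)

    def test_rank_one_complexity(self):
        p = cf.EnergyParameters()
        v = np.linspace(-1, 1, 15)
        for b in range(p.n_sep_bins):
            p.alpha_cs[b] = np.outer(v, v)
        out = cf.interaction_matrix_analysis(p, [100])
        comp = out["per_separation"][100]["complexity"]
        assert comp[0] == pytest.approx(1.0)

    def test_self_pcc_is_one(self):
        p = cf.EnergyParameters()
        rng = np.random.default_rng(20)
        a = rng.normal(size=(15, 15))
        sym = 0.5 * (a + a.T)
        for b in range(p.n_sep_bins):
            p.alpha_cs[b] = sym
        out = cf.interaction_matrix_analysis(p, [100, 1000])
        assert out["matrix_pcc"][0, 1] == pytest.approx(1.0)


def test_top_pairs_rank_order():
    m = random_probability_map(20, 21)
    pairs = top_pairs(m, n=5, min_separation=2)
    scores = [s for _, _, s in pairs]
    assert scores == sorted(scores, reverse=True)
    assert all(j - i >= 2 for i, j, _ in pairs)
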