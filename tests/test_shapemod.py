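"""Phenotyping stage: GPA, RV similarity, spectral segmentation, PCA,
parallel analysis, PLS adjustment, robust outlier QC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from facemodkit import shapemod, synthgen
from facemodkit.shapemod import LandmarkSet


def _random_faces(n=20, L=16, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=10.0, size=(L, 3))
    coords = base[None] + rng.normal(scale=noise, size=(n, L, 3))
    return LandmarkSet(np.array([f"i{i}" for i in range(n)]), coords)


def _rigidly_perturb(faces, seed=0, max_angle=180.0):
    rng = np.random.default_rng(seed)
    coords = np.empty_like(faces.coords)
    for i in range(faces.n):
        r = special_ortho_group.rvs(3, random_state=rng)
        s = rng.uniform(0.8, 1.2)
        t = rng.uniform(-30, 30, size=3)
        coords[i] = s * faces.coords[i] @ r.T + t
    return LandmarkSet(faces.ids, coords)


class TestGPA:
    def test_rotated_translated_copy_superimposes_exactly(self):
        rng = np.random.default_rng(1)
        shape = rng.normal(scale=5.0, size=(10, 3))
        theta = np.deg2rad(30)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        faces = LandmarkSet(
            np.array(["a", "b"]), np.stack([shape, shape @ rot.T + [3.0, -2.0, 7.0]])
        )
        aligned, _ = shapemod.gpa_align(faces)
        assert np.max(np.abs(aligned.coords[0] - aligned.coords[1])) < 1e-8

    def test_procrustes_distances_invariant_to_rigid_nuisance(self):
        faces = _random_faces(n=12, seed=3)
        a1, _ = shapemod.gpa_align(faces)
        a2, _ = shapemod.gpa_align(_rigidly_perturb(faces, seed=9))

        def pdists(aligned):
            x = aligned.coords.reshape(aligned.n, -1)
            return np.array(
                [
                    np.linalg.norm(x[i] - x[j])
                    for i, j in itertools.combinations(range(aligned.n), 2)
                ]
            )

        assert np.allclose(pdists(a1), pdists(a2), atol=1e-8)

    def test_idempotence(self):
        aligned, _ = shapemod.gpa_align(_random_faces(seed=5))
        again, _ = shapemod.gpa_align(aligned)
        assert np.max(np.abs(again.coords - aligned.coords)) < 1e-8

    def test_no_reflection_even_for_mirrored_input(self):
        # a mirrored configuration must NOT be superimposed by a reflection
        rng = np.random.default_rng(2)
        shape = rng.normal(size=(12, 3))
        mirrored = shape * np.array([-1.0, 1.0, 1.0])
        faces = LandmarkSet(np.array(["a", "b"]), np.stack([shape, mirrored]))
        aligned, _ = shapemod.gpa_align(faces)
        # perfect superimposition is impossible with proper rotations only
        assert np.max(np.abs(aligned.coords[0] - aligned.coords[1])) > 1e-3

    def test_degenerate_configuration_rejected(self):
        coords = np.zeros((3, 5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            shapemod.gpa_align(LandmarkSet(np.array(["a", "b", "c"]), coords))

    def test_centroid_sizes_recorded(self):
        faces = _random_faces(seed=6)
        aligned, _ = shapemod.gpa_align(faces)
        centered = faces.coords - faces.coords.mean(axis=1, keepdims=True)
        sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
        assert np.allclose(aligned.centroid_sizes, sizes)


class TestLandmarkSimilarity:
    def test_duplicated_landmark_has_rv_one(self):
        faces = _random_faces(n=30, L=8, seed=1)
        coords = np.concatenate([faces.coords, faces.coords[:, :1, :]], axis=1)
        aligned = LandmarkSet(faces.ids, coords, aligned=True)
        s = shapemod.landmark_similarity(aligned)
        assert s[0, 8] == pytest.approx(1.0, abs=1e-10)

    def test_range_symmetry_diagonal(self):
        aligned, _ = shapemod.gpa_align(_random_faces(n=25, seed=2))
        s = shapemod.landmark_similarity(aligned)
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 1.0)
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_independent_landmarks_rv_shrinks_with_n(self):
        def mean_offdiag(n, seed=0):
            rng = np.random.default_rng(seed)
            coords = rng.normal(size=(n, 6, 3))
            s = shapemod.landmark_similarity(
                LandmarkSet(np.arange(n).astype(str), coords, aligned=True)
            )
            off = s[~np.eye(6, dtype=bool)]
            return off.mean()

        small_n, large_n = mean_offdiag(100), mean_offdiag(5000)
        assert large_n < 0.02  # bias term vanishes
        assert large_n < small_n

    def test_rv_invariant_to_common_rotation(self):
        rng = np.random.default_rng(4)
        aligned, _ = shapemod.gpa_align(_random_faces(n=40, seed=4))
        s1 = shapemod.landmark_similarity(aligned)
        q = special_ortho_group.rvs(3, random_state=rng)
        s2 = shapemod.landmark_similarity(
            LandmarkSet(aligned.ids, aligned.coords @ q.T, aligned=True)
        )
        assert np.allclose(s1, s2, atol=1e-10)


def _planted_similarity(p=12, within=0.9, between=0.1):
    s = np.full((p, p), between)
    s[: p // 2, : p // 2] = within
    s[p // 2 :, p // 2 :] = within
    np.fill_diagonal(s, 1.0)
    return s


def _brute_force_ncut(s):
    """Smallest normalized cut over all bipartitions (oracle, p <= 14)."""
    p = s.shape[0]
    adj = s.copy()
    np.fill_diagonal(adj, 0.0)
    deg = adj.sum(axis=1)
    best, best_parts = np.inf, None
    for mask in range(1, 2 ** (p - 1)):
        a = np.array([bool(mask >> i & 1) for i in range(p)])
        if a.all() or (~a).all():
            continue
        cut = adj[np.ix_(a, ~a)].sum()
        ncut = cut / deg[a].sum() + cut / deg[~a].sum()
        if ncut < best:
            best, best_parts = ncut, (np.flatnonzero(a), np.flatnonzero(~a))
    return best_parts


class TestSpectralBipartition:
    def test_planted_blocks_match_brute_force(self):
        s = _planted_similarity()
        a, b = shapemod.spectral_bipartition(s)
        oracle_a, oracle_b = _brute_force_ncut(s)
        assert {frozenset(a), frozenset(b)} == {
            frozenset(oracle_a),
            frozenset(oracle_b),
        }

    def test_permutation_equivariance(self):
        s = _planted_similarity()
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        a1, b1 = shapemod.spectral_bipartition(s)
        a2, b2 = shapemod.spectral_bipartition(s[np.ix_(perm, perm)], indices=perm)
        assert {frozenset(a1), frozenset(b1)} == {frozenset(a2), frozenset(b2)}

    def test_all_equal_similarity_deterministic_tie_break(self):
        s = np.full((8, 8), 0.5)
        np.fill_diagonal(s, 1.0)
        a, b = shapemod.spectral_bipartition(s)
        assert 0 in a  # lowest-index landmark goes to part A
        assert len(a) > 0 and len(b) > 0
        a2, b2 = shapemod.spectral_bipartition(s)
        assert np.array_equal(a, a2) and np.array_equal(b, b2)

    def test_disconnected_components_split_first(self):
        s = np.zeros((9, 9))
        s[:4, :4] = 0.8
        s[4:, 4:] = 0.8
        np.fill_diagonal(s, 1.0)
        a, b = shapemod.spectral_bipartition(s)
        assert {frozenset(a), frozenset(b)} == {
            frozenset(range(4)),
            frozenset(range(4, 9)),
        }


class TestHierarchy:
    def test_single_level_is_full_face(self):
        aligned, _ = shapemod.gpa_align(_random_faces(seed=8))
        hier = shapemod.build_hierarchy(aligned, n_levels=1)
        assert len(hier.segments) == 1
        assert np.array_equal(hier.segments[0].indices, np.arange(16))

    def test_planted_leaves_recovered(self):
        cfg = synthgen.SynthConfig(
            n_individuals=300, n_landmarks=64, n_levels=3, seed=2
        )
        faces, gt = synthgen.generate_faces(cfg)
        aligned, _ = shapemod.gpa_align(faces)
        hier = shapemod.build_hierarchy(aligned, n_levels=3)
        hier.validate_partition()
        assert len(hier.segments) == 7
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            gt.true_segment_assignment, hier.leaf_labels(64)
        )
        assert ari > 0.9

    def test_small_branch_stops_and_reports_incomplete(self):
        aligned, _ = shapemod.gpa_align(_random_faces(n=30, L=12, seed=3))
        hier = shapemod.build_hierarchy(aligned, n_levels=4, min_split=8)
        assert not hier.complete
        assert len(hier.segments) < 2**4 - 1

    def test_serialization_roundtrip(self, small_phenotypes):
        hier, _, _ = small_phenotypes
        back = shapemod.SegmentHierarchy.from_dict(hier.to_dict())
        assert back.segment_ids == hier.segment_ids
        for sid in hier.segment_ids:
            assert np.array_equal(back.get(sid).indices, hier.get(sid).indices)


class TestModulePCA:
    def test_rank_one_variation_concentrates_variance(self):
        rng = np.random.default_rng(0)
        loading = rng.normal(size=24)
        loading /= np.linalg.norm(loading)
        scores = rng.normal(scale=3.0, size=100)
        x = np.outer(scores, loading) + rng.normal(scale=0.01, size=(100, 24))
        lm = LandmarkSet(
            np.arange(100).astype(str), x.reshape(100, 8, 3), aligned=True
        )
        phen = shapemod.module_pca(lm)
        assert phen.eigenvalues[0] / phen.eigenvalues.sum() > 0.99

    def test_variance_conservation_and_reconstruction(self):
        aligned, _ = shapemod.gpa_align(_random_faces(n=30, seed=4))
        phen = shapemod.module_pca(aligned)
        x = aligned.coords.reshape(30, -1)
        total_var = ((x - x.mean(axis=0)) ** 2).sum() / 29
        assert phen.eigenvalues.sum() == pytest.approx(total_var, rel=1e-10)
        recon = phen.mean_shape.reshape(-1) + phen.scores @ phen.loadings.T
        assert np.max(np.abs(recon - x)) < 1e-8

    def test_scores_uncorrelated_loadings_orthonormal(self):
        aligned, _ = shapemod.gpa_align(_random_faces(n=40, seed=5))
        phen = shapemod.module_pca(aligned)
        c = np.corrcoef(phen.scores.T)
        assert np.max(np.abs(c - np.eye(phen.k))) < 1e-8
        g = phen.loadings.T @ phen.loadings
        assert np.allclose(g, np.eye(phen.k), atol=1e-10)


class TestParallelAnalysis:
    def test_pure_noise_hits_floor(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = shapemod.parallel_analysis(
                rng.normal(size=(200, 30)), n_perm=30, rng=rng
            )
            hits += k == 1
        assert hits >= 18  # floor value in >= 95% of runs (binomial slack)

    def test_five_strong_components_retained(self):
        rng = np.random.default_rng(1)
        n, p = 300, 40
        load = np.linalg.qr(rng.normal(size=(p, 5)))[0]
        x = rng.normal(size=(n, 5)) * np.sqrt(50.0) @ load.T + rng.normal(
            size=(n, p)
        )
        assert shapemod.parallel_analysis(x, n_perm=50, rng=3) == 5

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 20))
        assert shapemod.parallel_analysis(x, rng=11) == shapemod.parallel_analysis(
            x, rng=11
        )


class TestPLSAdjust:
    def _phen_and_cov(self, n=500, k=4, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "id": np.arange(n).astype(str),
                "sex": rng.binomial(1, 0.5, n).astype(float),
                "age": rng.uniform(5, 40, n),
            }
        )
        scores = rng.normal(size=(n, k))
        scores[:, 0] += effect * cov["sex"].to_numpy()
        phen = shapemod.ModulePhenotype(
            1, cov["id"].to_numpy(), scores, np.ones(k), np.eye(k), np.zeros((1, 3))
        )
        return phen, cov

    def test_residuals_orthogonal_to_covariates(self):
        phen, cov = self._phen_and_cov(effect=2.0)
        adj = shapemod.pls_adjust(phen, cov)
        sex = cov["sex"].to_numpy()
        for j in range(adj.k):
            r = np.corrcoef(adj.scores[:, j], sex)[0, 1]
            assert abs(r) < 1e-8
        assert adj.adjusted

    def test_independent_covariates_change_little(self):
        phen, cov = self._phen_and_cov(effect=0.0)
        adj = shapemod.pls_adjust(phen, cov)
        rel = np.max(np.abs(adj.scores - phen.scores)) / phen.scores.std()
        assert rel < 0.3  # O(sqrt(p/n)) attenuation only

    def test_constant_column_dropped_with_warning(self):
        phen, cov = self._phen_and_cov()
        cov["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant covariate"):
            shapemod.pls_adjust(phen, cov)

    def test_fully_explained_phenotype_flagged(self):
        phen, cov = self._phen_and_cov()
        phen.scores = np.outer(
            cov["age"].to_numpy() - cov["age"].mean(), np.ones(phen.k)
        )
        with pytest.warns(UserWarning, match="fully explained"):
            adj = shapemod.pls_adjust(phen, cov)
        assert adj.zero_residual
        assert np.max(np.abs(adj.scores)) < 1e-10


class TestMahalanobisOutliers:
    def _phen(self, scores):
        n, k = scores.shape
        return shapemod.ModulePhenotype(
            1, np.arange(n).astype(str), scores, np.ones(k), np.eye(k), np.zeros((1, 3))
        )

    def test_planted_outlier_flagged_clean_data_mostly_not(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(500, 4))
        scores[7, 0] = 10.0
        d2, flags, qq = shapemod.mahalanobis_outliers(self._phen(scores))
        assert flags[7]
        assert flags.sum() <= 3  # Bonferroni-style control on the rest
        assert len(qq) == 500

    def test_distances_affine_invariant(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(300, 3))
        a = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        d1, _, _ = shapemod.mahalanobis_outliers(self._phen(scores))
        d2, _, _ = shapemod.mahalanobis_outliers(self._phen(scores @ a.T))
        assert np.allclose(d1, d2, rtol=1e-6, atol=1e-8)


def test_pipeline_produces_adjusted_modules(small_phenotypes, small_dataset):
    hier, phens, qc = small_phenotypes
    assert len(phens) == 7  # 2^3 - 1 segments
    hier.validate_partition()
    for phen in phens:
        assert phen.adjusted
        assert phen.k >= 1
        assert phen.n == small_dataset.faces.n
        assert phen.segment_id in qc
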