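"""Screening stage: residualization, GLM t-maps, permutation p, clusters."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from morphotrait import (CohortConfig, EffectSpec, GLMResult, GridParams,
                         VoxelClusterEffect, extract_clusters,
                         generate_subjects, generate_voxel_maps, glm_tmap,
                         parametric_pvalues, permutation_pvalues, residualize,
                         roi_means)
from morphotrait.cohort import VoxelImageSet, sphere_voxels
from morphotrait.exceptions import DesignMatrixError, DimensionError


# ------------------------------------------------------------------ oracles

def normal_equations_residuals(y, X):
    """Independent least-squares oracle via the normal equations."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def flood_fill_components(binary, connectivity=26):
    """Brute-force BFS connected components of a 3-D boolean grid."""
    if connectivity == 26:
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    seen = set()
    comps = []
    coords = {tuple(c) for c in np.argwhere(binary)}
    for start in sorted(coords):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        comp = set()
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nb in coords and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def toy_images(values, voxel_size=2.0):
    """Wrap an (n, X, Y, Z) array as a VoxelImageSet with a full-grid mask."""
    values = np.asarray(values, dtype=float)
    return VoxelImageSet(data=values, mask=np.ones(values.shape[1:], bool),
                         voxel_size_mm=voxel_size,
                         subject_ids=tuple(f"s{i}" for i in range(len(values))))


# ------------------------------------------------------------------ residualize

class TestResidualize:
    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal((30, 3))])
        y = rng.standard_normal((30, 5))
        got = residualize(y, X[:, 1:])
        want = normal_equations_residuals(y, X)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_orthogonality_to_design(self, rng):
        cov = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        res = residualize(y, cov)
        X = np.column_stack([np.ones(40), cov])
        rel = np.abs(X.T @ res) / (np.linalg.norm(X, axis=0)
                                   * np.linalg.norm(res) + 1e-300)
        assert rel.max() < 1e-8

    def test_projection_idempotent(self, rng):
        cov = rng.standard_normal((25, 2))
        y = residualize(rng.standard_normal(25), cov)
        np.testing.assert_allclose(residualize(y, cov), y, atol=1e-10)

    def test_perfect_fit_gives_zero(self, rng):
        age = rng.uniform(20, 26, 50)
        res = residualize(2.0 * age, age[:, None])
        assert np.abs(res).max() < 1e-9

    def test_rank_deficiency_names_column(self, rng):
        import pandas as pd
        age = rng.uniform(20, 26, 30)
        cov = pd.DataFrame({"age": age, "age_copy": age})
        with pytest.raises(DesignMatrixError, match="age"):
            residualize(rng.standard_normal(30), cov)


# ------------------------------------------------------------------ glm

class TestGlmTmap:
    def test_matches_textbook_t_on_toy(self):
        # 6-subject toy, one voxel, no covariates: closed-form simple
        # regression t = b / se(b)
        aq = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 2.9, 3.4, 4.8, 5.1, 6.5])
        images = toy_images(y.reshape(6, 1, 1, 1))
        glm = glm_tmap(images, aq, None)
        res = stats.linregress(aq, y)
        t_oracle = res.slope / res.stderr
        assert glm.df == 4
        np.testing.assert_allclose(glm.t_map[0, 0, 0], t_oracle, rtol=1e-10)
        np.testing.assert_allclose(glm.beta_map[0, 0, 0], res.slope,
                                   rtol=1e-10)

    def test_matches_multiple_regression_oracle(self, rng):
        import statsmodels.api as sm
        n = 25
        aq = rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        y = rng.standard_normal((n, 8))
        glm = glm_tmap(toy_images(y.reshape(n, 2, 2, 2)), aq, cov)
        X = sm.add_constant(np.column_stack([aq, cov]))
        for v in range(8):
            fit = sm.OLS(y[:, v], X).fit()
            np.testing.assert_allclose(glm.t_map.ravel()[v],
                                       fit.tvalues[1], rtol=1e-8)

    def test_orthogonal_trait_gives_zero_t(self, rng):
        n = 20
        aq = rng.standard_normal(n)
        y = residualize(rng.standard_normal(n), aq[:, None])
        glm = glm_tmap(toy_images(y.reshape(n, 1, 1, 1)), aq, None)
        assert abs(glm.t_map[0, 0, 0]) < 1e-8

    def test_injected_cluster_raises_t_inside(self, default_subjects):
        gp = GridParams(shape=(16, 16, 16))
        eff = EffectSpec(voxel_clusters=(
            VoxelClusterEffect((8, 8, 8), 3.0, 0.05),), null=False)
        images = generate_voxel_maps(default_subjects, eff, gp, seed=21)
        aq = default_subjects["aq_total"].to_numpy()
        glm = glm_tmap(images, aq, None)
        sphere = sphere_voxels((8, 8, 8), 3.0, gp.shape)
        inside = np.zeros(gp.shape, bool)
        inside[tuple(sphere.T)] = True
        assert (glm.t_map[inside & images.mask].mean()
                > glm.t_map[~inside & images.mask].mean() + 1.0)

    def test_constant_voxel_t_zero_with_warning(self, rng, caplog):
        n = 15
        y = rng.standard_normal((n, 2))
        y[:, 1] = 3.7
        images = toy_images(y.reshape(n, 2, 1, 1))
        with caplog.at_level("WARNING"):
            glm = glm_tmap(images, rng.standard_normal(n), None)
        assert glm.t_map[1, 0, 0] == 0.0
        assert "constant" in caplog.text


# ------------------------------------------------------------------ permutation

@pytest.fixture(scope="module")
def null_setup():
    rng = np.random.default_rng(1234)
    n = 30
    aq = rng.standard_normal(n)
    cov = rng.standard_normal((n, 2))
    images = toy_images(rng.standard_normal((n, 8, 8, 6)))
    return images, aq, cov


class TestPermutationPvalues:
    def test_uniform_under_null(self, null_setup):
        images, aq, cov = null_setup
        glm = glm_tmap(images, aq, cov)
        glm = permutation_pvalues(glm, images, aq, cov, n_perm=1000, seed=5)
        p = glm.p_map[images.mask]
        # +1/+1 estimator support is {1/(N+1) ... 1}; compare against that
        ks = stats.kstest(p, stats.uniform(loc=1 / 1001, scale=1000 / 1001).cdf)
        assert ks.pvalue > 0.01

    def test_extreme_voxel_gets_minimum_p(self):
        rng = np.random.default_rng(7)
        n = 40
        aq = rng.standard_normal(n)
        y = rng.standard_normal((n, 4))
        y[:, 0] = 5.0 * aq + 0.01 * rng.standard_normal(n)
        images = toy_images(y.reshape(n, 4, 1, 1))
        glm = glm_tmap(images, aq, None)
        glm = permutation_pvalues(glm, images, aq, None, n_perm=200, seed=3)
        assert glm.p_map[0, 0, 0] == pytest.approx(1 / 201)

    def test_zero_t_voxel_gets_p_near_one(self, rng):
        n = 24
        aq = rng.standard_normal(n)
        y = residualize(rng.standard_normal(n), aq[:, None])
        images = toy_images(y.reshape(n, 1, 1, 1))
        glm = glm_tmap(images, aq, None)
        glm = permutation_pvalues(glm, images, aq, None, n_perm=200, seed=3)
        assert glm.p_map[0, 0, 0] > 0.95

    def test_subject_relabeling_leaves_pvalues_statistically_invariant(self):
        rng = np.random.default_rng(11)
        n = 24
        aq = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        data = rng.standard_normal((n, 6, 6, 4))
        images = toy_images(data)
        n_perm = 2000
        glm = glm_tmap(images, aq, cov)
        p1 = permutation_pvalues(glm, images, aq, cov, n_perm=n_perm,
                                 seed=5).p_map
        order = rng.permutation(n)
        images2 = toy_images(data[order])
        glm2 = glm_tmap(images2, aq[order], cov[order])
        p2 = permutation_pvalues(glm2, images2, aq[order], cov[order],
                                 n_perm=n_perm, seed=5).p_map
        # identical t-maps; permutation p-values agree to MC resolution
        np.testing.assert_allclose(glm.t_map, glm2.t_map, atol=1e-10)
        assert np.abs(p1 - p2).max() < 5 * np.sqrt(0.25 / n_perm)

    def test_too_few_permutations_rejected(self, null_setup):
        images, aq, cov = null_setup
        glm = glm_tmap(images, aq, cov)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalues(glm, images, aq, cov, n_perm=50)


# ------------------------------------------------------------------ clusters

def make_glm(p_map, beta_map, t_map=None, mask=None):
    mask = np.ones(p_map.shape, bool) if mask is None else mask
    t_map = beta_map if t_map is None else t_map
    return GLMResult(beta_map=beta_map, t_map=t_map, mask=mask, df=10,
                     p_map=p_map, n_permutations=0)


class TestExtractClusters:
    def test_spherical_blob_size_and_mm3(self):
        shape = (16, 16, 16)
        sphere = sphere_voxels((8, 8, 8), 3.3, shape)
        p = np.ones(shape)
        beta = np.zeros(shape)
        p[tuple(sphere.T)] = 0.01
        beta[tuple(sphere.T)] = 1.0
        rois = extract_clusters(make_glm(p, beta), k_min=100,
                                voxel_size_mm=2.0)
        assert len(rois) == 1
        assert rois[0].size_voxels == len(sphere)
        assert rois[0].size_mm3 == len(sphere) * 8.0
        assert rois[0].sign == "positive"
        rois_high = extract_clusters(make_glm(p, beta),
                                     k_min=len(sphere) + 1)
        assert rois_high == []

    def test_opposite_signs_never_merge(self):
        shape = (12, 12, 12)
        p = np.ones(shape)
        beta = np.zeros(shape)
        p[2:5, 2:8, 2:8] = 0.01     # negative block
        beta[2:5, 2:8, 2:8] = -1.0
        p[5:8, 2:8, 2:8] = 0.01     # positive block, face-adjacent
        beta[5:8, 2:8, 2:8] = 1.0
        rois = extract_clusters(make_glm(p, beta), k_min=10)
        assert len(rois) == 2
        assert {r.sign for r in rois} == {"positive", "negative"}

    def test_peak_voxel_is_lexicographically_smallest_max(self):
        shape = (8, 8, 8)
        p = np.ones(shape)
        beta = np.zeros(shape)
        t = np.zeros(shape)
        p[2:6, 2:6, 2:6] = 0.01
        beta[2:6, 2:6, 2:6] = 1.0
        t[2:6, 2:6, 2:6] = 1.0
        t[3, 3, 3] = t[5, 5, 5] = 7.0   # tied maxima
        rois = extract_clusters(make_glm(p, beta, t_map=t), k_min=10)
        assert rois[0].peak_voxel == (3, 3, 3)

    def test_sorted_by_size_descending_with_ids(self):
        shape = (16, 16, 16)
        p = np.ones(shape)
        beta = np.zeros(shape)
        p[1:3, 1:3, 1:3] = 0.01; beta[1:3, 1:3, 1:3] = 1.0          # 8 vox
        p[8:12, 8:12, 8:12] = 0.01; beta[8:12, 8:12, 8:12] = 1.0    # 64 vox
        rois = extract_clusters(make_glm(p, beta), k_min=1)
        assert [r.size_voxels for r in rois] == [64, 8]
        assert [r.roi_id for r in rois] == ["roi-01", "roi-02"]

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            shape = (12, 12, 12)
            p = rng.random(shape)
            beta = rng.standard_normal(shape)
            rois = extract_clusters(make_glm(p, beta), p_threshold=0.2,
                                    k_min=1, connectivity=connectivity)
            got = {(r.sign, frozenset(map(tuple, r.voxel_list)))
                   for r in rois}
            want = set()
            for sign, mask_ in [("positive", beta > 0), ("negative", beta < 0)]:
                for comp in flood_fill_components((p < 0.2) & mask_,
                                                  connectivity):
                    want.add((sign, comp))
            assert got == want

    def test_missing_pmap_rejected(self):
        glm = GLMResult(beta_map=np.zeros((4, 4, 4)),
                        t_map=np.zeros((4, 4, 4)),
                        mask=np.ones((4, 4, 4), bool), df=5)
        with pytest.raises(ValueError, match="p_map"):
            extract_clusters(glm)

    def test_null_suprathreshold_fraction_matches_threshold(self):
        # with parametric p and independent voxels, ~5% fall under 0.05
        cfg = CohortConfig(n_exploration=60, n_validation=60, seed=31)
        subjects = generate_subjects(cfg)
        gp = GridParams(shape=(12, 12, 12), smooth_sigma_mm=0.0)
        images = generate_voxel_maps(subjects, EffectSpec(), gp, seed=32)
        glm = parametric_pvalues(
            glm_tmap(images, subjects["aq_total"].to_numpy(), None))
        frac = (glm.p_map[images.mask] < 0.05).mean()
        n_vox = images.mask.sum()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_vox)


# ------------------------------------------------------------------ roi means

class TestRoiMeans:
    def _roi(self, voxels):
        from morphotrait import ClusterROI
        voxels = np.asarray(voxels)
        return ClusterROI(
            roi_id="roi-01", sign="positive", voxel_list=voxels,
            size_voxels=len(voxels), size_mm3=len(voxels) * 8.0,
            peak_voxel=tuple(voxels[0]))

    def test_constant_image(self, rng):
        images = toy_images(np.full((5, 6, 6, 6), 3.25))
        roi = self._roi([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        np.testing.assert_allclose(roi_means(images, [roi]), 3.25)

    def test_single_voxel_roi(self, rng):
        data = rng.standard_normal((4, 5, 5, 5))
        images = toy_images(data)
        roi = self._roi([[2, 3, 4]])
        np.testing.assert_allclose(roi_means(images, [roi])[:, 0],
                                   data[:, 2, 3, 4])

    def test_matches_naive_loop_oracle(self, rng):
        data = rng.standard_normal((6, 8, 8, 8))
        images = toy_images(data)
        voxels = rng.integers(0, 8, size=(10, 3))
        roi = self._roi(voxels)
        got = roi_means(images, [roi])[:, 0]
        want = [np.mean([data[s, x, y, z] for x, y, z in voxels])
                for s in range(6)]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_out_of_mask_voxel_rejected(self, rng):
        data = rng.standard_normal((3, 6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        images = VoxelImageSet(data=data, mask=mask, voxel_size_mm=2.0,
                               subject_ids=("a", "b", "c"))
        roi = self._roi([[0, 0, 0]])
        with pytest.raises(DimensionError, match="mask"):
            roi_means(images, [roi])
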