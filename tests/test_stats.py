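"""Permutation inference and cluster-extent correction."""

import numpy as np
import pytest
from itertools import combinations

from scipy import ndimage, stats as sps

from tbmorph.stats import (ClusterSet, StatMap, estimate_fwhm, extract_clusters,
                           mc_cluster_threshold, permutation_p, voxelwise_t)


class FakeMap:
    def __init__(self, values):
        self.values = np.asarray(values, float)
        self.shape = self.values.shape


def _maps(arrays):
    return [FakeMap(a) for a in arrays]


class TestVoxelwiseT:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4, 2))
        sm = voxelwise_t(_maps([a, a + 0.1, a, a + 0.1]),
                         np.array(["EtOH", "EtOH", "Con", "Con"]))
        assert np.allclose(sm.t, 0.0)

    def test_one_sample_matches_hand_computation(self):
        rng = np.random.default_rng(1)
        data = rng.normal(2.0, 1.0, size=(5, 3, 3, 1))
        sm = voxelwise_t(_maps(list(data)), "one_sample")
        expected = data.mean(axis=0) / (data.std(axis=0, ddof=1) / np.sqrt(5))
        assert np.allclose(sm.t, expected)
        assert sm.df == 4

    def test_two_sample_matches_scipy_pooled(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 1.0, size=(4, 2, 2, 2))
        b = rng.normal(0.0, 1.0, size=(5, 2, 2, 2))
        sm = voxelwise_t(_maps(list(a) + list(b)),
                         np.array([1] * 4 + [0] * 5))
        ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.allclose(sm.t, ref.statistic)

    def test_zero_variance_flagged_infinite(self):
        a = [np.full((2, 2, 1), 1.0)] * 3 + [np.full((2, 2, 1), 0.0)] * 3
        sm = voxelwise_t(_maps(a), np.array([1, 1, 1, 0, 0, 0]))
        assert np.all(np.isinf(sm.t))
        assert sm.inf_flag.all()

    def test_single_subject_group_rejected(self):
        a = [np.zeros((2, 2, 1))] * 3
        with pytest.raises(ValueError):
            voxelwise_t(_maps(a), np.array([1, 0, 0]))


class TestPermutationP:
    def test_two_sample_exhaustive_equals_enumeration(self):
        """For a 3+3 design all 20 label arrangements are enumerated; p-values
        must match an independent brute-force oracle exactly."""
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 4, 4, 2))
        data[:3] += 0.7
        design = np.array(["EtOH"] * 3 + ["Con"] * 3)
        sm = permutation_p(_maps(list(data)), design, tail="greater", n_perm=5000,
                           seed=0)
        flat = data.reshape(6, -1)

        def pooled_t(idx):
            A = flat[list(idx)]
            B = flat[[i for i in range(6) if i not in idx]]
            va = ((A - A.mean(0)) ** 2).sum(0)
            vb = ((B - B.mean(0)) ** 2).sum(0)
            return (A.mean(0) - B.mean(0)) / np.sqrt((va + vb) / 4 * (2 / 3))

        t_obs = pooled_t((0, 1, 2))
        count = sum((pooled_t(c) >= t_obs).astype(int)
                    for c in combinations(range(6), 3))
        assert np.array_equal(sm.p.ravel(), count / 20)

    def test_one_sample_exhaustive_floor(self):
        """n = 4 sign flips: 16 arrangements, so a voxel where every value is
        positive attains exactly p = 1/16."""
        rng = np.random.default_rng(4)
        data = np.abs(rng.normal(1.0, 0.2, size=(4, 3, 3, 1)))
        sm = permutation_p(_maps(list(data)), "one_sample", tail="greater",
                           n_perm=5000, seed=0)
        assert np.isclose(sm.p.min(), 1 / 16)
        assert np.all(sm.p >= 1 / 16)

    def test_less_tail_mirrors_greater(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(6, 3, 3, 1))
        design = np.array([1, 1, 1, 0, 0, 0])
        pg = permutation_p(_maps(list(data)), design, tail="greater", seed=0).p
        pl = permutation_p(_maps(list(-data)), design, tail="less", seed=0).p
        assert np.allclose(pg, pl)

    def test_null_p_values_uniform(self):
        """Exchangeable null: the permutation p distribution is uniform (KS
        distance < 0.05 over 10k voxels, 5+5 exhaustive design)."""
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 100, 100, 1))
        design = np.array([1] * 5 + [0] * 5)
        sm = permutation_p(_maps(list(data)), design, tail="greater", n_perm=300,
                           seed=1)
        p = sm.p.ravel()
        grid = np.linspace(0.005, 0.995, 200)
        ks = np.abs(np.array([(p <= g).mean() for g in grid]) - grid).max()
        assert ks < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        data = list(rng.normal(size=(8, 3, 3, 1)))
        design = np.array([1] * 4 + [0] * 4)
        p1 = permutation_p(_maps(data), design, n_perm=40, seed=42).p
        p2 = permutation_p(_maps(data), design, n_perm=40, seed=42).p
        assert np.array_equal(p1, p2)

    def test_too_few_permutations_rejected(self):
        data = list(np.zeros((4, 2, 2, 1)))
        with pytest.raises(ValueError):
            permutation_p(_maps(data), "one_sample", n_perm=10)


class TestEstimateFwhm:
    def test_smoothed_noise_recovered(self):
        rng = np.random.default_rng(8)
        target = 3.0
        res = [ndimage.gaussian_filter(rng.standard_normal((40, 40, 40)),
                                       target / 2.3548) for _ in range(4)]
        est = estimate_fwhm(res, np.ones((40, 40, 40), bool), (1.0, 1.0, 1.0))
        assert np.all(np.abs(est.fwhm_mm - target) < 0.15 * target)

    def test_unsmoothed_noise_near_voxel(self):
        rng = np.random.default_rng(9)
        res = [rng.standard_normal((40, 40, 40)) for _ in range(4)]
        est = estimate_fwhm(res, np.ones((40, 40, 40), bool), (1.0, 1.0, 1.0))
        assert np.all(est.fwhm_mm <= 1.2)
        assert np.all(est.fwhm_mm >= 0.5)  # floor at half a voxel

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        r = ndimage.gaussian_filter(rng.standard_normal((30, 30, 30)), 1.0)
        mask = np.ones((30, 30, 30), bool)
        e1 = estimate_fwhm([r, 2 * r], mask, (1, 1, 1))
        e2 = estimate_fwhm([10 * r, 0.1 * r], mask, (1, 1, 1))
        assert np.allclose(e1.fwhm_mm, e2.fwhm_mm)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_fwhm([np.zeros((4, 4, 4))] * 2, np.zeros((4, 4, 4), bool),
                          (1, 1, 1))


class TestMCThreshold:
    def test_independent_voxels_small_threshold(self):
        mask = np.ones((64, 64, 64), bool)
        thr = mc_cluster_threshold((64, 64, 64), (1, 1, 1), mask, (0.1, 0.1, 0.1),
                                   voxel_p=0.01, alpha=0.05, n_sim=300, seed=0)
        assert thr.min_cluster_size <= 5

    def test_threshold_monotone_in_smoothness(self):
        mask = np.ones((48, 48, 48), bool)
        t1 = mc_cluster_threshold((48, 48, 48), (1, 1, 1), mask, (1, 1, 1),
                                  n_sim=300, seed=1)
        t4 = mc_cluster_threshold((48, 48, 48), (1, 1, 1), mask, (4, 4, 4),
                                  n_sim=300, seed=1)
        assert t4.min_cluster_size >= t1.min_cluster_size

    def test_alpha_one_means_no_correction(self):
        mask = np.ones((24, 24, 24), bool)
        thr = mc_cluster_threshold((24, 24, 24), (1, 1, 1), mask, (2, 2, 2),
                                   alpha=1.0, n_sim=200, seed=2)
        assert thr.min_cluster_size == 1

    def test_invalid_parameters_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            mc_cluster_threshold((8, 8, 8), (1, 1, 1), mask, (2, 2, 2), voxel_p=1.5)
        with pytest.raises(ValueError):
            mc_cluster_threshold((8, 8, 8), (1, 1, 1), mask, (2, 2, 2), n_sim=50)


def _pmap(p, tail="greater", t=None):
    p = np.asarray(p, float)
    return StatMap(t=t if t is not None else np.zeros(p.shape), p=p, tail=tail,
                   design="two_sample", df=10, mask=np.ones(p.shape, bool))


class TestExtractClusters:
    def test_all_nonsignificant_empty(self):
        cs = extract_clusters(_pmap(np.ones((8, 8, 8))), 0.01, 1)
        assert cs.clusters == []
        assert not cs.union_mask().any()

    def test_minimum_size_607_keeps_only_large_blob(self):
        """A 700-voxel significant blob survives a representative minimum
        cluster size of 607 while a 300-voxel blob is discarded."""
        p = np.ones((40, 40, 40))
        blob_big = np.zeros_like(p, dtype=bool)
        blob_big[2:9, 2:12, 2:12] = True          # 7*10*10 = 700
        blob_small = np.zeros_like(p, dtype=bool)
        blob_small[20:23, 20:30, 20:30] = True    # 3*10*10 = 300
        p[blob_big | blob_small] = 0.001
        cs = extract_clusters(_pmap(p), voxel_p=0.01, min_cluster_size=607)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].size == 700

    def test_connectivity_splits_touching_blobs(self):
        p = np.ones((10, 10, 10))
        p[2:4, 2:4, 2:4] = 0.001
        p[4:6, 4:6, 4:6] = 0.001  # touches only at a corner
        c6 = extract_clusters(_pmap(p), 0.01, 1, connectivity=6)
        c26 = extract_clusters(_pmap(p), 0.01, 1, connectivity=26)
        assert len(c6.clusters) == 2
        assert len(c26.clusters) == 1

    def test_direction_from_tail(self):
        p = np.ones((6, 6, 6))
        p[2:4, 2:4, 2:4] = 0.001
        assert extract_clusters(_pmap(p, "greater"), 0.01, 1).clusters[0].direction \
            == "expand"
        assert extract_clusters(_pmap(p, "less"), 0.01, 1).clusters[0].direction \
            == "shrink"

    def test_directional_coherence(self):
        """The same voxel can never be significant in both tails: exhaustive
        permutation p-values for opposite tails sum to > 1."""
        rng = np.random.default_rng(11)
        data = list(rng.normal(size=(6, 6, 6, 4)))
        design = np.array([1] * 3 + [0] * 3)
        pg = permutation_p(_maps(data), design, tail="greater", seed=0).p
        pl = permutation_p(_maps(data), design, tail="less", seed=0).p
        assert np.all(pg + pl > 1.0 - 1e-12)
        assert not np.any((pg < 0.01) & (pl < 0.01))

    def test_mirrored_clusters_cover_both_hemispheres(self):
        p = np.ones((10, 8, 8))
        p[7:9, 3:5, 3:5] = 0.001
        cs = extract_clusters(_pmap(p), 0.01, 1)
        mirrored = cs.mirrored(axis=0)
        m = mirrored.union_mask()
        assert m[7:9, 3:5, 3:5].all() and m[1:3, 3:5, 3:5].all()


class TestFamilywiseErrorControl:
    def test_cluster_threshold_controls_fwer_on_null_fields(self):
        """Calibrate the minimum cluster size on smooth null fields, then apply
        voxel p < 0.01 + that size to fresh null fields: the family-wise
        false-positive rate must be consistent with alpha = 0.05."""
        shape, spacing = (48, 48, 48), (1.0, 1.0, 1.0)
        mask = np.ones(shape, bool)
        fwhm = (2.0, 2.0, 2.0)
        thr = mc_cluster_threshold(shape, spacing, mask, fwhm, voxel_p=0.01,
                                   alpha=0.05, n_sim=500, seed=7)
        rng = np.random.default_rng(8)
        z_crit = sps.norm.isf(0.01)
        sigma = np.asarray(fwhm) / 2.3548
        structure = ndimage.generate_binary_structure(3, 1)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
            f = (f - f.mean()) / f.std()
            lab, n = ndimage.label(f > z_crit, structure=structure)
            if n and np.bincount(lab.ravel())[1:].max() >= thr.min_cluster_size:
                hits += 1
        # one-sided binomial check at 99% confidence
        crit = sps.binom.isf(0.01, n_rep, 0.05)
        assert hits <= crit, f"{hits}/{n_rep} exceeds binomial bound {crit}"
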