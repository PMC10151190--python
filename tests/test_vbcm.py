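"""Voxel-based correlational mapping: mass-univariate stats, clusters, LOOCV."""

from collections import deque

import numpy as np
import pytest
from scipy import stats

import lesionet.simulate as sim
from lesionet.image import VolumeImage
from lesionet.results import pearson_accuracy
from lesionet.vbcm import (
    LesionModelEngine,
    ROISet,
    VBCMConfig,
    extract_clusters,
    fdr_select,
    lesion_load,
    loocv_lesion_model,
    permutation_pvalue,
    stability_map,
    voxelwise_correlation,
)
from tests.conftest import generate_lesion_study


def volumes_from_matrix(x, shape, voxel=2.0):
    return [VolumeImage(row.reshape(shape), voxel) for row in x]


class TestVoxelwiseCorrelation:
    def test_perfect_voxel(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(8)
        x = rng.standard_normal((8, 27))
        x[:, 5] = y
        rmap, pmap, _ = voxelwise_correlation(volumes_from_matrix(x, (3, 3, 3)), y)
        assert rmap.data.reshape(-1)[5] == pytest.approx(1.0)
        assert pmap.data.reshape(-1)[5] < 1e-10

    def test_constant_voxel_excluded_not_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 8))
        x[:, 3] = 2.5
        y = rng.standard_normal(6)
        rmap, pmap, excluded = voxelwise_correlation(volumes_from_matrix(x, (2, 2, 2)), y)
        assert np.isnan(rmap.data.reshape(-1)[3])
        assert excluded.data.reshape(-1)[3]

    def test_matches_closed_form(self):
        """Six-subject toy data against scipy's pearsonr r and p."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 8))
        y = rng.standard_normal(6)
        rmap, pmap, _ = voxelwise_correlation(volumes_from_matrix(x, (2, 2, 2)), y)
        for v in range(8):
            r_ref, p_ref = stats.pearsonr(x[:, v], y)
            assert rmap.data.reshape(-1)[v] == pytest.approx(r_ref, abs=1e-12)
            assert pmap.data.reshape(-1)[v] == pytest.approx(p_ref, abs=1e-10)

    def test_mismatched_grids_rejected(self):
        imgs = [VolumeImage(np.zeros((2, 2, 2))), VolumeImage(np.zeros((3, 3, 3)))]
        with pytest.raises(ValueError):
            voxelwise_correlation(imgs + imgs, np.arange(4.0))


class TestFDR:
    def test_all_small_all_selected(self):
        p = np.full(100, 0.001)
        assert fdr_select(p, 0.05).all()

    def test_hand_evaluated_step_up(self):
        """BH on {0.01, 0.02, 0.2, 0.9} at q=0.05 keeps the first two:
        0.02 <= 2*0.05/4 = 0.025 is the largest passing rank."""
        selected = fdr_select(np.array([0.01, 0.02, 0.2, 0.9]), 0.05)
        assert selected.tolist() == [True, True, False, False]

    def test_nan_entries_never_selected(self):
        p = np.array([0.001, np.nan, 0.001])
        sel = fdr_select(p, 0.05)
        assert sel.tolist() == [True, False, True]

    def test_null_false_discovery_control(self):
        """On i.i.d. uniform p-values the expected FDP is at most q."""
        rng = np.random.default_rng(3)
        fdp = [fdr_select(rng.uniform(size=1000), 0.05).any() for _ in range(500)]
        assert np.mean(fdp) <= 0.06

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_select(np.array([0.5, 1.5]), 0.05)


def flood_fill_labels(binary, connectivity="face"):
    """Independent BFS component labelling oracle."""
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    if connectivity in ("edge", "corner"):
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
            and (connectivity == "corner" or abs(dx) + abs(dy) + abs(dz) <= 2)
        ]
    out = np.zeros(binary.shape, dtype=int)
    next_label = 0
    for start in map(tuple, np.argwhere(binary)):
        if out[start]:
            continue
        next_label += 1
        queue = deque([start])
        out[start] = next_label
        while queue:
            cur = queue.popleft()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not out[nb]:
                    out[nb] = next_label
                    queue.append(nb)
    return out, next_label


class TestClusters:
    def test_volume_threshold_is_strict(self):
        """251 voxels at 2 mm (2008 mm^3) survive >2 cm^3; 250 (2000) do not."""
        cfg = VBCMConfig()
        for n_vox, expected in [(251, 1), (250, 0)]:
            binary = np.zeros((10, 10, 10), dtype=bool)
            binary.reshape(-1)[:n_vox] = True  # a filled slab: face-connected
            rois = extract_clusters(binary, cfg, voxel_size_mm=2.0)
            assert rois.n_rois == expected

    def test_corner_touching_blobs(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[0:2, 0:2, 0:2] = True
        binary[2:4, 2:4, 2:4] = True
        face = extract_clusters(binary, VBCMConfig(min_cluster_volume_mm3=1.0,
                                                   connectivity="face"))
        corner = extract_clusters(binary, VBCMConfig(min_cluster_volume_mm3=1.0,
                                                     connectivity="corner"))
        assert face.n_rois == 2
        assert corner.n_rois == 1

    @pytest.mark.parametrize("connectivity", ["face", "corner"])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(5):
            binary = rng.random((8, 8, 8)) < 0.3
            cfg = VBCMConfig(min_cluster_volume_mm3=1e-9, connectivity=connectivity)
            rois = extract_clusters(binary, cfg, voxel_size_mm=1.0)
            oracle, n_oracle = flood_fill_labels(binary, connectivity)
            assert rois.n_rois == n_oracle
            # same partition: labels must be a bijection of oracle labels
            ours = rois.label_volume.data
            for lab in range(1, n_oracle + 1):
                ours_here = ours[oracle == lab]
                assert (ours_here == ours_here[0]).all()

    def test_labels_sorted_by_size(self):
        binary = np.zeros((10, 10, 10), dtype=bool)
        binary[0:2, 0:2, 0:2] = True    # 8 voxels
        binary[5:9, 5:9, 5:9] = True    # 64 voxels
        rois = extract_clusters(binary, VBCMConfig(min_cluster_volume_mm3=1.0))
        assert rois.voxel_counts.tolist() == [64, 8]
        assert rois.label_volume.data[6, 6, 6] == 1


class TestLesionLoad:
    def _roiset(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0:2, 0:2, 0:2] = 1
        labels[2:4, :, :] = 2
        return ROISet(VolumeImage(labels, 2.0), np.array([8, 32]),
                      np.array([64.0, 256.0]))

    def test_full_partial_and_zero_coverage(self):
        rois = self._roiset()
        lesion = np.zeros((4, 4, 4))
        lesion[0:2, 0:2, 0:2] = 1.0      # all of ROI 1
        lesion[2:4, 0:2, :] = 1.0        # half of ROI 2
        loads = lesion_load(VolumeImage(lesion, 2.0), rois)
        assert loads.tolist() == [1.0, 0.5]
        zero = lesion_load(VolumeImage(np.zeros((4, 4, 4)), 2.0), rois)
        assert zero.tolist() == [0.0, 0.0]


class TestLOOCVModel:
    def test_recovers_planted_effect(self):
        """Noise-free affine target of one blob's load gives r > 0.95."""
        rng = np.random.default_rng(9)
        shape = (10, 10, 10)
        blob = np.zeros(shape, dtype=bool)
        blob[2:7, 2:7, 2:7] = True  # 125 voxels = 1000 mm^3 at 2 mm
        n = 12
        a = np.linspace(0.1, 1.0, n)
        images = []
        for i in range(n):
            img = 0.01 * rng.random(shape)
            img[blob] = a[i]
            images.append(VolumeImage(img, 2.0))
        y = 2.0 - 3.0 * a
        vb = VBCMConfig(min_cluster_volume_mm3=500.0, n_permutations=19, seed=1)
        res = loocv_lesion_model(images, y, vb, compute_permutation=False)
        assert res.accuracy_r > 0.95
        assert len(res.predicted) == n

    def test_no_leakage(self):
        """Perturbing the held-out target never changes that fold's ROIs or
        coefficients."""
        cfg, atlas, lesions, abnormality, truth, factors = generate_lesion_study(
            22, n_patients=12
        )
        y = factors[:, 0]
        engine = LesionModelEngine(abnormality, VBCMConfig(min_cluster_volume_mm3=500.0))
        for i in range(engine.n):
            perturbed = y.copy()
            perturbed[i] += 100.0
            _, rois_a, coef_a = engine._fit_fold(i, y, collect=True)
            _, rois_b, coef_b = engine._fit_fold(i, perturbed, collect=True)
            assert np.array_equal(rois_a.label_volume.data, rois_b.label_volume.data)
            if coef_a is not None:
                assert np.allclose(coef_a, coef_b)

    def test_empty_fold_falls_back_to_training_mean(self):
        rng = np.random.default_rng(5)
        imgs = volumes_from_matrix(rng.standard_normal((8, 27)), (3, 3, 3))
        y = rng.standard_normal(8)
        vb = VBCMConfig(fdr_q=1e-6, min_cluster_volume_mm3=1e6)
        res = loocv_lesion_model(imgs, y, vb, compute_permutation=False)
        assert res.notes["n_empty_folds"] == 8
        means = np.array([np.delete(y, i).mean() for i in range(8)])
        assert np.allclose(res.predicted, means)


class TestPermutation:
    def test_extreme_p_values(self):
        # runner keyed on an easily-ranked statistic: corr with a fixed vector
        x = np.arange(10.0)
        runner = lambda y: float(np.corrcoef(x, y)[0, 1])
        p, null = permutation_pvalue(runner, x, n_perm=1000, seed=0)
        assert p == pytest.approx(1.0 / 1001.0)
        p_low, _ = permutation_pvalue(runner, -x, n_perm=100, seed=0)
        assert p_low == 1.0

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalue(lambda y: 0.0, np.arange(5.0), 0, 0)

    def test_null_p_uniform(self):
        """With a null target the permutation p is ~uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal(12)
        ps = []
        for run in range(200):
            y = rng.standard_normal(12)
            runner = lambda t: float(np.corrcoef(x, t)[0, 1])
            p, _ = permutation_pvalue(runner, y, n_perm=99, seed=run)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestStabilityMap:
    def _roiset_from(self, binary):
        return extract_clusters(binary, VBCMConfig(min_cluster_volume_mm3=1e-9))

    def test_identical_roisets(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[1:3, 1:3, 1:3] = True
        sets = [self._roiset_from(binary) for _ in range(10)]
        smap = stability_map(sets)
        assert smap.data[binary].min() == 10
        assert smap.data[~binary].max() == 0

    def test_empty_roisets(self):
        smap = stability_map([], shape=(3, 3, 3))
        assert smap.data.sum() == 0


def test_accuracy_nan_for_constant_predictions():
    assert np.isnan(pearson_accuracy(np.ones(5), np.arange(5.0)))
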