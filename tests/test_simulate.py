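"""Synthetic cohort generator: planted structure, invariants, determinism."""

import numpy as np
import pytest

import lesionet as ln
import lesionet.simulate as sim
from lesionet.image import VolumeImage


def tiny_config(**overrides):
    fields = dict(
        grid_shape=(8, 8, 8), voxel_size_mm=2.0, n_patients=4, n_controls=2,
        n_rois=8, n_tests=8, n_factors=2, n_timepoints=20, n_communities=2,
        lesion_volume_range_mm3=(80.0, 400.0), effect_r2=0.5, seed=5,
    )
    fields.update(overrides)
    return ln.SimConfig(**fields)


class TestAtlas:
    def test_regular_partition(self):
        cfg = tiny_config(grid_shape=(4, 4, 4), n_rois=8,
                          lesion_volume_range_mm3=(8.0, 64.0))
        atlas = sim.make_atlas(cfg)
        counts = np.bincount(atlas.data.ravel())[1:]
        assert len(counts) == 8
        assert (counts == 8).all()

    def test_deterministic(self):
        cfg = tiny_config()
        a1, a2 = sim.make_atlas(cfg), sim.make_atlas(cfg)
        assert np.array_equal(a1.data, a2.data)

    def test_all_voxels_labelled_and_connected(self):
        """Every region is a face-connected component (flood-fill check)."""
        cfg = tiny_config(grid_shape=(8, 8, 8), n_rois=64)
        atlas = sim.make_atlas(cfg)
        labels = atlas.data
        assert labels.min() >= 1 and labels.max() == 64
        from scipy.ndimage import label as cc_label
        for lab in range(1, 65):
            _, n_comp = cc_label(labels == lab)
            assert n_comp == 1

    def test_grown_atlas_connected(self):
        """Non-factorizable K falls back to BFS growth; still connected."""
        cfg = tiny_config(grid_shape=(7, 8, 9), n_rois=13)
        atlas = sim.make_atlas(cfg)
        labels = atlas.data
        assert set(np.unique(labels)) == set(range(1, 14))
        from scipy.ndimage import label as cc_label
        for lab in range(1, 14):
            _, n_comp = cc_label(labels == lab)
            assert n_comp == 1

    def test_too_many_rois_rejected(self):
        with pytest.raises(ValueError):
            sim.make_atlas(tiny_config(grid_shape=(2, 2, 2), n_rois=9))


class TestLesions:
    def test_no_patients_no_lesions(self):
        masks, abn = sim.simulate_lesions(tiny_config(n_patients=0))
        assert masks == [] and abn == []

    def test_left_lateralized(self):
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=10,
                          lesion_volume_range_mm3=(80.0, 800.0))
        masks, _ = sim.simulate_lesions(cfg)
        mid = cfg.midline
        for m in masks:
            xs = np.argwhere(m.data)[:, 0]
            assert xs.max() < mid

    def test_volume_range_respected(self):
        """80-400 mm^3 at 2 mm voxels means 10-50 voxels per mask."""
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=100,
                          lesion_volume_range_mm3=(80.0, 400.0))
        masks, _ = sim.simulate_lesions(cfg)
        counts = [int(m.data.sum()) for m in masks]
        assert all(10 <= c <= 50 for c in counts)

    def test_single_connected_component(self):
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=20,
                          lesion_volume_range_mm3=(160.0, 1600.0))
        masks, _ = sim.simulate_lesions(cfg)
        from scipy.ndimage import label as cc_label
        for m in masks:
            _, n_comp = cc_label(m.data)
            assert n_comp == 1

    def test_abnormality_in_unit_interval(self):
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=5,
                          lesion_volume_range_mm3=(160.0, 1600.0))
        _, abn = sim.simulate_lesions(cfg)
        for a in abn:
            assert a.data.min() >= 0.0 and a.data.max() <= 1.0

    def test_infeasible_volume_range(self):
        with pytest.raises(ValueError):
            sim.simulate_lesions(tiny_config(lesion_volume_range_mm3=(1.0, 2.0)))


class TestBehaviour:
    def test_zero_effect_uncorrelated(self):
        """effect_r2 = 0: factor and lesion load are uncorrelated at n=200."""
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=200, effect_r2=0.0,
                          lesion_volume_range_mm3=(160.0, 1600.0))
        atlas = sim.make_atlas(cfg)
        lesions, abn = sim.simulate_lesions(cfg, atlas)
        truth = sim.make_ground_truth(cfg, atlas, lesions, abnormality=abn)
        rng = np.random.default_rng(0)
        f = sim.latent_factors(cfg, abn, atlas, truth, rng)
        loads = sim.roi_damage_fractions(abn, atlas)
        for j in range(cfg.n_factors):
            r = np.corrcoef(f[:, j], loads[:, truth.critical_roi_ids[j] - 1])[0, 1]
            assert abs(r) < 0.15

    def test_full_effect_exact_affine(self):
        """effect_r2 = 1 with no noise: factor is affine in the critical load."""
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=12, effect_r2=1.0,
                          noise_sd=0.0, lesion_volume_range_mm3=(160.0, 1600.0))
        atlas = sim.make_atlas(cfg)
        lesions, abn = sim.simulate_lesions(cfg, atlas)
        truth = sim.make_ground_truth(cfg, atlas, lesions, abnormality=abn)
        f = sim.latent_factors(cfg, abn, atlas, truth, np.random.default_rng(0))
        load = sim.roi_damage_fractions(abn, atlas)[:, truth.critical_roi_ids[0] - 1]
        r = np.corrcoef(f[:, 0], load)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_identical_lesions_identical_factors(self):
        cfg = tiny_config(grid_shape=(10, 10, 10), n_patients=2, effect_r2=1.0,
                          lesion_volume_range_mm3=(160.0, 800.0))
        atlas = sim.make_atlas(cfg)
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[1:3, 2:5, 2:5] = True
        lesions = [VolumeImage(mask, 2.0), VolumeImage(mask.copy(), 2.0)]
        truth = sim.make_ground_truth(cfg, atlas, lesions)
        f = sim.latent_factors(cfg, lesions, atlas, truth, np.random.default_rng(0))
        assert np.allclose(f[0], f[1])

    def test_battery_within_maxima(self, small_cohort):
        cohort, _ = small_cohort
        scores, maxima = cohort.battery.scores, cohort.battery.maxima
        assert (scores.values >= 0).all()
        stated = maxima.dropna()
        assert not scores[stated.index].gt(stated, axis=1).any().any()
        assert maxima.isna().any()  # some tests exercise the group-max rule

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(effect_r2=1.3).validate()
        with pytest.raises(ValueError):
            tiny_config(effect_r2=0.8, sc_independent_r2=0.4).validate()


class TestTimeseries:
    def test_shared_latent_high_correlation(self):
        """Same community, no lesion, noise -> 0 gives r -> 1."""
        cfg = tiny_config(noise_sd=1e-4, n_patients=1, n_timepoints=50)
        atlas = sim.make_atlas(cfg)
        lesions = [VolumeImage(np.zeros(cfg.grid_shape, dtype=bool), 2.0)]
        truth = sim.make_ground_truth(cfg, atlas, lesions)
        ts, _ = sim.simulate_timeseries(cfg, lesions, atlas, truth)
        comm = truth.fc_community_assignment
        same = np.where(comm == comm[0])[0]
        r = np.corrcoef(ts[0][same[0]], ts[0][same[1]])[0, 1]
        assert r > 0.999

    def test_cross_community_independent(self):
        """Across 50 simulated subjects, cross-community mean r stays near 0."""
        cfg = tiny_config(n_patients=50, noise_sd=0.5)
        atlas = sim.make_atlas(cfg)
        empty = [VolumeImage(np.zeros(cfg.grid_shape, dtype=bool), 2.0)] * 50
        truth = sim.make_ground_truth(cfg, atlas, list(empty))
        ts, _ = sim.simulate_timeseries(cfg, list(empty), atlas, truth)
        comm = truth.fc_community_assignment
        a = np.where(comm == 0)[0][0]
        b = np.where(comm == 1)[0][0]
        rs = [np.corrcoef(ts[s][a], ts[s][b])[0, 1] for s in range(50)]
        assert abs(np.mean(rs)) < 0.1

    def test_destroyed_roi_is_pure_noise(self):
        """A 100%-damaged ROI decouples from every other ROI."""
        cfg = tiny_config(n_patients=50, noise_sd=0.5)
        atlas = sim.make_atlas(cfg)
        lesion = VolumeImage((atlas.data == 1), 2.0)
        lesions = [lesion] * 50
        truth = sim.make_ground_truth(cfg, atlas, list(lesions))
        ts, _ = sim.simulate_timeseries(cfg, list(lesions), atlas, truth)
        rs = np.array([
            [np.corrcoef(ts[s][0], ts[s][k])[0, 1] for k in range(1, cfg.n_rois)]
            for s in range(50)
        ])
        assert np.abs(rs.mean(axis=0)).max() < 0.1

    def test_too_few_timepoints(self):
        cfg = tiny_config(n_timepoints=4)
        atlas = sim.make_atlas(cfg)
        with pytest.raises(ValueError):
            sim.simulate_timeseries(cfg, [], atlas, sim.make_ground_truth(cfg, atlas, []))


class TestStructural:
    def _setup(self, **overrides):
        cfg = tiny_config(grid_shape=(10, 10, 10), n_patients=3,
                          lesion_volume_range_mm3=(80.0, 800.0), **overrides)
        atlas = sim.make_atlas(cfg)
        lesions, _ = sim.simulate_lesions(cfg, atlas)
        truth = sim.make_ground_truth(cfg, atlas, lesions)
        return cfg, atlas, lesions, truth

    def test_no_lesion_equals_base(self):
        cfg, atlas, lesions, truth = self._setup()
        empty = [VolumeImage(np.zeros(cfg.grid_shape, dtype=bool), 2.0)] * 3
        scm = sim.simulate_structural_connectomes(cfg, empty, atlas, truth)
        assert np.allclose(scm[0], truth.sc_base_connectome * (1 - np.eye(cfg.n_rois)))

    def test_destroyed_roi_zero_row(self):
        cfg, atlas, lesions, truth = self._setup()
        full = [VolumeImage(atlas.data == 1, 2.0)] * 3
        scm = sim.simulate_structural_connectomes(cfg, full, atlas, truth)
        assert np.allclose(scm[0][0, :], 0) and np.allclose(scm[0][:, 0], 0)

    def test_collinear_is_deterministic_lesion_function(self):
        """sc_collinear: the SC matrix regenerates exactly from the lesion."""
        cfg, atlas, lesions, truth = self._setup(sc_collinear=True)
        scm1 = sim.simulate_structural_connectomes(cfg, lesions, atlas, truth)
        scm2 = sim.simulate_structural_connectomes(cfg, lesions, atlas, truth)
        assert np.max(np.abs(scm1 - scm2)) == 0.0
        damage = sim.roi_damage_fractions(lesions, atlas)
        surv = 1.0 - damage[1]
        expect = truth.sc_base_connectome * np.outer(surv, surv)
        np.fill_diagonal(expect, 0.0)
        assert np.max(np.abs(scm1[1] - expect)) == 0.0

    def test_entries_in_unit_interval(self):
        cfg, atlas, lesions, truth = self._setup(sc_collinear=False,
                                                 sc_independent_r2=0.3)
        scm = sim.simulate_structural_connectomes(cfg, lesions, atlas, truth)
        assert scm.min() >= 0.0 and scm.max() <= 1.0
        assert np.allclose(scm, np.transpose(scm, (0, 2, 1)))


class TestCohort:
    def test_bitwise_reproducibility(self, small_config):
        c1, t1 = ln.simulate_cohort(small_config)
        c2, t2 = ln.simulate_cohort(small_config)
        assert np.array_equal(c1.atlas.data, c2.atlas.data)
        for m1, m2 in zip(c1.lesion_masks, c2.lesion_masks):
            assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(c1.patient_timeseries, c2.patient_timeseries)
        assert np.array_equal(c1.structural, c2.structural)
        assert c1.battery.scores.equals(c2.battery.scores)
        assert np.array_equal(t1.critical_roi_ids, t2.critical_roi_ids)

    def test_controls_have_no_lesion_attenuation(self, small_cohort):
        cohort, _ = small_cohort
        assert cohort.control_timeseries.shape[0] == cohort.config.n_controls
        assert np.isfinite(cohort.control_timeseries).all()

    def test_variance_budget(self):
        """At n=500 the planted predictor's r^2 is within 0.1 of effect_r2."""
        cfg = tiny_config(grid_shape=(12, 12, 12), n_patients=500, effect_r2=0.5,
                          lesion_volume_range_mm3=(160.0, 1600.0))
        atlas = sim.make_atlas(cfg)
        lesions, abn = sim.simulate_lesions(cfg, atlas)
        truth = sim.make_ground_truth(cfg, atlas, lesions, abnormality=abn)
        f = sim.latent_factors(cfg, abn, atlas, truth, np.random.default_rng(1))
        load = sim.roi_damage_fractions(abn, atlas)[:, truth.critical_roi_ids[0] - 1]
        r2 = np.corrcoef(f[:, 0], load)[0, 1] ** 2
        assert abs(r2 - cfg.effect_r2) < 0.1

    def test_critical_rois_in_left_half(self, small_cohort):
        cohort, truth = small_cohort
        mid = cohort.config.midline
        for roi in truth.critical_roi_ids:
            centroid = np.mean(np.argwhere(cohort.atlas.data == roi), axis=0)
            assert centroid[0] < mid

    def test_loading_columns_orthogonal(self, small_cohort):
        _, truth = small_cohort
        gram = truth.test_loading_matrix.T @ truth.test_loading_matrix
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0)


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    cohort, truth = small_cohort
    sim.write_cohort(cohort, truth, tmp_path)
    assert (tmp_path / "atlas.nii.gz").exists()
    assert (tmp_path / "ground_truth.json").exists()
    battery = ln.Battery.from_tsv(tmp_path / "battery.tsv")
    assert np.allclose(battery.scores.values, cohort.battery.scores.values)
    loaded = VolumeImage.load(tmp_path / "lesion_001.nii.gz")
    assert np.array_equal(loaded.data.astype(bool), cohort.lesion_masks[0].data)
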