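import numpy as np
import pytest

import lesionet as ln
import lesionet.simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort used by several module tests."""
    return ln.SimConfig(
        grid_shape=(14, 14, 14),
        voxel_size_mm=3.0,
        n_patients=20,
        n_controls=5,
        n_rois=12,
        n_tests=12,
        n_factors=3,
        n_timepoints=60,
        n_communities=4,
        lesion_volume_range_mm3=(800.0, 5000.0),
        effect_r2=0.6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = ln.simulate_cohort(small_config)
    return cohort, truth


@pytest.fixture(scope="session")
def factor_scores(small_cohort):
    cohort, _ = small_cohort
    scaled = ln.normalize_battery(cohort.battery)
    model = ln.fit_varimax_pca(scaled)
    return ln.project_factor_scores(model, scaled)


def acceptance_sim_config(seed, **overrides):
    """The reduced-grid study conditions used by the simulation-based
    acceptance properties: a 16^3 grid at 2.5 mm, 16 parcels, lesions of
    0.8-4 cm^3 clustered in a left vascular territory."""
    fields = dict(
        grid_shape=(16, 16, 16),
        voxel_size_mm=2.5,
        n_rois=16,
        n_tests=12,
        n_factors=3,
        n_timepoints=30,
        n_communities=4,
        lesion_volume_range_mm3=(800.0, 4000.0),
        lesion_fwhm_vox=1.5,
        lesion_centre_sd_frac=0.2,
        n_controls=3,
        effect_r2=0.5,
        seed=seed,
    )
    fields.update(overrides)
    return ln.SimConfig(**fields)


def generate_lesion_study(seed, **overrides):
    """Lesions + planted factor for one synthetic cohort (no connectivity)."""
    cfg = acceptance_sim_config(seed, **overrides)
    atlas = sim.make_atlas(cfg)
    lesions, abnormality = sim.simulate_lesions(cfg, atlas)
    truth = sim.make_ground_truth(cfg, atlas, lesions)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    factors = sim.latent_factors(cfg, lesions, atlas, truth, rng)
    return cfg, atlas, lesions, abnormality, truth, factors
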