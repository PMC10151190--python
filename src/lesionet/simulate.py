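"""Synthetic post-stroke cohort generator.

Produces reproducible cohorts with the statistical structure the downstream
analyses assume: left-lateralized ellipsoidal lesions on a common grid, a
behavioural test battery whose latent factors are linear in lesion load within
planted critical regions, ROI time series with community structure attenuated
at lesioned regions, and structural connectomes degraded multiplicatively by
lesion — optionally carrying a lesion-independent behavioural signal.

The generator also returns the planted ground truth (critical ROIs, loading
matrix, base connectome, community labels) so that parameter-recovery and
null-calibration properties can be scored exactly.

Variance bookkeeping
--------------------
Each latent behavioural factor is built on a unit-variance budget::

    f = sqrt(effect_r2) * z(1 - load) + sqrt(sc_independent_r2) * z(u) + e

where ``load`` is the damaged fraction of that factor's critical ROI, ``u`` is
a per-subject latent carried only by structural-connectome edges (only for the
designated factor 0, and only when ``sc_collinear`` is off), ``z`` denotes
empirical standardization across patients and ``e`` is Gaussian noise sized so
the budget sums to one. ``noise_sd`` governs *test-level* measurement noise
only; the factor-level noise is fixed by the budget, so ``effect_r2 = 1``
yields a factor that is an exact affine function of lesion load.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .factors import Battery
from .image import VolumeImage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: amplitude of the lesion-independent SC signal component on its edge pattern
SC_SIGNAL_AMPLITUDE = 0.2
#: the factor index whose variance the independent SC component carries
SC_DESIGNATED_FACTOR = 0


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults are desk-scale: a 24^3 grid at 2 mm (48 mm field of view), 60
    regions standing in for a whole-brain parcellation, 20 tests loading on 4
    behavioural factors, 120 resting-state timepoints.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    n_patients: int = 60
    n_controls: int = 20
    n_rois: int = 60
    n_tests: int = 20
    n_factors: int = 4
    n_timepoints: int = 120
    n_communities: int = 6
    lesion_volume_range_mm3: tuple[float, float] = (1500.0, 12000.0)
    lesion_centre_sd_frac: float = 0.2  # spread of lesion centres around the territory core
    effect_r2: float = 0.5
    sc_collinear: bool = True
    sc_independent_r2: float = 0.0
    noise_sd: float = 0.5
    lesion_fwhm_vox: float = 2.0
    tr_seconds: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 dimensions of size >= 2")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if self.n_rois > int(np.prod(self.grid_shape)):
            raise ValueError("n_rois exceeds voxel count")
        if not (0.0 <= self.effect_r2 <= 1.0):
            raise ValueError("effect_r2 must be in [0, 1]")
        if not (0.0 <= self.sc_independent_r2 <= 1.0):
            raise ValueError("sc_independent_r2 must be in [0, 1]")
        if self.effect_r2 + self.sc_independent_r2 > 1.0:
            raise ValueError("effect_r2 + sc_independent_r2 must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_factors < 1 or self.n_tests < self.n_factors:
            raise ValueError("need n_tests >= n_factors >= 1")
        if self.n_communities < 2:
            raise ValueError("n_communities must be >= 2")
        lo, hi = self.lesion_volume_range_mm3
        if not (0 < lo <= hi):
            raise ValueError("lesion_volume_range_mm3 must be 0 < lo <= hi")

    @property
    def midline(self) -> int:
        """Left/right split index on the first voxel axis (left = x < midline)."""
        return self.grid_shape[0] // 2


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort (enables recovery scoring)."""

    critical_roi_ids: np.ndarray          # (F,) 1-based atlas labels
    factor_effect_weights: np.ndarray     # (F,)
    test_loading_matrix: np.ndarray       # (M, F), orthogonal columns
    lesion_centres: np.ndarray            # (n_patients, 3) voxel coords
    lesion_volumes_mm3: np.ndarray        # (n_patients,)
    sc_base_connectome: np.ndarray        # (K, K) symmetric, in [0, 1]
    fc_community_assignment: np.ndarray   # (K,) community label per ROI
    sc_signal_pattern: np.ndarray         # (K, K) symmetric 0/1 edge pattern
    sc_latent: np.ndarray                 # (n_patients,) subject latent u

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Cohort:
    """A generated study sample (patients + healthy controls)."""

    atlas: VolumeImage
    lesion_masks: list[VolumeImage]
    abnormality: list[VolumeImage]
    battery: Battery
    patient_timeseries: np.ndarray        # (n_patients, K, T)
    control_timeseries: np.ndarray        # (n_controls, K, T)
    structural: np.ndarray                # (n_patients, K, K)
    config: SimConfig


# ---------------------------------------------------------------------------
# atlas


def _balanced_factor_triple(k: int, shape: tuple[int, int, int]) -> tuple | None:
    """Most cube-like (k1,k2,k3) with k1*k2*k3 == k and ki <= shape[i]."""
    best, best_score = None, np.inf
    target = (np.prod(shape) / k) ** (1 / 3)
    for a in range(1, min(k, shape[0]) + 1):
        if k % a:
            continue
        for b in range(1, min(k // a, shape[1]) + 1):
            if (k // a) % b:
                continue
            c = k // (a * b)
            if c > shape[2]:
                continue
            dims = (shape[0] / a, shape[1] / b, shape[2] / c)
            score = sum((d - target) ** 2 for d in dims)
            if score < best_score:
                best, best_score = (a, b, c), score
    return best


def _grown_atlas(k: int, shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Multi-source balanced BFS growth; regions connected by construction."""
    nvox = int(np.prod(shape))
    labels = np.zeros(shape, dtype=np.int32)
    flat_seeds = rng.choice(nvox, size=k, replace=False)
    heap = []
    sizes = np.zeros(k + 1, dtype=np.int64)
    counter = 0
    for lab, fs in enumerate(np.sort(flat_seeds), start=1):
        idx = np.unravel_index(fs, shape)
        labels[idx] = lab
        sizes[lab] = 1
        heapq.heappush(heap, (1, counter, lab, idx))
        counter += 1
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while heap:
        _, _, lab, idx = heapq.heappop(heap)
        for off in offsets:
            nb = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            if labels[nb] == 0:
                labels[nb] = lab
                sizes[lab] += 1
                heapq.heappush(heap, (int(sizes[lab]), counter, lab, nb))
                counter += 1
    return labels


def make_atlas(config: SimConfig) -> VolumeImage:
    """Partition the grid into K connected, near-equal-volume labelled regions.

    When K factorizes onto the grid axes the parcellation is a regular block
    grid (deterministic regardless of seed); otherwise regions are grown by
    balanced multi-source BFS from seeded source voxels.
    """
    config.validate()
    shape = tuple(config.grid_shape)
    k = config.n_rois
    triple = _balanced_factor_triple(k, shape)
    if triple is not None:
        edges = [np.array_split(np.arange(s), t) for s, t in zip(shape, triple)]
        labels = np.zeros(shape, dtype=np.int32)
        lab = 1
        for xs in edges[0]:
            for ys in edges[1]:
                for zs in edges[2]:
                    labels[np.ix_(xs, ys, zs)] = lab
                    lab += 1
    else:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA71A5]))
        labels = _grown_atlas(k, shape, rng)
    return VolumeImage(labels, config.voxel_size_mm)


# ---------------------------------------------------------------------------
# lesions


def _ellipsoid_count(centre, semi, shape, midline) -> np.ndarray:
    """Boolean mask of an ellipsoid clipped to the left half of the grid."""
    lo = [max(0, int(np.floor(c - s))) for c, s in zip(centre, semi)]
    hi = [min(n - 1, int(np.ceil(c + s))) for c, s, n in zip(centre, semi, shape)]
    hi[0] = min(hi[0], midline - 1)
    mask = np.zeros(shape, dtype=bool)
    if any(l > h for l, h in zip(lo, hi)):
        return mask
    gx, gy, gz = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    inside = (
        ((gx - centre[0]) / semi[0]) ** 2
        + ((gy - centre[1]) / semi[1]) ** 2
        + ((gz - centre[2]) / semi[2]) ** 2
    ) <= 1.0
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = inside
    return mask


def simulate_lesions(
    config: SimConfig, atlas: VolumeImage | None = None, rng: np.random.Generator | None = None
) -> tuple[list[VolumeImage], list[VolumeImage]]:
    """Generate left-half ellipsoidal lesion masks and smoothed abnormality maps.

    Each mask is a single ellipsoid clipped to ``x < midline``, with its voxel
    count bisected into the configured volume range. The continuous
    abnormality image is the Gaussian-smoothed mask (values in [0, 1]),
    standing in for a normalized, smoothed structural abnormality map.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    shape = tuple(config.grid_shape)
    mid = config.midline
    vox_vol = config.voxel_size_mm**3
    lo_mm, hi_mm = config.lesion_volume_range_mm3
    lo_vox = int(np.ceil(lo_mm / vox_vol))
    hi_vox = int(np.floor(hi_mm / vox_vol))
    left_count = mid * shape[1] * shape[2]
    if lo_vox > hi_vox or lo_vox < 1:
        raise ValueError("lesion volume range infeasible at this voxel size")
    if lo_vox > left_count:
        raise ValueError("lesion volume range exceeds the left half of the grid")

    sigma = config.lesion_fwhm_vox * FWHM_TO_SIGMA
    # lesion centres cluster around a vascular-territory core in the left half
    # (stroke lesions share an arterial territory rather than tiling the
    # hemisphere), with configurable scatter; when a parcellation is supplied
    # the core snaps to the centroid of the nearest left-half parcel so that
    # planted effects are resolved at parcel granularity
    core = np.array([0.5 * mid, 0.5 * shape[1], 0.5 * shape[2]])
    if atlas is not None:
        labels = atlas.data
        best, best_d = None, np.inf
        for lab in range(1, int(labels.max()) + 1):
            c = np.mean(np.argwhere(labels == lab), axis=0)
            if c[0] >= mid:
                continue
            d = float(np.sum((c - core) ** 2))
            if d < best_d:
                best, best_d = c, d
        if best is not None:
            core = best
    scatter = config.lesion_centre_sd_frac * np.array([mid, shape[1], shape[2]])
    masks, abnormal = [], []
    for _ in range(config.n_patients):
        mask = None
        for _attempt in range(50):
            centre = np.clip(
                core + scatter * rng.standard_normal(3),
                [1.0, 1.0, 1.0],
                [mid - 1.0, shape[1] - 2.0, shape[2] - 2.0],
            )
            ratios = rng.uniform(0.7, 1.3, size=3)
            target = rng.integers(lo_vox, hi_vox + 1)
            # bisection on the overall scale of the semi-axes
            s_lo, s_hi = 0.5, float(max(shape))
            cand = None
            for _ in range(60):
                s = 0.5 * (s_lo + s_hi)
                m = _ellipsoid_count(centre, s * ratios, shape, mid)
                cnt = int(m.sum())
                if lo_vox <= cnt <= hi_vox:
                    cand = m
                    if cnt >= target:
                        break
                    s_lo = s
                elif cnt < lo_vox:
                    s_lo = s
                else:
                    s_hi = s
            if cand is not None:
                mask = cand
                break
        if mask is None:
            raise ValueError("could not fit a lesion into the volume range")
        masks.append(VolumeImage(mask, config.voxel_size_mm))
        abn = gaussian_filter(mask.astype(float), sigma=sigma)
        abnormal.append(VolumeImage(np.clip(abn, 0.0, 1.0), config.voxel_size_mm))
    return masks, abnormal


# ---------------------------------------------------------------------------
# ground truth


def roi_damage_fractions(masks: list[VolumeImage], atlas: VolumeImage) -> np.ndarray:
    """(n_subjects, K) mean image value per atlas region.

    For binary lesion masks this is the damaged voxel fraction; for
    continuous abnormality images it is the regional lesion load.
    """
    labels = atlas.data.ravel()
    k = int(labels.max())
    counts = np.bincount(labels, minlength=k + 1)[1:].astype(float)
    out = np.empty((len(masks), k))
    for i, m in enumerate(masks):
        hit = np.bincount(labels, weights=m.data.ravel().astype(float), minlength=k + 1)[1:]
        out[i] = hit / counts
    return out


def make_ground_truth(
    config: SimConfig,
    atlas: VolumeImage,
    lesions: list[VolumeImage],
    rng: np.random.Generator | None = None,
    abnormality: list[VolumeImage] | None = None,
) -> GroundTruth:
    """Plant critical ROIs, loadings, communities and the base connectome.

    Critical ROIs are the left-half regions whose lesion load (mean
    abnormality when continuous images are given, damaged fraction otherwise)
    varies most across the generated patients (one per factor), which
    guarantees the planted behavioural effect is identifiable at the
    configured sample size.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    k, f, m = config.n_rois, config.n_factors, config.n_tests
    labels = atlas.data
    mid = config.midline

    centroids = np.array(
        [np.mean(np.argwhere(labels == lab), axis=0) for lab in range(1, k + 1)]
    )
    left_rois = np.where(centroids[:, 0] < mid)[0]  # 0-based
    if len(left_rois) < f:
        raise ValueError("not enough left-half ROIs to plant critical regions")

    load_source = abnormality if abnormality is not None else lesions
    damage = roi_damage_fractions(load_source, atlas) if load_source else np.zeros((0, k))
    if damage.shape[0] >= 2:
        var = damage[:, left_rois].var(axis=0)
        order = left_rois[np.argsort(-var, kind="stable")]
    else:
        order = left_rois
    critical = order[:f] + 1  # 1-based labels; factor j gets the j-th most variant

    # block loading matrix: disjoint test support per factor -> orthogonal cols
    loadings = np.zeros((m, f))
    blocks = np.array_split(np.arange(m), f)
    magnitudes = np.array([0.85, 0.75, 0.9, 0.8])
    for j, block in enumerate(blocks):
        for t_idx, row in enumerate(block):
            loadings[row, j] = magnitudes[t_idx % len(magnitudes)]

    communities = (np.arange(k) * config.n_communities) // k

    base = np.full((k, k), 0.15)
    same = communities[:, None] == communities[None, :]
    base[same] = 0.6
    jitter = rng.uniform(-0.05, 0.05, size=(k, k))
    base = np.clip(base + (jitter + jitter.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(base, 0.0)

    # lesion-independent SC signal lives on within-community edges of the
    # community farthest from the lesioned hemisphere's critical regions
    right_rois = np.where(centroids[:, 0] >= mid)[0]
    pool = right_rois if len(right_rois) >= 3 else np.arange(k)[-max(3, k // 4):]
    carrier = pool[-min(6, len(pool)):]
    pattern = np.zeros((k, k))
    for a in range(len(carrier)):
        for b in range(a + 1, len(carrier)):
            pattern[carrier[a], carrier[b]] = pattern[carrier[b], carrier[a]] = 1.0

    centres = np.array(
        [np.mean(np.argwhere(l.data), axis=0) if l.data.any() else np.full(3, np.nan)
         for l in lesions]
    ) if lesions else np.zeros((0, 3))
    volumes = np.array([l.volume_mm3() for l in lesions])

    sc_latent = np.clip(rng.standard_normal(config.n_patients), -2.0, 2.0)

    return GroundTruth(
        critical_roi_ids=critical,
        factor_effect_weights=np.ones(f),
        test_loading_matrix=loadings,
        lesion_centres=centres,
        lesion_volumes_mm3=volumes,
        sc_base_connectome=base,
        fc_community_assignment=communities,
        sc_signal_pattern=pattern,
        sc_latent=sc_latent,
    )


# ---------------------------------------------------------------------------
# behaviour


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def latent_factors(
    config: SimConfig,
    lesions: list[VolumeImage],
    atlas: VolumeImage,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_patients, F) latent factor scores on the unit-variance budget.

    ``lesions`` may be binary masks or continuous abnormality images; the
    lesion load entering the factor is the mean image value in the critical
    ROI (the damaged proportion for binary masks).
    """
    n, f = config.n_patients, config.n_factors
    damage = roi_damage_fractions(lesions, atlas)
    factors = np.empty((n, f))
    sc_r2 = config.sc_independent_r2 if not config.sc_collinear else 0.0
    for j in range(f):
        load = damage[:, truth.critical_roi_ids[j] - 1]
        budget = config.effect_r2 + (sc_r2 if j == SC_DESIGNATED_FACTOR else 0.0)
        signal = np.sqrt(config.effect_r2) * truth.factor_effect_weights[j] * _zscore(1.0 - load)
        if j == SC_DESIGNATED_FACTOR and sc_r2 > 0:
            signal = signal + np.sqrt(sc_r2) * _zscore(truth.sc_latent)
        noise = np.sqrt(max(0.0, 1.0 - budget)) * rng.standard_normal(n)
        factors[:, j] = signal + noise
    return factors


def simulate_cohort_behaviour(
    config: SimConfig,
    lesions: list[VolumeImage],
    truth: GroundTruth,
    atlas: VolumeImage,
    rng: np.random.Generator | None = None,
    factors: np.ndarray | None = None,
) -> Battery:
    """Generate the raw test battery from planted latent factors.

    Raw score for test m: ``max_m * clip(0.6 + 0.15 * (L f)_m + noise, 0, 1)``,
    i.e. tests sit near 60% of their maximum for an average patient and move
    with their factor. Every third test has no stated maximum (its recorded
    maximum is missing), exercising the group-max normalization rule.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if factors is None:
        factors = latent_factors(config, lesions, atlas, truth, rng)
    m = config.n_tests
    maxima_values = np.array([10.0 * (1 + i % 5) for i in range(m)])
    y = factors @ truth.test_loading_matrix.T
    y = y + config.noise_sd * rng.standard_normal(y.shape)
    raw = maxima_values * np.clip(0.6 + 0.15 * y, 0.0, 1.0)
    stated = np.array([np.nan if i % 3 == 2 else maxima_values[i] for i in range(m)])
    names = [f"test_{i + 1:02d}" for i in range(m)]
    subjects = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    scores = pd.DataFrame(raw, index=subjects, columns=names)
    return Battery(scores=scores, maxima=pd.Series(stated, index=names))


# ---------------------------------------------------------------------------
# time series


def simulate_timeseries(
    config: SimConfig,
    lesions: list[VolumeImage],
    atlas: VolumeImage,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI time series for patients and healthy controls.

    ROI k of subject s follows ``(1 - d_sk) * g_c(k) + noise_sd * eps`` where
    ``g_c`` is that community's latent signal (fresh per subject) and ``d_sk``
    the damaged fraction of the ROI — a fully lesioned ROI emits pure noise,
    an intact ROI shares its community signal. Controls use zero damage.
    """
    config.validate()
    if config.n_timepoints < 8:
        raise ValueError("n_timepoints must be >= 8 (correlation unstable below)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    k, t = config.n_rois, config.n_timepoints
    comm = truth.fc_community_assignment
    damage = roi_damage_fractions(lesions, atlas)

    def one_subject(d: np.ndarray) -> np.ndarray:
        latents = rng.standard_normal((comm.max() + 1, t))
        noise = rng.standard_normal((k, t)) * config.noise_sd
        return (1.0 - d)[:, None] * latents[comm] + noise

    patients = np.stack([one_subject(damage[s]) for s in range(config.n_patients)]) \
        if config.n_patients else np.zeros((0, k, t))
    zeros = np.zeros(k)
    controls = np.stack([one_subject(zeros) for _ in range(config.n_controls)]) \
        if config.n_controls else np.zeros((0, k, t))
    return patients, controls


def control_volume4d(
    config: SimConfig,
    atlas: VolumeImage,
    control_series: np.ndarray,
    control_index: int,
    voxel_noise_sd: float = 0.3,
) -> np.ndarray:
    """Reconstruct a control subject's 4D volume from its ROI series.

    Each voxel carries its ROI's series plus independent voxel noise, seeded
    deterministically from the config seed and control index.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5, control_index]))
    series = control_series[control_index]  # (K, T)
    vol = series[atlas.data - 1]  # (nx, ny, nz, T)
    return vol + voxel_noise_sd * rng.standard_normal(vol.shape)


# ---------------------------------------------------------------------------
# structural connectomes


def simulate_structural_connectomes(
    config: SimConfig,
    lesions: list[VolumeImage],
    atlas: VolumeImage,
    truth: GroundTruth,
) -> np.ndarray:
    """Per-patient structural connectivity matrices in [0, 1].

    With ``sc_collinear`` the connectome is an exact deterministic function of
    the lesion: ``base_ij * (1 - d_i) * (1 - d_j)`` — the streamline
    probability between two regions decays with the damaged fraction at either
    end. Otherwise a subject latent ``u`` additionally modulates a fixed
    lesion-independent edge pattern.
    """
    config.validate()
    k = config.n_rois
    damage = roi_damage_fractions(lesions, atlas)
    out = np.empty((config.n_patients, k, k))
    for s in range(config.n_patients):
        surv = 1.0 - damage[s]
        mat = truth.sc_base_connectome * np.outer(surv, surv)
        if not config.sc_collinear and config.sc_independent_r2 > 0:
            mat = np.clip(
                mat + SC_SIGNAL_AMPLITUDE * truth.sc_latent[s] * truth.sc_signal_pattern,
                0.0,
                1.0,
            )
        np.fill_diagonal(mat, 0.0)
        out[s] = mat
    return out


# ---------------------------------------------------------------------------
# orchestration of the generator


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort plus its ground truth, reproducibly from the seed.

    Stage RNG streams are spawned from ``SeedSequence([seed, stage_index])``
    so stages are reproducible independently of each other.
    """
    config.validate()
    atlas = make_atlas(config)
    lesions, abnormal = simulate_lesions(config, atlas)
    truth = make_ground_truth(config, atlas, lesions, abnormality=abnormal)
    rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    factors = latent_factors(config, abnormal, atlas, truth, rng_b)
    battery = simulate_cohort_behaviour(
        config, lesions, truth, atlas, rng=rng_b, factors=factors
    )
    pat_ts, ctl_ts = simulate_timeseries(config, lesions, atlas, truth)
    sc = simulate_structural_connectomes(config, lesions, atlas, truth)
    cohort = Cohort(
        atlas=atlas,
        lesion_masks=lesions,
        abnormality=abnormal,
        battery=battery,
        patient_timeseries=pat_ts,
        control_timeseries=ctl_ts,
        structural=sc,
        config=config,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir: str | Path) -> None:
    """Write a cohort to disk: NIfTI volumes, TSV tables, JSON ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.save(out / "atlas.nii.gz")
    for i, (m, a) in enumerate(zip(cohort.lesion_masks, cohort.abnormality)):
        m.save(out / f"lesion_{i + 1:03d}.nii.gz")
        a.save(out / f"abnormality_{i + 1:03d}.nii.gz")
    table = cohort.battery.scores.copy()
    table.loc["__maximum__"] = cohort.battery.maxima
    table.to_csv(out / "battery.tsv", sep="\t")
    for i in range(cohort.patient_timeseries.shape[0]):
        np.savetxt(out / f"timeseries_{i + 1:03d}.tsv",
                   cohort.patient_timeseries[i], delimiter="\t")
        np.savetxt(out / f"sc_{i + 1:03d}.tsv", cohort.structural[i], delimiter="\t")
    for i in range(cohort.control_timeseries.shape[0]):
        np.savetxt(out / f"control_timeseries_{i + 1:03d}.tsv",
                   cohort.control_timeseries[i], delimiter="\t")
    truth.to_json(out / "ground_truth.json")
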