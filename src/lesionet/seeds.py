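"""Healthy-control seed-based FC networks with Monte-Carlo cluster correction.

A lesion-derived seed region is intersected with a grey-matter mask; each
control subject contributes a Fisher-z map of the correlation between the
seed-mean time course and every in-mask voxel. The maps enter a one-sample
t-test, thresholded voxelwise (default two-sided P < 0.001) and corrected for
cluster extent with a Monte-Carlo procedure: smooth Gaussian null fields are
simulated at the data's estimated smoothness, the maximum suprathreshold
cluster size is recorded per simulation, and the (1 - cluster_p) quantile of
those maxima becomes the minimum surviving cluster size. Finally, the top
predictive nodes from the patient connectivity models are scored for overlap
with the surviving (positive-tail) healthy network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .connectivity import R_CLAMP
from .image import VolumeImage, check_same_grid
from .simulate import FWHM_TO_SIGMA


@dataclass
class GroupNetworkMap:
    t_map: VolumeImage
    voxel_p_thr: float
    cluster_p_thr: float
    cluster_size_thr: int
    suprathreshold: VolumeImage       # boolean mask of surviving clusters
    df: int


def seed_fc_map(
    seed_roi: VolumeImage, volume4d: np.ndarray, grey_mask: VolumeImage
) -> VolumeImage:
    """Fisher-z map of seed-mean correlation with every grey-matter voxel."""
    check_same_grid(seed_roi, grey_mask)
    data = np.asarray(volume4d, dtype=float)
    if data.shape[:3] != seed_roi.shape:
        raise ValueError("4D volume grid does not match the seed grid")
    seed = seed_roi.data.astype(bool) & grey_mask.data.astype(bool)
    if not seed.any():
        raise ValueError("seed does not intersect the grey-matter mask")
    seed_series = data[seed].mean(axis=0)
    t = data.shape[-1]
    flat = data.reshape(-1, t)
    mask_flat = grey_mask.data.astype(bool).reshape(-1)
    xc = flat[mask_flat] - flat[mask_flat].mean(axis=1, keepdims=True)
    sc = seed_series - seed_series.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
    r = np.zeros(xc.shape[0])
    ok = denom > 1e-12
    r[ok] = (xc @ sc)[ok] / denom[ok]
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    out = np.zeros(mask_flat.shape)
    out[mask_flat] = z
    return VolumeImage(out.reshape(seed_roi.shape), seed_roi.voxel_size_mm)


def group_tmap(z_maps: list[VolumeImage]) -> tuple[VolumeImage, VolumeImage]:
    """One-sample t of Fisher-z maps against zero; (t_map, excluded_mask).

    Voxels with zero variance across subjects (including all-zero voxels
    outside the grey mask) are excluded rather than assigned an unbounded t.
    """
    if len(z_maps) < 3:
        raise ValueError("need at least 3 subject maps")
    check_same_grid(*z_maps)
    stack = np.stack([m.data for m in z_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = sd > 1e-12
    t = np.full(mean.shape, np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    vs = z_maps[0].voxel_size_mm
    return VolumeImage(t, vs), VolumeImage(~valid, vs)


def estimate_fwhm(residual_maps: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Spatial smoothness (FWHM, voxels) from the lag-1 autocorrelation.

    For Gaussian-smoothed white noise with kernel sd ``s`` the spatial
    autocorrelation at lag 1 is exp(-1 / (4 s^2)); invert and average over
    axes and maps. Values are clipped below at 0 (unsmoothed data).
    """
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    rhos = []
    for vol in maps:
        for ax in range(3):
            a = np.moveaxis(vol, ax, 0)
            x, y = a[:-1].reshape(-1), a[1:].reshape(-1)
            if mask is not None:
                m = np.moveaxis(np.asarray(mask, dtype=bool), ax, 0)
                mm = m[:-1].reshape(-1) & m[1:].reshape(-1)
                x, y = x[mm], y[mm]
            if len(x) > 10 and x.std() > 0 and y.std() > 0:
                rhos.append(np.corrcoef(x, y)[0, 1])
    rho = float(np.clip(np.mean(rhos), 1e-6, 1 - 1e-6)) if rhos else 1e-6
    sigma = np.sqrt(-1.0 / (4.0 * np.log(rho))) if rho > 0 else 0.0
    return float(sigma / FWHM_TO_SIGMA)


def montecarlo_cluster_threshold(
    grid_shape: tuple[int, int, int],
    grey_mask: np.ndarray | VolumeImage | None,
    smoothness_fwhm: float,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
    two_sided: bool = True,
) -> int:
    """Minimum cluster size controlling family-wise error at ``cluster_p``.

    Simulates smooth Gaussian null fields (white noise convolved to
    ``smoothness_fwhm``, re-standardized within the mask), thresholds at the
    voxelwise p, and returns the ceiling of the (1 - cluster_p) quantile of
    the per-simulation maximum cluster size.
    """
    if n_sims < 500:
        raise ValueError("n_sims must be >= 500 for a stable quantile")
    if isinstance(grey_mask, VolumeImage):
        grey_mask = grey_mask.data
    mask = (np.ones(grid_shape, dtype=bool) if grey_mask is None
            else np.asarray(grey_mask).astype(bool))
    if mask.shape != tuple(grid_shape):
        raise ValueError("mask shape does not match grid")
    sigma = smoothness_fwhm * FWHM_TO_SIGMA
    if smoothness_fwhm >= min(grid_shape):
        raise ValueError("smoothness wider than the grid")
    zthr = stats.norm.isf(voxel_p / 2.0) if two_sided else stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    structure = ndimage.generate_binary_structure(3, 1)
    max_sizes = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        field = rng.standard_normal(grid_shape)
        if sigma > 0:
            field = ndimage.gaussian_filter(field, sigma)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        exceed = (np.abs(field) >= zthr) if two_sided else (field >= zthr)
        exceed &= mask
        if not exceed.any():
            max_sizes[s] = 0
            continue
        labelled, n = ndimage.label(exceed, structure=structure)
        max_sizes[s] = np.bincount(labelled.reshape(-1))[1:].max()
    return int(np.ceil(np.quantile(max_sizes, 1.0 - cluster_p)))


def threshold_group_map(
    t_map: VolumeImage,
    df: int,
    voxel_p: float,
    cluster_size_thr: int,
    positive_only: bool = True,
    cluster_p: float = 0.05,
) -> GroupNetworkMap:
    """Apply the voxel threshold and the Monte-Carlo cluster-extent threshold.

    The voxel test is two-sided; by default only the positive tail enters the
    surviving network (seed networks of interest are positive correlations).
    """
    tthr = stats.t.isf(voxel_p / 2.0, df)
    t = t_map.data
    finite = np.isfinite(t)
    exceed = finite & ((t >= tthr) if positive_only else (np.abs(t) >= tthr))
    structure = ndimage.generate_binary_structure(3, 1)
    labelled, n = ndimage.label(exceed, structure=structure)
    keep = np.zeros_like(exceed)
    if n:
        counts = np.bincount(labelled.reshape(-1), minlength=n + 1)[1:]
        for lab in np.where(counts >= cluster_size_thr)[0] + 1:
            keep |= labelled == lab
    return GroupNetworkMap(
        t_map=t_map,
        voxel_p_thr=voxel_p,
        cluster_p_thr=cluster_p,
        cluster_size_thr=cluster_size_thr,
        suprathreshold=VolumeImage(keep, t_map.voxel_size_mm),
        df=df,
    )


def node_overlap(
    top_node_ids, atlas: VolumeImage, network_mask: VolumeImage
) -> tuple[int, dict[int, bool]]:
    """How many of the top nodes touch the healthy network.

    A node overlaps when at least one voxel of its atlas region lies in the
    suprathreshold mask. Returns (count, {node_id: overlaps}).
    """
    check_same_grid(atlas, network_mask)
    mask = network_mask.data.astype(bool)
    in_mask = set(np.unique(atlas.data[mask]).tolist()) - {0}
    flags = {int(nid): int(nid) in in_mask for nid in np.atleast_1d(top_node_ids)}
    return sum(flags.values()), flags
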