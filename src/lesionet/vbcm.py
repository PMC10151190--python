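"""Leave-one-out cross-validated voxel-based correlational mapping.

On each fold the held-out subject is excluded from everything: the voxelwise
correlation of abnormality with the behavioural target, the BH-FDR voxel
selection, the cluster-extent filter that defines regions of interest, and
the linear lesion-load regression. The held-out subject's lesion load in the
training-set ROIs is then pushed through that regression to produce one
out-of-fold prediction per subject. Significance is assessed by permutation:
shuffle the target and re-run the entire cross-validated procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .image import VolumeImage, check_same_grid
from .results import PredictionResult, pearson_accuracy

logger = logging.getLogger(__name__)

_CONNECTIVITY_STRUCTURES = {
    "face": ndimage.generate_binary_structure(3, 1),
    "edge": ndimage.generate_binary_structure(3, 2),
    "corner": ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VBCMConfig:
    """Thresholds of the voxel-based correlational mapping stage."""

    fdr_q: float = 0.05
    min_cluster_volume_mm3: float = 2000.0  # clusters must be strictly larger
    connectivity: str = "face"
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.min_cluster_volume_mm3 <= 0:
            raise ValueError("min_cluster_volume_mm3 must be positive")
        if self.connectivity not in _CONNECTIVITY_STRUCTURES:
            raise ValueError(f"connectivity must be one of {list(_CONNECTIVITY_STRUCTURES)}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ROISet:
    """Connected significant clusters surviving the volume threshold."""

    label_volume: VolumeImage           # labels 1..n_rois, sorted by size desc
    voxel_counts: np.ndarray
    volumes_mm3: np.ndarray

    @property
    def n_rois(self) -> int:
        return len(self.voxel_counts)


# ---------------------------------------------------------------------------
# mass-univariate pieces


def _corr_and_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise Pearson r of x (n, V) against y (n,) with two-tailed p.

    Returns (r, p, valid) where invalid columns (zero variance) carry NaN.
    """
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for voxelwise correlation")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    valid = (sx > 1e-12) & (sy > 1e-12)
    r = np.full(x.shape[1], np.nan)
    if sy > 1e-12:
        with np.errstate(invalid="ignore", divide="ignore"):
            r[valid] = (xc.T @ yc)[valid] / (sx[valid] * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    p = np.full_like(r, np.nan)
    rv = r[valid]
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt(df / np.maximum(1.0 - rv**2, 1e-300))
    p[valid] = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p, valid


def voxelwise_correlation(
    images: list[VolumeImage], target: np.ndarray
) -> tuple[VolumeImage, VolumeImage, VolumeImage]:
    """Per-voxel Pearson correlation of image values with a behavioural score.

    Returns (r_map, p_map, excluded_mask); voxels with zero variance across
    subjects are excluded (NaN in both maps), not reported as r = 0.
    """
    check_same_grid(*images)
    x = np.stack([img.data.reshape(-1) for img in images]).astype(float)
    y = np.asarray(target, dtype=float)
    if len(y) != len(images):
        raise ValueError("one target value per image required")
    r, p, valid = _corr_and_p(x, y)
    shape = images[0].shape
    vs = images[0].voxel_size_mm
    return (
        VolumeImage(r.reshape(shape), vs),
        VolumeImage(p.reshape(shape), vs),
        VolumeImage((~valid).reshape(shape), vs),
    )


def fdr_select(p_map: np.ndarray | VolumeImage, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up selection over finite p-values.

    NaN entries (excluded voxels) never enter the correction and are never
    selected. Returns a boolean array of the input shape.
    """
    arr = p_map.data if isinstance(p_map, VolumeImage) else np.asarray(p_map)
    flat = arr.reshape(-1).astype(float)
    valid = np.isfinite(flat)
    if np.nanmin(flat[valid], initial=0.0) < 0 or np.nanmax(flat[valid], initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.zeros(flat.shape, dtype=bool)
    if valid.any():
        reject, *_ = multipletests(flat[valid], alpha=q, method="fdr_bh")
        out[valid] = reject
    return out.reshape(arr.shape)


def extract_clusters(binary: np.ndarray | VolumeImage, config: VBCMConfig,
                     voxel_size_mm: float | None = None) -> ROISet:
    """Connected components of a binary map, dropping small clusters.

    Components with volume <= ``min_cluster_volume_mm3`` are removed (the
    surviving clusters are strictly larger). Labels are renumbered 1..n by
    descending voxel count (ties by original scan order).
    """
    if isinstance(binary, VolumeImage):
        data, vs = binary.data.astype(bool), binary.voxel_size_mm
    else:
        data = np.asarray(binary).astype(bool)
        vs = 1.0 if voxel_size_mm is None else voxel_size_mm
    structure = _CONNECTIVITY_STRUCTURES[config.connectivity]
    labelled, n = ndimage.label(data, structure=structure)
    vox_vol = vs**3
    counts = np.bincount(labelled.reshape(-1), minlength=n + 1)[1:]
    keep = np.where(counts * vox_vol > config.min_cluster_volume_mm3)[0]
    order = keep[np.argsort(-counts[keep], kind="stable")]
    relabel = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        relabel[old + 1] = new
    out = relabel[labelled]
    kept_counts = counts[order]
    return ROISet(
        label_volume=VolumeImage(out, vs),
        voxel_counts=kept_counts,
        volumes_mm3=kept_counts * vox_vol,
    )


def lesion_load(image: VolumeImage, rois: ROISet) -> np.ndarray:
    """Mean image value within each ROI (damaged proportion for binary masks)."""
    check_same_grid(image, rois.label_volume)
    labels = rois.label_volume.data.reshape(-1)
    k = rois.n_rois
    if k == 0:
        return np.zeros(0)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if (counts == 0).any():
        raise ValueError("ROISet contains an empty ROI")
    sums = np.bincount(labels, weights=image.data.reshape(-1).astype(float),
                       minlength=k + 1)[1:]
    return sums / counts


# ---------------------------------------------------------------------------
# the cross-validated model


class LesionModelEngine:
    """Precomputed LOOCV machinery for one image set.

    Holding the subjects x voxels matrix and per-fold image statistics fixed
    lets a permutation re-run the full pipeline (voxelwise correlation, FDR,
    clustering, regression) for a shuffled target at array speed. The image
    statistics are target-independent, so caching them leaks nothing.
    """

    def __init__(self, images: list[VolumeImage], config: VBCMConfig):
        config.validate()
        check_same_grid(*images)
        self.config = config
        self.shape = images[0].shape
        self.voxel_size = images[0].voxel_size_mm
        self.x = np.stack([img.data.reshape(-1) for img in images]).astype(float)
        n = self.x.shape[0]
        if n < 5:
            raise ValueError("need at least 5 subjects for LOOCV")
        self.n = n
        # per-fold (leave-one-out) column sums and sums of squares
        tot = self.x.sum(axis=0)
        tot2 = (self.x**2).sum(axis=0)
        self._fold_sum = tot[None, :] - self.x
        self._fold_sum2 = tot2[None, :] - self.x**2
        m = n - 1
        self._fold_mean = self._fold_sum / m
        var = self._fold_sum2 / m - self._fold_mean**2
        self._fold_ss = np.sqrt(np.maximum(var, 0.0) * m)
        self._df = m - 2

    def _fold_correlation(self, i: int, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """r and two-tailed p over voxels for the fold excluding subject i.

        Uses rank-one downdates of the full-sample cross products, so no
        fold-sized copy of the image matrix is made.
        """
        m = self.n - 1
        xty_full = self.x.T @ y
        y_mean = (y.sum() - y[i]) / m
        y_ss = (y**2).sum() - y[i] ** 2 - m * y_mean**2
        sy = np.sqrt(max(y_ss, 0.0))
        num = (xty_full - self.x[i] * y[i]) - y_mean * self._fold_sum[i]
        denom = self._fold_ss[i] * sy
        valid = (self._fold_ss[i] > 1e-12) & (sy > 1e-12)
        r = np.full(self.x.shape[1], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[valid] = num[valid] / denom[valid]
        r = np.clip(r, -1.0, 1.0)
        p = np.full_like(r, np.nan)
        rv = r[valid]
        t = rv * np.sqrt(self._df / np.maximum(1.0 - rv**2, 1e-300))
        p[valid] = 2.0 * stats.t.sf(np.abs(t), self._df)
        return r, p

    def _fit_fold(self, i: int, y: np.ndarray, collect: bool):
        """One LOOCV fold: ROI discovery + regression on training subjects only."""
        mask = np.ones(self.n, dtype=bool)
        mask[i] = False
        yt = y[mask]
        _, p = self._fold_correlation(i, y)
        selected = fdr_select(p.reshape(self.shape), self.config.fdr_q)
        rois = extract_clusters(selected, self.config, self.voxel_size)
        if rois.n_rois == 0:
            pred = float(yt.mean())
            return pred, (rois if collect else None), None
        labels = rois.label_volume.data.reshape(-1)
        k = rois.n_rois
        counts = np.bincount(labels, minlength=k + 1)[1:]
        # loads: (subjects, k) mean abnormality per cluster
        sums = np.zeros((self.n, k))
        for c in range(1, k + 1):
            idx = np.where(labels == c)[0]
            sums[:, c - 1] = self.x[:, idx].sum(axis=1)
        loads = sums / counts
        design = np.column_stack([np.ones(self.n - 1), loads[mask]])
        coef, *_ = np.linalg.lstsq(design, yt, rcond=None)
        pred = float(np.concatenate([[1.0], loads[i]]) @ coef)
        return pred, (rois if collect else None), (coef if collect else None)

    def run(self, y: np.ndarray, collect: bool = False):
        """Full LOOCV pass; returns (predictions, fold ROISets, fold coefs)."""
        y = np.asarray(y, dtype=float)
        preds = np.empty(self.n)
        roisets, coefs = [], []
        for i in range(self.n):
            pred, rois, coef = self._fit_fold(i, y, collect)
            preds[i] = pred
            if collect:
                roisets.append(rois)
                coefs.append(coef)
        return preds, roisets, coefs

    def accuracy(self, y: np.ndarray) -> float:
        preds, _, _ = self.run(y)
        return pearson_accuracy(preds, y)


def permutation_pvalue(
    model_runner, target: np.ndarray, n_perm: int, seed: int
) -> tuple[float, np.ndarray]:
    """One-sided permutation p for a cross-validated accuracy.

    ``model_runner(y)`` must return the accuracy r for a target vector and is
    re-run in full (ROI redefinition, hyperparameter retuning) per shuffle.
    p = (1 + #{null r >= observed r}) / (n_perm + 1); NaN accuracies in the
    null (degenerate shuffles) count as non-exceedances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = model_runner(np.asarray(target, dtype=float))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = model_runner(rng.permutation(target))
    if np.isnan(observed):
        return 1.0, null
    exceed = int(np.sum(null[np.isfinite(null)] >= observed))
    return (1.0 + exceed) / (n_perm + 1.0), null


def loocv_lesion_model(
    images: list[VolumeImage],
    target: np.ndarray,
    config: VBCMConfig,
    compute_permutation: bool = True,
) -> PredictionResult:
    """LOOCV lesion-load model with per-fold ROI discovery.

    Folds that yield no surviving cluster predict the training-set mean (this
    is logged). The permutation test re-runs the entire procedure per shuffle.
    """
    engine = LesionModelEngine(images, config)
    y = np.asarray(target, dtype=float)
    preds, roisets, coefs = engine.run(y, collect=True)
    empty = sum(1 for r in roisets if r.n_rois == 0)
    if empty:
        logger.info("%d/%d folds had no surviving cluster; mean prediction used",
                    empty, engine.n)
    acc = pearson_accuracy(preds, y)
    perm_p = None
    if compute_permutation:
        perm_p, _ = permutation_pvalue(
            engine.accuracy, y, config.n_permutations, config.seed
        )
    return PredictionResult(
        predicted=preds,
        actual=y,
        accuracy_r=acc,
        perm_p=perm_p,
        fold_artifacts=list(zip(roisets, coefs)),
        notes={"n_empty_folds": empty},
    )


def stability_map(roisets: list[ROISet], shape: tuple | None = None,
                  voxel_size_mm: float = 1.0) -> VolumeImage:
    """Per-voxel count of folds whose surviving clusters covered the voxel."""
    grids = [r.label_volume for r in roisets if r is not None]
    if not grids:
        if shape is None:
            raise ValueError("no ROISets and no shape given")
        return VolumeImage(np.zeros(shape, dtype=np.int32), voxel_size_mm)
    check_same_grid(*grids)
    counts = np.zeros(grids[0].shape, dtype=np.int32)
    for g in grids:
        counts += (g.data > 0)
    return VolumeImage(counts, grids[0].voxel_size_mm)
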