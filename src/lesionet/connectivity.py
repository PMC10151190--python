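"""Lesion-aware functional and structural connectivity features.

Functional connectivity: ROI-mean time courses are detrended and band-passed
(default 0.01–0.08 Hz), pairwise Pearson correlations are Fisher
z-transformed, and every ROI pair touching the subject's lesion — a single
lesioned voxel suffices — is zeroed. Structural connectivity: the two
reciprocal streamline probabilities are averaged and connections emanating
from ROIs with more than 95% damage are zeroed. Either matrix is collapsed to
a K(K-1)/2 vector of below-diagonal entries in a fixed scan order (columns j
ascending, rows i ascending within each column), so feature c maps back to a
unique ROI pair for every subject; K = 200 gives 19,900 features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .image import VolumeImage, check_same_grid

R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """K x K symmetric connectivity with lesion-masking provenance."""

    values: np.ndarray
    modality: str                      # "FC" | "SC"
    masked_rois: set = field(default_factory=set)  # 1-based ROI ids zeroed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=0, rtol=0):
            raise ValueError("connectivity matrix must be exactly symmetric")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def detrend_bandpass(
    series: np.ndarray, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.08
) -> np.ndarray:
    """Remove per-ROI linear trends, then band-pass with a zero-phase filter.

    A 4th-order Butterworth applied forward and backward (filtfilt), the
    conventional conditioning step for resting-state ROI series.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 16:
        raise ValueError("need at least 16 timepoints to band-pass")
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz infeasible for TR={tr_seconds}s "
            f"(Nyquist {nyquist:.3f} Hz)"
        )
    detrended = sps.detrend(series, axis=-1, type="linear")
    sos = sps.butter(4, [low_hz / nyquist, high_hz / nyquist], btype="band", output="sos")
    return sps.sosfiltfilt(sos, detrended, axis=-1)


def roi_timeseries(volume4d: np.ndarray, atlas: VolumeImage) -> np.ndarray:
    """Mean time course within each atlas region: (K, T) matrix."""
    data = np.asarray(volume4d, dtype=float)
    if data.shape[:3] != atlas.shape:
        raise ValueError("4D volume and atlas grids differ")
    labels = atlas.data.reshape(-1)
    k = int(labels.max())
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if (counts == 0).any():
        empty = list(np.where(counts == 0)[0] + 1)
        raise ValueError(f"atlas regions with zero voxels: {empty}")
    flat = data.reshape(-1, data.shape[-1])
    sums = np.zeros((k + 1, flat.shape[1]))
    np.add.at(sums, labels, flat)
    return sums[1:] / counts[:, None]


def fc_matrix(series: np.ndarray) -> ConnectivityMatrix:
    """Fisher-z functional connectivity from ROI time series.

    z_ij = atanh(r_ij) with r clamped to +/-(1 - 1e-7) so identical series
    stay finite; zero-variance ROIs have their pairs set to 0 and are
    recorded in ``masked_rois``. Diagonal is 0.
    """
    series = np.asarray(series, dtype=float)
    k, t = series.shape
    sd = series.std(axis=1)
    degenerate = np.where(sd <= 1e-12)[0]
    z_rows = np.zeros_like(series)
    ok = sd > 1e-12
    z_rows[ok] = (series[ok] - series[ok].mean(axis=1, keepdims=True)) / (
        sd[ok, None] * np.sqrt(t)
    )
    r = z_rows @ z_rows.T  # zero for any pair involving a degenerate ROI
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    return ConnectivityMatrix(z, "FC", set((degenerate + 1).tolist()))


def lesioned_rois(lesion: VolumeImage, atlas: VolumeImage) -> set:
    """1-based ids of atlas regions overlapping the lesion by >= 1 voxel."""
    check_same_grid(lesion, atlas)
    hit = np.unique(atlas.data[lesion.data.astype(bool)])
    return set(int(h) for h in hit if h > 0)


def _zero_rois(values: np.ndarray, rois: set) -> np.ndarray:
    out = values.copy()
    if rois:
        idx = np.array(sorted(rois), dtype=int) - 1
        out[idx, :] = 0.0
        out[:, idx] = 0.0
    return out


def lesion_mask_fc(
    fc: ConnectivityMatrix, lesion: VolumeImage, atlas: VolumeImage
) -> ConnectivityMatrix:
    """Zero all pairs incident to any ROI that overlaps the lesion."""
    hit = lesioned_rois(lesion, atlas)
    return ConnectivityMatrix(
        _zero_rois(fc.values, hit), fc.modality, fc.masked_rois | hit
    )


def symmetrize_and_mask_sc(
    raw: np.ndarray,
    lesion: VolumeImage | None,
    atlas: VolumeImage | None,
    damage_thr: float = 0.95,
) -> ConnectivityMatrix:
    """Average reciprocal streamline probabilities and mask destroyed ROIs.

    s_ij = (raw_ij + raw_ji) / 2; ROIs whose damaged voxel fraction strictly
    exceeds ``damage_thr`` have all incident connections zeroed.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("structural connectivity entries must be >= 0")
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    masked: set = set()
    if lesion is not None and atlas is not None:
        check_same_grid(lesion, atlas)
        labels = atlas.data.reshape(-1)
        k = sym.shape[0]
        counts = np.bincount(labels, minlength=k + 1)[1:]
        hits = np.bincount(labels, weights=lesion.data.reshape(-1).astype(float),
                           minlength=k + 1)[1:]
        frac = np.divide(hits, counts, out=np.zeros_like(hits), where=counts > 0)
        masked = set((np.where(frac > damage_thr)[0] + 1).tolist())
        sym = _zero_rois(sym, masked)
    return ConnectivityMatrix(sym, "SC", masked)


# ---------------------------------------------------------------------------
# vectorization


def pair_index(k: int) -> list[tuple[int, int]]:
    """Feature column -> (ROI_i, ROI_j) 1-based pair, in the fixed scan order.

    Order: below-diagonal entries scanned column by column, i.e. (2,1), (3,1),
    ..., (K,1), (3,2), ... — identical for every subject.
    """
    iu = np.triu_indices(k, 1)
    return [(int(j) + 1, int(i) + 1) for i, j in zip(iu[0], iu[1])]


def vectorize_lower(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Collapse a symmetric K x K matrix to its K(K-1)/2 below-diagonal vector."""
    values = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.array_equal(values, values.T):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def unvectorize_lower(vector: np.ndarray, k: int) -> np.ndarray:
    """Rebuild the symmetric K x K matrix from its feature vector."""
    vector = np.asarray(vector, dtype=float)
    if len(vector) != k * (k - 1) // 2:
        raise ValueError("vector length does not match K(K-1)/2")
    out = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    out[iu] = vector
    return out + out.T


@dataclass
class FeatureMatrix:
    """Subjects x ROI-pair feature matrix with its column -> pair mapping."""

    values: np.ndarray
    pairs: list[tuple[int, int]]
    modality: str

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"modality": self.modality,
             "pairs": [[int(a), int(b)] for a, b in self.pairs]}
        ))


def build_feature_matrix(matrices: list[ConnectivityMatrix], modality: str) -> FeatureMatrix:
    """Stack per-subject connectivity vectors into a feature matrix."""
    if not matrices:
        raise ValueError("no connectivity matrices given")
    k = matrices[0].n_rois
    rows = [vectorize_lower(m) for m in matrices]
    return FeatureMatrix(np.stack(rows), pair_index(k), modality)
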