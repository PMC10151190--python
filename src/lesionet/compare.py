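"""Pairwise model comparison on matched subjects.

Two cross-validated models predicting the same subjects are compared through
their per-subject squared prediction errors with a Wilcoxon signed-rank test:
d_i = (actual_i - predA_i)^2 - (actual_i - predB_i)^2, zero differences
dropped, tied |d| mid-ranked. The z statistic is negative when model B's
errors dominate in rank mass (d predominantly negative). p is computed by
exact enumeration of the sign-flip distribution for n <= 25 nonzero
differences and by the tie-corrected, continuity-corrected normal
approximation otherwise.

The companion operation extracts out-of-fold residuals from a lesion model so
connectivity models can be asked to explain the variance the lesion left
unexplained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .results import PredictionResult


@dataclass
class ComparisonResult:
    median_sq_error_a: float
    median_sq_error_b: float
    wilcoxon_z: float
    wilcoxon_p: float
    n_pairs: int
    label_a: str = "A"
    label_b: str = "B"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def _signed_rank_statistics(d: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, z, ranks) for nonzero differences with mid-ranks and tie correction."""
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = len(d)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 0.0, ranks
    centred = w_plus - mu
    correction = 0.5 * np.sign(centred)
    z = (centred - correction) / np.sqrt(var)
    return w_plus, float(z), ranks

def _exact_signrank_p(d: np.ndarray) -> float:
    """Two-sided p by dynamic programming over all 2^n sign assignments.

    Equivalent to exhaustive enumeration: the DP accumulates the exact
    distribution of W+ over sign flips, valid with tied (mid) ranks because
    doubled mid-ranks are integers.
    """
    ranks = stats.rankdata(np.abs(d))
    doubled = np.round(ranks * 2).astype(int)
    w_obs = int(np.round(ranks[d > 0].sum() * 2))
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    lower = dist[: w_obs + 1].sum()
    upper = dist[w_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def compare_squared_errors(
    pred_a: np.ndarray | PredictionResult,
    pred_b: np.ndarray | PredictionResult,
    actual: np.ndarray | None = None,
    label_a: str = "A",
    label_b: str = "B",
    exact_n_max: int = 25,
) -> ComparisonResult:
    """Wilcoxon signed-rank comparison of squared prediction errors."""
    if isinstance(pred_a, PredictionResult):
        if actual is None:
            actual = np.asarray(pred_a.actual, dtype=float)
        pred_a = np.asarray(pred_a.predicted, dtype=float)
    if isinstance(pred_b, PredictionResult):
        pred_b = np.asarray(pred_b.predicted, dtype=float)
    if actual is None:
        raise ValueError("actual scores required")
    actual = np.asarray(actual, dtype=float)
    pred_a, pred_b = np.asarray(pred_a, dtype=float), np.asarray(pred_b, dtype=float)
    if not (len(pred_a) == len(pred_b) == len(actual)):
        raise ValueError("subject sets must be aligned")
    err_a = (actual - pred_a) ** 2
    err_b = (actual - pred_b) ** 2
    d = err_a - err_b
    nonzero = d[d != 0]
    if len(nonzero) < 5:
        raise ValueError(
            f"insufficient data: only {len(nonzero)} nonzero error differences"
        )
    _, z, _ = _signed_rank_statistics(nonzero)
    if len(nonzero) <= exact_n_max:
        p = _exact_signrank_p(nonzero)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)  # p lies in (0, 1]
    return ComparisonResult(
        median_sq_error_a=float(np.median(err_a)),
        median_sq_error_b=float(np.median(err_b)),
        wilcoxon_z=z,
        wilcoxon_p=min(1.0, p),
        n_pairs=len(nonzero),
        label_a=label_a,
        label_b=label_b,
    )


def residual_targets(lesion_result: PredictionResult) -> np.ndarray:
    """Out-of-fold residuals (actual - cross-validated prediction).

    These are leakage-free targets for connectivity models asked to explain
    the variance the lesion model left unexplained.
    """
    pred = np.asarray(lesion_result.predicted, dtype=float)
    actual = np.asarray(lesion_result.actual, dtype=float)
    if len(pred) != len(actual) or len(pred) == 0 or not np.isfinite(pred).all():
        raise ValueError("lesion result is incomplete")
    return actual - pred
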