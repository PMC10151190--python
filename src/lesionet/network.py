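"""Summaries of cross-validated connectivity models as weighted networks.

Per-fold coefficient vectors are averaged feature-wise, z-scored over the
features that carry any weight, and thresholded at |z| > 3.29 (two-sided
P < 0.001). The surviving connections are summarized per node by degree —
the sum of absolute incident weights by default, the signed sum behind a
flag — together with the proportion of positive incident connections, the
top-k nodes by degree, and a node-filtered view of the significant
connections (a visualization aid, not a refitted model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = 3.29  # two-sided P < 0.001


@dataclass
class WeightMap:
    mean_weights: np.ndarray       # per ROI-pair feature
    z_weights: np.ndarray          # NaN where standardization undefined
    significant: np.ndarray        # boolean mask, |z| > z_thr
    z_thr: float
    pairs: list                    # feature -> (ROI_i, ROI_j), 1-based


@dataclass
class NodeSummary:
    degrees: np.ndarray                 # per node, 0-indexed node id = ROI id - 1
    positive_proportion: np.ndarray     # NaN for isolated nodes
    top_node_ids: np.ndarray            # 1-based, descending degree


def average_weights_z(
    fold_weights: list[np.ndarray] | np.ndarray,
    pairs: list,
    z_thr: float = Z_THRESHOLD_DEFAULT,
) -> WeightMap:
    """Average per-fold weights and z-score over features with nonzero mean.

    Structural zeros (features never selected in any fold) are excluded from
    the standardization population so sparse models are not swamped; if every
    carried weight is identical the z-scores are undefined and the
    significant set is empty (logged).
    """
    w = np.asarray(fold_weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("fold weights must be a list of equal-length vectors")
    if w.shape[1] != len(pairs):
        raise ValueError("weight length does not match the pair map")
    mean_w = w.mean(axis=0)
    pop = mean_w != 0.0
    z = np.full_like(mean_w, np.nan)
    significant = np.zeros(mean_w.shape, dtype=bool)
    if pop.any():
        sd = mean_w[pop].std()
        if sd > 0:
            z[pop] = (mean_w[pop] - mean_w[pop].mean()) / sd
            significant = np.abs(np.nan_to_num(z)) > z_thr
        else:
            logger.warning("all carried weights equal: z undefined, empty significant set")
    else:
        logger.warning("all-zero weights: empty significant set")
    return WeightMap(mean_w, z, significant, z_thr, list(pairs))


def nodal_degree(weightmap: WeightMap, signed: bool = False) -> NodeSummary:
    """Degree and positive-connection proportion per node over significant features.

    degree(k) = sum of |w_f| (or w_f when ``signed``) over significant
    features incident to node k; the positive proportion counts positive
    incident significant weights over all incident significant weights and is
    undefined (NaN) for isolated nodes.
    """
    n_nodes = max((max(a, b) for a, b in weightmap.pairs), default=0)
    degrees = np.zeros(n_nodes)
    pos = np.zeros(n_nodes)
    tot = np.zeros(n_nodes)
    for f in np.where(weightmap.significant)[0]:
        a, b = weightmap.pairs[f]
        wf = weightmap.mean_weights[f]
        contrib = wf if signed else abs(wf)
        degrees[a - 1] += contrib
        degrees[b - 1] += contrib
        tot[a - 1] += 1
        tot[b - 1] += 1
        if wf > 0:
            pos[a - 1] += 1
            pos[b - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(tot > 0, pos / np.maximum(tot, 1), np.nan)
    order = np.lexsort((np.arange(n_nodes), -degrees))
    return NodeSummary(degrees, prop, order + 1)


def top_nodes(summary: NodeSummary, k: int = 10) -> np.ndarray:
    """The k highest-degree nodes (1-based ids), ties broken by lower id.

    If fewer than k nodes have nonzero degree, only those are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nonzero = summary.top_node_ids[summary.degrees[summary.top_node_ids - 1] > 0]
    if len(nonzero) < k:
        if len(nonzero) < min(k, len(summary.degrees)):
            logger.info("only %d nodes have nonzero degree (requested %d)",
                        len(nonzero), k)
        return nonzero
    return nonzero[:k]


def filter_by_nodes(weightmap: WeightMap, node_ids) -> np.ndarray:
    """Significant features with at least one endpoint among ``node_ids``.

    Returns a boolean feature mask — a subset of the significant set. This is
    a visualization aid; it is not the same model refitted on fewer nodes.
    """
    ids = set(int(i) for i in np.atleast_1d(np.asarray(node_ids, dtype=int)).tolist())
    out = np.zeros(len(weightmap.pairs), dtype=bool)
    for f in np.where(weightmap.significant)[0]:
        a, b = weightmap.pairs[f]
        if a in ids or b in ids:
            out[f] = True
    return out


def write_network_tables(
    weightmap: WeightMap, summary: NodeSummary, outdir: str | Path, top_k: int = 10
) -> None:
    """Node and edge tables (TSV) for downstream network tooling."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, len(summary.degrees) + 1),
            "degree": summary.degrees,
            "positive_proportion": summary.positive_proportion,
        }
    )
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    sig = np.where(weightmap.significant)[0]
    edges = pd.DataFrame(
        {
            "roi_i": [weightmap.pairs[f][0] for f in sig],
            "roi_j": [weightmap.pairs[f][1] for f in sig],
            "mean_weight": weightmap.mean_weights[sig],
            "z_weight": weightmap.z_weights[sig],
        }
    )
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    np.savetxt(out / "top_nodes.tsv", top_nodes(summary, top_k), fmt="%d")
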