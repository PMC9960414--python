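"""Resampled consensus clustering of genes with CDF / delta-area diagnostics.

Items are genes (matrix rows); features are samples. Each repetition
subsamples items and features without replacement, clusters the submatrix by
Ward linkage on Euclidean distance, and cuts the tree at each requested k.
The consensus for a pair of items is the fraction of repetitions in which
they co-clustered among those in which they were co-sampled. Final per-k
labels come from hierarchical clustering of (1 - consensus) as a distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from metabosub.data_io import ExpressionMatrix
from metabosub.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConsensusConfig:
    k_values: tuple[int, ...] = (2, 3, 4, 5)
    reps: int = 100
    p_item: float = 0.8
    p_feature: float = 1.0
    linkage_final: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_values = tuple(int(k) for k in self.k_values)
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if any(k < 2 for k in self.k_values):
            raise ValidationError("every k must be >= 2")
        if not self.k_values:
            raise ValidationError("k_values must be non-empty")
        if not 0.0 < self.p_item <= 1.0:
            raise ValidationError("p_item must lie in (0, 1]")
        if not 0.0 < self.p_feature <= 1.0:
            raise ValidationError("p_feature must lie in (0, 1]")
        if self.linkage_final not in ("average", "ward"):
            raise ValidationError(f"unknown final linkage {self.linkage_final!r}")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and CDF diagnostics."""

    item_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, dict[str, int]]
    pair_sample_counts: np.ndarray
    auc: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)

    def label_array(self, k: int) -> np.ndarray:
        return np.array([self.labels[k][g] for g in self.item_ids])


def _ecdf_auc(values: np.ndarray) -> float:
    """Area under the empirical CDF of ``values`` over [0, 1].

    Exact step-function integration; equals 1 - mean(values) for values in
    [0, 1].
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return 0.0
    grid = np.unique(np.concatenate(([0.0], v, [1.0])))
    cdf = np.searchsorted(v, grid, side="right") / v.size
    widths = np.diff(grid)
    return float(np.sum(widths * cdf[:-1]))


def consensus_cluster(expr_centered: ExpressionMatrix,
                      config: ConsensusConfig) -> ConsensusResult:
    """Run resampled consensus clustering of the matrix rows.

    Deterministic under ``config.seed``; per-rep seeds are derived by a
    counter so repetitions are order-independent.
    """
    values = np.asarray(expr_centered.values, dtype=float)
    items = list(expr_centered.gene_ids)
    n_items, n_features = values.shape
    if max(config.k_values) > n_items:
        raise ValidationError(
            f"k={max(config.k_values)} exceeds the {n_items} available items")
    if n_items >= 2 and np.all(values == values[0]):
        raise ValidationError(
            f"all rows identical; clustering is degenerate (rows: {items})")

    n_sub_items = math.ceil(config.p_item * n_items)
    n_sub_features = math.ceil(config.p_feature * n_features)
    co_cluster = {k: np.zeros((n_items, n_items)) for k in config.k_values}
    co_sampled = np.zeros((n_items, n_items))

    for rep in range(config.reps):
        rng = np.random.default_rng([config.seed, rep])
        item_idx = np.sort(rng.choice(n_items, n_sub_items, replace=False))
        feat_idx = np.sort(rng.choice(n_features, n_sub_features, replace=False))
        sub = values[np.ix_(item_idx, feat_idx)]
        Z = linkage(sub, method="ward", metric="euclidean")
        mask = np.zeros(n_items, dtype=bool)
        mask[item_idx] = True
        co_sampled += np.outer(mask, mask)
        for k in config.k_values:
            sub_labels = fcluster(Z, t=k, criterion="maxclust")
            same = sub_labels[:, None] == sub_labels[None, :]
            co_cluster[k][np.ix_(item_idx, item_idx)] += same

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning("%d item pairs were never co-sampled; consensus set to 0",
                       int(never.sum()) // 2)
    denom = np.where(co_sampled == 0, 1.0, co_sampled)

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, dict[str, int]] = {}
    for k in config.k_values:
        M = co_cluster[k] / denom
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        Zf = linkage(squareform(1.0 - M, checks=False), method=config.linkage_final)
        lab = fcluster(Zf, t=k, criterion="maxclust")
        labels[k] = dict(zip(items, (int(x) for x in lab)))

    result = ConsensusResult(items, consensus, labels, co_sampled)
    cdf_delta_area(result)
    return result


def cdf_delta_area(result: ConsensusResult) -> list[tuple[int, float, float]]:
    """AUC of the consensus-value ECDF per k and its relative change vs k-1.

    For the smallest k the delta is defined as the AUC itself. The result's
    ``auc`` / ``delta_area`` fields are filled in place and the table is
    returned as (k, auc, delta_area) rows.
    """
    ks = sorted(result.consensus)
    rows: list[tuple[int, float, float]] = []
    prev_auc: float | None = None
    for k in ks:
        M = result.consensus[k]
        iu = np.triu_indices_from(M, k=1)
        auc = _ecdf_auc(M[iu])
        if prev_auc is None:
            delta = auc
        else:
            delta = (auc - prev_auc) / prev_auc if prev_auc != 0 else float("inf")
        result.auc[k] = auc
        result.delta_area[k] = delta
        rows.append((k, auc, delta))
        prev_auc = auc
    return rows
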