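"""NearMiss-1 under-sampling of the majority class.

The positive (sumoylated) sites are vastly outnumbered by confirmed
negatives, and a classifier trained on the raw data would be dominated by
the majority class. NearMiss-1 keeps every minority sample and retains only
the majority samples whose mean Euclidean distance to their ``n_neighbors``
nearest minority samples is smallest — the majority points closest to the
class boundary — until both classes have equal size.

The procedure is fully deterministic: ties in the mean distance are broken
by original row index, and no randomness is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .encoding import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NearMissConfig:
    """version: only NearMiss-1 is implemented; n_neighbors: how many nearest
    minority samples the mean distance is taken over (default 3, clamped to
    the minority count with a warning when larger)."""

    version: int = 1
    n_neighbors: int = 3

    def __post_init__(self) -> None:
        if self.version != 1:
            raise ValueError("only NearMiss version 1 is implemented")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


def nearmiss_undersample(
    dataset: LabeledDataset, cfg: NearMissConfig = NearMissConfig()
) -> LabeledDataset:
    """Balance a dataset by NearMiss-1 under-sampling of the majority class.

    Returns a dataset with exactly min(class counts) samples per class,
    preserving the original row order of the retained samples. Distances are
    computed on the raw (unscaled) features.
    """
    y = dataset.y
    n_pos = int(np.count_nonzero(y == 1))
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    minority_label = 1 if n_pos <= n_neg else 0
    min_idx = np.flatnonzero(y == minority_label)
    maj_idx = np.flatnonzero(y != minority_label)
    if len(min_idx) == len(maj_idx):
        return dataset.subset(np.arange(len(y)))

    k = cfg.n_neighbors
    if k > len(min_idx):
        logger.warning(
            "n_neighbors=%d exceeds minority count %d; clamping", k, len(min_idx)
        )
        k = len(min_idx)
    # exact Euclidean distances (no dot-product shortcut) keep the selection
    # reproducible against a naive reference
    dists = cdist(dataset.X[maj_idx], dataset.X[min_idx])
    if k < dists.shape[1]:
        dists = np.partition(dists, k - 1, axis=1)[:, :k]
    mean_dist = dists.mean(axis=1)
    # stable sort -> ties broken by original index (maj_idx is ascending)
    order = np.argsort(mean_dist, kind="stable")
    keep_maj = maj_idx[order[: len(min_idx)]]
    keep = np.sort(np.concatenate([min_idx, keep_maj]))
    return dataset.subset(keep)
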