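"""SPXY calibration/validation partitioning.

Sample set Partitioning based on joint X–Y distances: a Kennard–Stone-style
greedy maximin selection on the joint distance
``d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy)``, where dx is Euclidean
distance between spectra and dy the absolute target difference, so the
calibration set covers both the spectral and the concentration space. The
procedure is fully deterministic (no RNG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class SplitResult:
    calibration: np.ndarray  # sorted sample indices
    validation: np.ndarray

    def __post_init__(self):
        cal = np.sort(np.asarray(self.calibration, dtype=int))
        val = np.sort(np.asarray(self.validation, dtype=int))
        if np.intersect1d(cal, val).size:
            raise PartitionError("calibration and validation sets overlap")
        object.__setattr__(self, "calibration", cal)
        object.__setattr__(self, "validation", val)

    @property
    def n_cal(self) -> int:
        return len(self.calibration)


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized spectral + concentration distance matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise PartitionError("X rows != y length")
    dx = squareform(pdist(X))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    if d.max() == 0:
        raise PartitionError("all samples identical in X and y; no distances to rank")
    return d


def spxy_split(X: np.ndarray, y: np.ndarray, n_cal: int) -> SplitResult:
    """Select ``n_cal`` calibration samples by greedy maximin on joint x–y
    distances; the remainder forms the validation set.

    Seeds with the pair at maximum joint distance, then repeatedly adds the
    sample whose minimum distance to the selected set is largest. Ties break
    toward the lowest original sample index.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not 2 <= n_cal < n:
        raise PartitionError(f"need 2 <= n_cal < n_samples, got n_cal={n_cal}, n={n}")
    d = joint_distance_matrix(X, y)

    # seed pair: maximum joint distance, lexicographically smallest on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = np.flatnonzero(flat == flat.max())[0]
    selected = [int(iu[0][best]), int(iu[1][best])]

    remaining = np.setdiff1d(np.arange(n), selected)
    min_dist = d[remaining][:, selected].min(axis=1)
    while len(selected) < n_cal:
        k = int(np.flatnonzero(min_dist == min_dist.max())[0])  # lowest index wins
        chosen = int(remaining[k])
        selected.append(chosen)
        remaining = np.delete(remaining, k)
        min_dist = np.delete(min_dist, k)
        if remaining.size:
            min_dist = np.minimum(min_dist, d[remaining, chosen])
    return SplitResult(calibration=np.array(selected), validation=remaining)
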