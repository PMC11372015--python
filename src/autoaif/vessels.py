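"""Filtering of non-AIF-shaped curves and artery/vein clustering.

Curves survive the filter iff their peak exceeds ``(1 - a1) * Mean_peak`` and
their tail stays below ``((1 - a2) * Mean_tail) + Mean_tail`` (both strict).
Survivors are split into two groups by agglomerative hierarchical clustering
(Ward linkage, Euclidean distance on the raw activity curves — raw amplitudes
preserve the peak separation the filter established); the cluster with the
earlier mean time-to-peak is the arterial one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .peaks import CohortStats
from .frames import TACMatrix

__all__ = [
    "ThresholdConfig",
    "ClusterResult",
    "filter_candidates",
    "cluster_two",
    "label_artery_vein",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Peak threshold fraction a1 and tail threshold fraction a2 (in (0, 1))."""

    a1: float
    a2: float = 0.9

    def __post_init__(self) -> None:
        for name in ("a1", "a2"):
            v = float(getattr(self, name))
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class ClusterResult:
    """Arterial / venous row-index sets with their mean times-to-peak (s)."""

    artery_rows: np.ndarray
    vein_rows: np.ndarray
    artery_ttp: float
    vein_ttp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "artery_rows",
                           np.asarray(self.artery_rows, dtype=np.intp))
        object.__setattr__(self, "vein_rows",
                           np.asarray(self.vein_rows, dtype=np.intp))
        if np.intersect1d(self.artery_rows, self.vein_rows).size:
            raise ValueError("artery and vein row sets must be disjoint")


def filter_candidates(
    tacs,
    peak_values,
    tails,
    stats: CohortStats,
    cfg: ThresholdConfig,
) -> np.ndarray:
    """Row indices whose peak/tail pass the two shape criteria.

    Curves whose peak detector found nothing (NaN peak) are removed first.
    An empty result is returned as-is (downstream steps fail loudly on it).
    """
    if isinstance(tacs, TACMatrix):
        n = tacs.n_voxels
    else:
        n = np.atleast_2d(np.asarray(tacs)).shape[0]
    peak_values = np.asarray(peak_values, dtype=float)
    tails = np.asarray(tails, dtype=float)
    if peak_values.shape != (n,) or tails.shape != (n,):
        raise ValueError("peaks and tails must have one entry per TAC row")
    peak_ok = peak_values > (1.0 - cfg.a1) * stats.mean_peak
    tail_ok = tails < (2.0 - cfg.a2) * stats.mean_tail
    keep = np.isfinite(peak_values) & peak_ok & tail_ok
    return np.flatnonzero(keep)


def cluster_two(tacs, normalize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Split activity curves into two groups (Ward linkage, Euclidean).

    With ``normalize=True`` each curve is scaled to unit Euclidean norm
    first, so the split is driven by curve shape (bolus timing and washout)
    rather than amplitude — partial-volume scaling then cannot pull
    attenuated members of one vascular family into the other.

    Deterministic for a fixed input order.  All-identical inputs cannot be
    split meaningfully at k=2; a singleton split is returned with a warning so
    that pathological cohorts fail loudly downstream rather than silently.
    """
    if isinstance(tacs, TACMatrix):
        tacs = tacs.activities
    X = np.atleast_2d(np.asarray(tacs, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("clustering requires at least two curves")
    if np.all(X == X[0]):
        warnings.warn("all curves identical; returning a degenerate singleton split",
                      stacklevel=2)
        return np.array([0], dtype=np.intp), np.arange(1, X.shape[0], dtype=np.intp)
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
    labels = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(X)
    return np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)


def label_artery_vein(
    clusters: tuple[np.ndarray, np.ndarray],
    peak_times,
    tails=None,
) -> ClusterResult:
    """Assign the earlier-peaking cluster the arterial label.

    ``peak_times`` (seconds) and optional ``tails`` are indexed by the same
    rows the cluster index sets refer to.  Equal mean times-to-peak are broken
    by the smaller mean tail (veins share their late tails with tissue), with
    a warning.
    """
    a, b = (np.asarray(c, dtype=np.intp) for c in clusters)
    if a.size == 0 or b.size == 0:
        raise ValueError("both clusters must be non-empty")
    peak_times = np.asarray(peak_times, dtype=float)
    ttp_a = float(peak_times[a].mean())
    ttp_b = float(peak_times[b].mean())
    if ttp_a == ttp_b:
        if tails is None:
            raise ValueError("tie on mean time-to-peak and no tails to break it")
        warnings.warn("mean time-to-peak tie; labelling by smaller mean tail",
                      stacklevel=2)
        tails = np.asarray(tails, dtype=float)
        first_is_artery = tails[a].mean() <= tails[b].mean()
    else:
        first_is_artery = ttp_a < ttp_b
    if first_is_artery:
        return ClusterResult(a, b, ttp_a, ttp_b)
    return ClusterResult(b, a, ttp_b, ttp_a)
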