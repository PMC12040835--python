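"""Evaluation metrics: spatial overlap, intensity agreement, reliability.

Maps are compared after reducing each to its most-active voxels: a network
occupies only a small part of the brain, so the top 5% of voxel intensities
(descending sort) defines its active set.  Three map-to-map similarities are
provided:

* ``spatial``   — fraction of the template's active set covered by the
  component's active set, ``|C & T| / |T|``.  Asymmetric by construction; a
  symmetric Jaccard variant ``|C & T| / |C | T|`` is available behind a flag.
* ``intensity`` — ``sum_i (|x_i| + |y_i|) / max(|x_i - y_i|, eps)``; grows
  without bound as the maps coincide, so identical maps yield a large finite
  value set by the ``eps`` guard.
* ``hausdorff`` — intensity-weighted overlap ``X / Y`` with
  ``X = sum_{i in C&T} 2 min(x_i, y_i)`` and ``Y = sum_{i in C|T} (x_i + y_i)``,
  bounded in [0, 1] and symmetric.  Despite the name this is an overlap score
  (1 = identical active sets and intensities), not the classical point-set
  Hausdorff distance.

Component-to-template matching uses optimal one-to-one linear assignment, and
test-retest reliability is summarised by the intraclass correlation
coefficient (one-way random, ICC(1,1), by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .maps import SpatialMapSet

__all__ = [
    "SimilarityMatrix",
    "binarize_top_fraction",
    "spatial_similarity",
    "intensity_similarity",
    "hausdorff_metric",
    "pearson_similarity",
    "match_components",
    "test_retest_matrix",
    "icc",
]

INTENSITY_EPS = 1e-8


@dataclass
class SimilarityMatrix:
    """Component x template similarity values with an optional 1-1 matching."""

    values: np.ndarray
    metric_name: str
    row_ind: np.ndarray | None = None
    col_ind: np.ndarray | None = None

    @property
    def matched_values(self) -> np.ndarray:
        if self.row_ind is None:
            raise ValueError("no assignment computed")
        return self.values[self.row_ind, self.col_ind]

    @property
    def mean_matched(self) -> float:
        return float(self.matched_values.mean())

    @property
    def assignment(self) -> dict[int, int]:
        """Injective component -> template mapping."""
        if self.row_ind is None:
            raise ValueError("no assignment computed")
        return dict(zip(self.row_ind.tolist(), self.col_ind.tolist()))


def binarize_top_fraction(map_values: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the ``ceil(fraction * M)`` most intense voxels.

    Ties at the threshold break toward the lower voxel index, so the active
    set is deterministic and has exactly ``ceil(fraction * M)`` members.
    """
    v = np.asarray(map_values, dtype=float).ravel()
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = int(np.ceil(fraction * v.size))
    return np.argsort(-v, kind="stable")[:k]


def spatial_similarity(component_map: np.ndarray, template_map: np.ndarray,
                       fraction: float = 0.05, symmetric: bool = False) -> float:
    """Active-set overlap ``|C & T| / |T|`` (or Jaccard if ``symmetric``)."""
    c, t = _as_pair(component_map, template_map)
    C = set(binarize_top_fraction(c, fraction).tolist())
    T = set(binarize_top_fraction(t, fraction).tolist())
    if not T:
        raise ValueError("template active set is empty")
    denom = len(C | T) if symmetric else len(T)
    return len(C & T) / denom


def intensity_similarity(component_map: np.ndarray, template_map: np.ndarray) -> float:
    """Voxelwise intensity agreement; large when maps nearly coincide."""
    x, y = _as_pair(component_map, template_map)
    return float(np.sum((np.abs(x) + np.abs(y)) /
                        np.maximum(np.abs(x - y), INTENSITY_EPS)))


def hausdorff_metric(component_map: np.ndarray, template_map: np.ndarray,
                     fraction: float = 0.05) -> float:
    """Intensity-weighted overlap of top-fraction active sets, in [0, 1].

    Negative intensities are clipped to zero (maps are expected sign-fixed
    upstream).  Returns 0 with a warning when both maps vanish on the union.
    """
    x, y = _as_pair(component_map, template_map)
    x = np.maximum(x, 0.0)
    y = np.maximum(y, 0.0)
    C = binarize_top_fraction(x, fraction)
    T = binarize_top_fraction(y, fraction)
    inter = np.intersect1d(C, T)
    union = np.union1d(C, T)
    Y = float(x[union].sum() + y[union].sum())
    if Y == 0:
        warnings.warn("both maps are zero on the active-set union", stacklevel=2)
        return 0.0
    X = float(2.0 * np.minimum(x[inter], y[inter]).sum())
    return X / Y


def pearson_similarity(component_map: np.ndarray, template_map: np.ndarray,
                       fraction: float | None = None) -> float:
    """Plain Pearson correlation of voxel intensities (alternative metric)."""
    x, y = _as_pair(component_map, template_map)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


_METRICS = {
    "spatial": spatial_similarity,
    "intensity": lambda x, y, fraction=0.05: intensity_similarity(x, y),
    "hausdorff": hausdorff_metric,
    "pearson": lambda x, y, fraction=0.05: pearson_similarity(x, y),
}


def similarity_matrix(components: np.ndarray, templates: np.ndarray, metric: str = "spatial",
                      fraction: float = 0.05) -> np.ndarray:
    """Full pairwise component x template similarity values."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    comps = np.atleast_2d(np.asarray(components, dtype=float))
    tmpls = np.atleast_2d(np.asarray(templates, dtype=float))
    return np.array([[fn(c, t, fraction=fraction) for t in tmpls] for c in comps])


def match_components(components: SpatialMapSet | np.ndarray,
                     templates: SpatialMapSet | np.ndarray,
                     metric: str = "spatial", fraction: float = 0.05) -> SimilarityMatrix:
    """Optimally assign components to templates, one-to-one.

    Requires at least as many components as templates; the assignment
    maximises total similarity over all injections (Hungarian algorithm).
    """
    comps = components.maps if isinstance(components, SpatialMapSet) else np.atleast_2d(components)
    tmpls = templates.maps if isinstance(templates, SpatialMapSet) else np.atleast_2d(templates)
    if comps.shape[0] < tmpls.shape[0]:
        raise ValueError("need at least as many components as templates")
    values = similarity_matrix(comps, tmpls, metric=metric, fraction=fraction)
    row_ind, col_ind = linear_sum_assignment(values, maximize=True)
    order = np.argsort(col_ind)
    return SimilarityMatrix(values=values, metric_name=metric,
                            row_ind=row_ind[order], col_ind=col_ind[order])


def test_retest_matrix(session1: SpatialMapSet | np.ndarray,
                       session2: SpatialMapSet | np.ndarray,
                       metric: str = "hausdorff", fraction: float = 0.05) -> SimilarityMatrix:
    """Cross-session similarity with matched pairs.

    Session-2 maps are matched one-to-one to session-1 maps by the named
    metric; ``mean_matched`` summarises reproducibility across components.
    """
    s1 = session1.maps if isinstance(session1, SpatialMapSet) else np.atleast_2d(session1)
    s2 = session2.maps if isinstance(session2, SpatialMapSet) else np.atleast_2d(session2)
    if s1.shape[0] != s2.shape[0]:
        raise ValueError("sessions must provide equal map counts for matching")
    return match_components(s2, s1, metric=metric, fraction=fraction)


def icc(measurements: np.ndarray, variant: str = "icc1") -> float:
    """Intraclass correlation of a ``groups x measurements`` table.

    ``icc1`` is the one-way random-effects ICC(1,1)
    ``(MSB - MSW) / (MSB + (k - 1) MSW)``: the fraction of total variance
    attributable to between-group differences.  Two-way forms ``icc2``
    (random raters, ICC(2,1)) and ``icc3`` (fixed raters, ICC(3,1)) are
    available.  A table with zero within-group variance yields exactly 1.
    """
    table = np.asarray(measurements, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 measurements per group")
    n, k = table.shape
    grand = table.mean()
    group_means = table.mean(axis=1)
    ss_between = k * np.sum((group_means - grand) ** 2)
    ss_within = np.sum((table - group_means[:, None]) ** 2)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    if variant == "icc1":
        denom = msb + (k - 1) * msw
        return 1.0 if denom == 0 else float((msb - msw) / denom)
    col_means = table.mean(axis=0)
    ss_col = n * np.sum((col_means - grand) ** 2)
    msc = ss_col / (k - 1)
    mse = (ss_within - ss_col) / ((n - 1) * (k - 1))
    if variant == "icc2":
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3":
        denom = msb + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return 1.0 if denom == 0 else float((msb - mse) / denom)


def _as_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"maps must share a mask: {x.shape} vs {y.shape}")
    return x, y
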