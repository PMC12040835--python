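"""Rank Reduction Operator: pivoted-QR effective-rank estimation.

The layer sizes of the hierarchy are estimated from the diagonal of the
column-pivoted QR factorisation.  Pivoting makes the magnitudes ``|R_ii|``
non-increasing; a pronounced drop between consecutive diagonals marks the
boundary between structured components and the noise floor.  Three
diagnostics are computed along the diagonal:

* weighted ratio    ``wr_i = d_i / d_{i+1}``  (the primary decision rule),
* weighted difference ``wd_i = (d_i - d_{i-1}) / sum_{k<i} d_k``,
* weighted correlation ``wc_i = |corr(row_{i+2}, row_{i+1}) - corr(row_{i+1}, row_i)|``
  over ordered component rows.

The estimated rank is the position of the largest weighted ratio, accepted
only when that ratio clears ``ratio_threshold``; otherwise the matrix is
treated as unstructured and its full numerical rank is returned.  Applying
the reduction operator drops the trailing (smallest-pivot) components, by at
least one per application, so repeated application terminates at rank 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

__all__ = [
    "RROThresholds",
    "RankDiagnostics",
    "qr_diagonal",
    "weighted_ratio",
    "weighted_difference",
    "weighted_correlation",
    "estimate_rank",
    "rank_diagnostics",
    "apply_rro",
]


@dataclass(frozen=True)
class RROThresholds:
    """Decision thresholds for the rank estimate.

    ``ratio_threshold`` is the minimum weighted ratio accepted as a genuine
    rank gap (below it the full numerical rank is used); ``eps_abs`` is the
    relative floor ``d_i >= eps_abs * d_1`` below which diagonals count as
    numerically zero.
    """

    ratio_threshold: float = 1.5
    eps_abs: float = 1e-8

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must exceed 1")
        if not 0 < self.eps_abs < 1:
            raise ValueError("eps_abs must be in (0, 1)")


@dataclass
class RankDiagnostics:
    """Pivot magnitudes, gap statistics and the resulting rank estimate."""

    d: np.ndarray
    wr: np.ndarray
    wd: np.ndarray
    wc: np.ndarray | None
    estimated_rank: int


def qr_diagonal(matrix: np.ndarray) -> np.ndarray:
    """Magnitudes ``|R_ii|`` of the column-pivoted QR, sorted non-increasing."""
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError(f"need a 2D matrix with at least one row/column, got {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite values")
    R = qr(A, mode="r", pivoting=True)[0]
    d = np.abs(np.diag(R))
    return np.sort(d)[::-1]


def weighted_ratio(d: np.ndarray) -> np.ndarray:
    """``wr_i = d_i / d_{i+1}``; a zero follower yields +inf (maximal gap)."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two diagonal values")
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = d[:-1] / d[1:]
    wr[np.isnan(wr)] = 1.0  # 0/0: no information, treat as flat
    return wr


def weighted_difference(d: np.ndarray) -> np.ndarray:
    """``wd_i = (d_i - d_{i-1}) / sum_{k<i} d_k`` for ``i >= 2``."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two diagonal values")
    cum = np.cumsum(d)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        wd = np.diff(d) / cum
    wd[np.isnan(wd)] = 0.0
    return wd


def weighted_correlation(rows: np.ndarray) -> np.ndarray:
    """Absolute Pearson-correlation differences between adjacent components.

    ``wc_i = |corr(row_{i+2}, row_{i+1}) - corr(row_{i+1}, row_i)|`` for
    ``i = 1..D-2``.  A constant row has undefined correlation; its terms are
    set to 0 with a warning.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    D = rows.shape[0]
    if D < 3:
        raise ValueError("need at least three component rows")
    sd = rows.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant component row: correlation terms set to 0", stacklevel=2)
    centered = rows - rows.mean(axis=1, keepdims=True)
    corrs = np.zeros(D - 1)
    for i in range(D - 1):
        if sd[i] == 0 or sd[i + 1] == 0:
            corrs[i] = 0.0
        else:
            corrs[i] = float(centered[i] @ centered[i + 1] /
                             (np.linalg.norm(centered[i]) * np.linalg.norm(centered[i + 1])))
    return np.abs(np.diff(corrs))


def estimate_rank(matrix: np.ndarray, thresholds: RROThresholds | None = None) -> int:
    """Effective rank from the largest weighted-ratio gap.

    Returns the index of the maximal ``wr_i`` among positions whose diagonal
    clears the numerical floor, provided that maximum reaches
    ``ratio_threshold``; otherwise the full numerical rank (the count of
    diagonals above the floor).  A zero matrix degenerates to rank 1 with a
    warning.
    """
    thresholds = thresholds or RROThresholds()
    d = qr_diagonal(matrix)
    if d[0] == 0:
        warnings.warn("zero matrix: rank defaults to 1", stacklevel=2)
        return 1
    num_rank = int(np.count_nonzero(d >= thresholds.eps_abs * d[0]))
    if d.size < 2 or num_rank < 1:
        return max(num_rank, 1)
    wr = weighted_ratio(d)
    # gaps are only meaningful where the leading diagonal is above the floor
    valid = wr[: min(num_rank, wr.size)]
    i = int(np.argmax(valid))
    if valid[i] >= thresholds.ratio_threshold:
        return i + 1
    return num_rank


def rank_diagnostics(matrix: np.ndarray, thresholds: RROThresholds | None = None) -> RankDiagnostics:
    """Full diagnostic bundle: pivot magnitudes, WR, WD, WC and the estimate."""
    matrix = np.asarray(matrix, dtype=float)
    d = qr_diagonal(matrix)
    wr = weighted_ratio(d) if d.size >= 2 else np.array([])
    wd = weighted_difference(d) if d.size >= 2 else np.array([])
    wc = weighted_correlation(matrix) if matrix.shape[0] >= 3 else None
    return RankDiagnostics(d=d, wr=wr, wd=wd, wc=wc,
                           estimated_rank=estimate_rank(matrix, thresholds))


def apply_rro(components: np.ndarray, k: int = 1) -> np.ndarray:
    """Drop the trailing ``k`` components (smallest QR-pivot magnitude).

    Components must be ordered strongest-first; the leading ``D - k`` rows are
    returned in their original order.  Composition is consistent:
    ``apply_rro(apply_rro(c, 1), 1) == apply_rro(c, 2)``.
    """
    components = np.atleast_2d(np.asarray(components))
    D = components.shape[0]
    if not 1 <= k < D:
        raise ValueError(f"k must satisfy 1 <= k < {D}, got {k}")
    return components[: D - k]
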