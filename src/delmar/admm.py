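"""Single-layer low-rank + sparse decomposition solved by ADMM.

One layer approximates an input matrix ``S`` as ``X @ Y + Z`` where ``X``
(``rows x D``) holds temporal/loading weights, ``Y`` (``D x cols``) holds
spatial features, and ``Z`` is an l1-penalised background matrix that absorbs
sparse, weak structure (artifacts and thermal noise).  The augmented
Lagrangian

    L = beta/2 * ||X Y + Z - S||_F^2  +  <X Y + Z - S, e>  +  (1/beta) ||Z||_1

is minimised by alternating steps: least-squares updates of X and Y (the
bilinear fidelity term), a soft-thresholding (shrinkage) update of Z — the
proximal operator of the l1 norm — and a gradient ascent step on the
multiplier ``e``.  The sparsity level is controlled by ``1/beta``: larger
``beta`` means a smaller shrinkage threshold and a denser background.

The l1 weight is expressed in units of the input's root-mean-square entry, so
``beta`` is scale-free: the effective threshold is
``tau = rms(S) / beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdmmConfig", "LayerDecomposition", "soft_threshold", "admm_layer", "layer_residual"]


def soft_threshold(value: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Elementwise shrinkage ``sign(v) * max(|v| - tau, 0)``.

    The proximal operator of ``tau * ||.||_1``; a contraction toward zero that
    exactly nulls entries with magnitude at most ``tau``.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    v = np.asarray(value, dtype=float)
    out = np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


@dataclass
class AdmmConfig:
    """Solver settings for one decomposition layer.

    Parameters
    ----------
    beta
        Positive penalty parameter; the shrinkage threshold is
        ``rms(input) / beta``, so the background sparsity level is set by
        ``1/beta``.
    max_iter, tol
        Iteration cap and relative-residual stopping tolerance
        ``||XY + Z - S||_F / ||S||_F``.
    seed
        Seed for the random factor initialisation mode.
    rank_mode
        ``"auto"`` estimates layer sizes with the rank-reduction operator;
        ``"fixed"`` uses caller-supplied ranks.
    init
        ``"svd"`` (deterministic, leading singular directions) or
        ``"random"`` (seeded Gaussian factors).
    """

    beta: float = 1.0
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0
    rank_mode: str = "auto"
    init: str = "svd"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.rank_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown rank_mode {self.rank_mode!r}")
        if self.init not in ("svd", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class LayerDecomposition:
    """Fitted factors and convergence record of one layer."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    multiplier: np.ndarray
    rank: int
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False

    def reconstruction(self) -> np.ndarray:
        """Low-rank (denoised) part ``X @ Y``, excluding the background ``Z``."""
        return self.X @ self.Y


def _init_factors(S: np.ndarray, rank: int, config: AdmmConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        X = rng.standard_normal((S.shape[0], rank))
        Y = np.linalg.pinv(X) @ S
        return X, Y
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    return U[:, :rank], s[:rank, None] * Vt[:rank]


def admm_layer(input_matrix: np.ndarray, rank: int, config: AdmmConfig | None = None) -> LayerDecomposition:
    """Fit ``input ~ X Y + Z`` at a fixed rank by ADMM with shrinkage.

    Each iteration performs: a least-squares update of ``X`` (with ``Y``,
    ``Z``, ``e`` held fixed), a least-squares update of ``Y``, shrinkage of the
    residual-adjusted target into ``Z``, and the multiplier step
    ``e <- e + beta (X Y + Z - S)``.  Rank-deficient normal equations are
    handled by the pseudoinverse.  Stops at ``max_iter`` or when the relative
    residual drops to ``tol``; the residual history records every iteration.
    """
    config = config or AdmmConfig()
    S = np.asarray(input_matrix, dtype=float)
    if S.ndim != 2:
        raise ValueError(f"input must be 2D, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("input contains non-finite values")
    if not 1 <= rank <= min(S.shape):
        raise ValueError(f"rank must be in [1, {min(S.shape)}], got {rank}")

    beta = config.beta
    norm_S = float(np.linalg.norm(S))
    tau = (norm_S / np.sqrt(S.size)) / beta  # rms-scaled l1 weight

    X, Y = _init_factors(S, rank, config)
    Z = np.zeros_like(S)
    e = np.zeros_like(S)
    history: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        A = S - Z - e / beta
        X = A @ np.linalg.pinv(Y)
        Y = np.linalg.pinv(X) @ A
        Z = soft_threshold(S - X @ Y - e / beta, tau)
        R = X @ Y + Z - S
        e = e + beta * R
        res = float(np.linalg.norm(R))
        if norm_S > 0:
            res /= norm_S
        history.append(res)
        if res <= config.tol:
            converged = True
            break
    return LayerDecomposition(X=X, Y=Y, Z=Z, multiplier=e, rank=rank,
                              residual_history=history, converged=converged)


def layer_residual(decomp: LayerDecomposition, input_matrix: np.ndarray) -> float:
    """Relative Frobenius residual ``||X Y + Z - S||_F / ||S||_F``.

    For a zero-norm input the absolute residual is returned instead.
    """
    S = np.asarray(input_matrix, dtype=float)
    res = float(np.linalg.norm(decomp.X @ decomp.Y + decomp.Z - S))
    norm_S = float(np.linalg.norm(S))
    return res / norm_S if norm_S > 0 else res
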