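"""Joint Markov chain of two memory-one strategies and its stationary state.

Two memory-one strategies a (player 1) and b (player 2), each a 4-vector of
cooperation probabilities conditional on the previous joint outcome in the
owner's own perspective, induce a 4-state Markov chain over joint outcomes
(CC, CD, DC, DD in player 1's perspective).  Conditional on the previous
state k, the players move independently, so row k of the transition matrix
is the outer-product row

    ( a_k b_s(k),  a_k (1 - b_s(k)),  (1 - a_k) b_s(k),  (1 - a_k)(1 - b_s(k)) )

where s = (CC, DC, CD, DD) is the perspective swap: what player 1 calls CD,
player 2 calls DC, so in rows 2 and 3 player 2's conditioning entry is the
transposed one.

The stationary distribution v solves v'M = v', i.e. v spans the null space
of (M - I)'.  When that eigenspace is not one-dimensional (periodic or
reducible chains, which do occur for strategies estimated from finite data
with entries exactly 0 or 1), the Cesàro time-average of the chain started
from the uniform distribution is returned instead, and the diagnostics say
so.  Entries of exactly 0 or 1 are never perturbed: the all-cooperate pair
stays exactly absorbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .ipd_recovery import MemoryOneStrategy, PERSPECTIVE_SWAP

__all__ = [
    "MarkovSystem",
    "MissingStrategyError",
    "build_transition_matrix",
    "stationary_vector",
    "stationary_vectors_batch",
    "solve_system",
    "fill_missing",
]

logger = logging.getLogger(__name__)

#: singular values below this are treated as zero in the null-space solve
SVD_TOL = 1e-10
#: steps of the Cesàro-averaged power iteration fallback
CESARO_STEPS = 100_000


class MissingStrategyError(ValueError):
    """A strategy has never-visited conditioning states and no fill applied."""


@dataclass
class MarkovSystem:
    """A solved joint chain: transition matrix, stationary vector, diagnostics."""

    M: np.ndarray
    v: np.ndarray
    residual: float
    fallback_used: bool = False
    fill_policy: str | None = None


def _strategy_array(p, side: str) -> np.ndarray:
    if isinstance(p, MemoryOneStrategy):
        arr = p.p
    else:
        arr = np.asarray(p, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"{side} strategy must be a 4-vector, got shape {arr.shape}")
    if np.any(np.isnan(arr)):
        raise MissingStrategyError(
            f"{side} strategy has missing entries {arr}; apply "
            "fill_missing(strategy, policy=...) before building the chain"
        )
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{side} strategy entries must lie in [0, 1], got {arr}")
    return arr


def fill_missing(
    strategy: MemoryOneStrategy, policy: str = "uniform"
) -> MemoryOneStrategy:
    """Complete never-visited conditioning states of an estimated strategy.

    ``"uniform"`` fills with 0.5 (the maximum-entropy completion);
    ``"owner_mean"`` fills with the mean of the defined entries (0.5 when
    none are defined).  A filled strategy is logged at WARNING level.
    """
    missing = np.isnan(strategy.p)
    if not missing.any():
        return strategy
    if policy == "uniform":
        fill = 0.5
    elif policy == "owner_mean":
        defined = strategy.p[~missing]
        fill = float(defined.mean()) if defined.size else 0.5
    else:
        raise ValueError(f"unknown fill policy {policy!r}; use 'uniform' or 'owner_mean'")
    p = strategy.p.copy()
    p[missing] = fill
    logger.warning(
        "filled %d missing entr%s of %s strategy with %.3g (policy=%s)",
        missing.sum(), "y" if missing.sum() == 1 else "ies", strategy.owner, fill, policy,
    )
    return MemoryOneStrategy(owner=strategy.owner, p=p, counts=strategy.counts.copy())


def build_transition_matrix(p1, p2) -> np.ndarray:
    """4x4 joint transition matrix of strategies ``p1`` (player 1) and ``p2``.

    Rows and columns are ordered CC, CD, DC, DD in player 1's perspective.
    Both strategies must be fully defined (see :func:`fill_missing`).
    """
    a = _strategy_array(p1, "player-1")
    b = _strategy_array(p2, "player-2")
    bs = b[PERSPECTIVE_SWAP]
    M = np.column_stack(
        [a * bs, a * (1 - bs), (1 - a) * bs, (1 - a) * (1 - bs)]
    )
    return M


def _validate_stochastic(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {M.shape}")
    if np.any(M < -1e-12):
        raise ValueError("transition matrix has negative entries")
    if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"rows must sum to 1, got sums {M.sum(axis=1)}")
    return M


def _cleanup(v: np.ndarray) -> np.ndarray:
    # clip numerically-zero entries so absorbing chains come out exact
    v = v.copy()
    v[np.abs(v) < 1e-13] = 0.0
    return v / v.sum()


def _cesaro_average(M: np.ndarray, steps: int = CESARO_STEPS) -> np.ndarray:
    x = np.full(4, 0.25)
    acc = np.zeros(4)
    for _ in range(steps):
        x = x @ M
        acc += x
    return acc / steps


def stationary_vector(M: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic 4x4 matrix.

    Returns the normalized non-negative left eigenvector for eigenvalue 1
    when it is unique; otherwise the Cesàro time-average limit from the
    uniform start.  Use :func:`solve_system` to also obtain diagnostics.
    """
    return solve_system_matrix(M).v


def solve_system_matrix(M: np.ndarray) -> MarkovSystem:
    """Like :func:`stationary_vector` but returning the full diagnostics."""
    M = _validate_stochastic(M)
    ns = scipy.linalg.null_space(M.T - np.eye(4), rcond=SVD_TOL)
    fallback = False
    v = None
    if ns.shape[1] == 1:
        cand = ns[:, 0]
        total = cand.sum()
        if abs(total) > 1e-12:
            cand = cand / total
            if np.all(cand >= -1e-10):
                v = _cleanup(np.clip(cand, 0.0, None))
    if v is None or np.abs(v @ M - v).max() > 1e-10:
        v = _cleanup(np.clip(_cesaro_average(M), 0.0, None))
        fallback = True
    residual = float(np.abs(v @ M - v).max())
    return MarkovSystem(M=M, v=v, residual=residual, fallback_used=fallback)


def solve_system(p1, p2, fill_policy: str | None = None) -> MarkovSystem:
    """Build the joint chain of two strategies and solve its stationary state.

    When ``fill_policy`` is given, missing entries of estimated strategies
    are completed first (see :func:`fill_missing`).
    """
    applied = None
    if fill_policy is not None:
        if isinstance(p1, MemoryOneStrategy) and not p1.is_complete:
            p1, applied = fill_missing(p1, fill_policy), fill_policy
        if isinstance(p2, MemoryOneStrategy) and not p2.is_complete:
            p2, applied = fill_missing(p2, fill_policy), fill_policy
    system = solve_system_matrix(build_transition_matrix(p1, p2))
    system.fill_policy = applied
    return system


def stationary_vectors_batch(Ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stationary vectors for a stack of 4x4 row-stochastic matrices.

    Solves the normal equations of the constrained least-squares system
    [(M - I)'; 1'] v = [0; 1] in one batched call, then re-solves any
    ill-conditioned instance through the robust scalar path.  Returns
    (v, residuals) with shapes (n, 4) and (n,).
    """
    Ms = np.asarray(Ms, dtype=float)
    n = Ms.shape[0]
    A = Ms - np.eye(4)
    G = A @ np.transpose(A, (0, 2, 1)) + 1.0  # (M-I)(M-I)' + 11'
    try:
        v = np.linalg.solve(G, np.ones((n, 4, 1)))[..., 0]
    except np.linalg.LinAlgError:
        v = np.full((n, 4), np.nan)
    residuals = np.abs(np.einsum("ni,nij->nj", v, Ms) - v).max(axis=1)
    bad = ~np.isfinite(residuals) | (residuals > 1e-10) | (v < -1e-12).any(axis=1)
    for i in np.flatnonzero(bad):
        system = solve_system_matrix(Ms[i])
        v[i] = system.v
        residuals[i] = system.residual
    good = ~bad
    if good.any():
        v[good] = np.clip(v[good], 0.0, None)
        v[good] /= v[good].sum(axis=1, keepdims=True)
    return v, residuals
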