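"""Zero-determinant strategy detection by fitting the linear payoff relation.

A memory-one strategy p enforces a zero-determinant (ZD) relation when its
Press-Dyson tilde transform

    p~ = (p_CC - 1, p_CD - 1, p_DC, p_DD)

is a linear combination of the two players' payoff vectors and the unit
vector: p~ = phi*S_own + kappa*S_other + eps*1.  When that holds, the
determinant defining the stationary expectation of phi*S_own +
kappa*S_other + eps vanishes for *every* opponent, so the two players'
stationary payoffs satisfy phi*s_own + kappa*s_other + eps = 0 — the
enforced linear relation (extortionate or generous depending on the
coefficients).

Since p~ is linear in (phi, kappa, eps), membership is decided by an exact
closed-form linear least-squares fit: the strategy is flagged ZD when the
infinity-norm residual falls below tolerance (default 1e-6).  A scalar
l = -ln(1 - min(sum|residual|, 1 - 1e-12)) is reported alongside, a
monotone transform of the summed residual that is exactly 0 iff the
determinant vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness_analysis import PairAnalysis, signed_payoff_vector
from .ipd_recovery import MemoryOneStrategy
from .markov_engine import fill_missing

__all__ = ["ZDFit", "tilde_transform", "zd_fit", "cohort_zd_scan"]

_TILDE_SHIFT = np.array([1.0, 1.0, 0.0, 0.0])


@dataclass
class ZDFit:
    """Fitted coefficients of the linear payoff relation and the verdict."""

    phi: float
    kappa: float
    epsilon: float
    residual: float  # infinity norm of p~ - (phi S_own + kappa S_other + eps 1)
    l_value: float
    is_zd: bool
    degenerate: bool = False  # S_own, S_other, 1 linearly dependent


def tilde_transform(strategy) -> np.ndarray:
    """Press-Dyson tilde of a strategy in its owner's perspective."""
    p = strategy.p if isinstance(strategy, MemoryOneStrategy) else np.asarray(strategy, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"strategy must be a 4-vector, got shape {p.shape}")
    if np.any(np.isnan(p)):
        raise ValueError("strategy has missing entries; fill before the ZD fit")
    return p - _TILDE_SHIFT


def zd_fit(
    strategy,
    S_own: np.ndarray,
    S_other: np.ndarray,
    tolerance: float = 1e-6,
) -> ZDFit:
    """Least-squares fit of p~ = phi*S_own + kappa*S_other + eps*1.

    All three vectors must be aligned in the same (the strategy owner's)
    perspective.  The problem is linear, so the exact optimum is obtained in
    closed form; ``is_zd`` is True when the infinity-norm residual is below
    ``tolerance``.  Degenerate payoff vectors (S_own, S_other, 1 linearly
    dependent) are flagged but still fitted.
    """
    q = tilde_transform(strategy)
    S_own = np.asarray(S_own, dtype=float)
    S_other = np.asarray(S_other, dtype=float)
    if S_own.shape != (4,) or S_other.shape != (4,):
        raise ValueError("payoff vectors must be 4-vectors")
    A = np.column_stack([S_own, S_other, np.ones(4)])
    coef, _, rank, _ = np.linalg.lstsq(A, q, rcond=None)
    resid_vec = q - A @ coef
    residual = float(np.abs(resid_vec).max())
    resid_sum = float(np.abs(resid_vec).sum())
    l_value = float(-np.log(1.0 - min(resid_sum, 1.0 - 1e-12)))
    return ZDFit(
        phi=float(coef[0]),
        kappa=float(coef[1]),
        epsilon=float(coef[2]),
        residual=residual,
        l_value=l_value,
        is_zd=bool(residual < tolerance),
        degenerate=bool(rank < 3),
    )


def cohort_zd_scan(
    results: list[PairAnalysis], tolerance: float = 1e-6
) -> dict:
    """Scan every analyzed pair for ZD enforcement in both directions.

    Per pair, the fit is run once with the participant as would-be enforcer
    (everything in the participant's perspective) and once with the
    responder (everything swapped into the responder's perspective).
    Returns counts, the flagged fraction and the per-interaction fits.
    """
    if not results:
        raise ValueError("no analyzed pairs to scan")
    fits = []
    n_zd = 0
    for r in results:
        S_part_p1 = signed_payoff_vector(r.cells_participant, player1="participant")
        S_resp_p1 = signed_payoff_vector(r.cells_responder, player1="participant")
        S_part_p2 = signed_payoff_vector(r.cells_participant, player1="responder")
        S_resp_p2 = signed_payoff_vector(r.cells_responder, player1="responder")
        directions = (
            ("participant", r.strategy_participant, S_part_p1, S_resp_p1),
            ("responder", r.strategy_responder, S_resp_p2, S_part_p2),
        )
        for direction, strategy, S_own, S_other in directions:
            if not strategy.is_complete:
                strategy = fill_missing(strategy, "uniform")
            fit = zd_fit(strategy, S_own, S_other, tolerance=tolerance)
            n_zd += fit.is_zd
            fits.append({"pair_id": r.pair_id, "direction": direction, "fit": fit})
    return {
        "n_interactions": len(fits),
        "n_zd": int(n_zd),
        "fraction_zd": n_zd / len(fits),
        "tolerance": tolerance,
        "fits": fits,
    }
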