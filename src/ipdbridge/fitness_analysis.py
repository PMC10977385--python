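"""Stationary-state payoffs, extinction rates and total evolutionary fitness.

The expected payoff of an agent at the stationary state is the dot product
v . S of the joint chain's stationary vector with the agent's signed payoff
4-vector.  Cells built from rejected ultimatums hold *forgone* amounts —
what the agent sacrificed, not what it banked — and enter the fitness
calculation negated.  The sign rule is applied by the semantic
``forgone_mask`` (cells where the responder rejected) rather than by literal
outcome labels, so it is correct in either player's perspective.

An interaction counts toward the opponent's "extinction" tally when the
opponent's stationary payoff strictly exceeds the participant's; the cohort
extinction rate is the fraction of such pairs per opponent type.  Total
fitness of a participant across both opponents is

    f = (own payoff vs individualistic + own payoff vs prosocial)
        - (individualistic's payoff + prosocial's payoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ipd_recovery import (
    PERSPECTIVE_SWAP,
    MemoryOneStrategy,
    PayoffCells,
    estimate_transition_probabilities,
    recover_payoff_matrix,
)
from .markov_engine import MarkovSystem, solve_system
from .synthetic_cohort import Cohort, SessionTable

__all__ = [
    "FitnessResult",
    "PairAnalysis",
    "signed_payoff_vector",
    "stationary_payoff",
    "extinction_rate",
    "total_fitness",
    "analyze_pair",
    "analyze_cohort",
    "cohort_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class FitnessResult:
    """Stationary payoffs of one participant-opponent pair."""

    pair_id: str
    opponent_label: str
    stationary_payoff_participant: float
    stationary_payoff_opponent: float
    opponent_prevails: bool
    signed_cells_used: dict


@dataclass
class PairAnalysis:
    """Full per-pair pipeline output: strategies, payoffs, chain, fitness."""

    fitness: FitnessResult
    strategy_participant: MemoryOneStrategy
    strategy_responder: MemoryOneStrategy
    cells_participant: PayoffCells
    cells_responder: PayoffCells
    system: MarkovSystem

    @property
    def pair_id(self) -> str:
        return self.fitness.pair_id

    @property
    def opponent_label(self) -> str:
        return self.fitness.opponent_label

    @property
    def opponent_prevails(self) -> bool:
        return self.fitness.opponent_prevails


def signed_payoff_vector(
    cells: PayoffCells, player1: str = "participant"
) -> np.ndarray:
    """Sign-adjusted payoff 4-vector re-indexed into player 1's perspective.

    Forgone cells (responder rejected) are negated.  Missing cells enter as
    0 — a never-observed outcome should also carry ~0 stationary mass; the
    caller is warned downstream if it does not.
    """
    values = cells.values.copy()
    missing = np.isnan(values)
    if missing.any():
        logger.warning(
            "%s payoff cells %s never observed; entering fitness as 0",
            cells.owner,
            [int(i) for i in np.flatnonzero(missing)],
        )
        values[missing] = 0.0
    values[cells.forgone_mask] = -values[cells.forgone_mask]
    if cells.owner != player1:
        values = values[PERSPECTIVE_SWAP]
    return values


def stationary_payoff(v: np.ndarray, signed_S: np.ndarray) -> float:
    """Expected payoff per trial at stationarity: the dot product v . S."""
    v = np.asarray(v, dtype=float)
    signed_S = np.asarray(signed_S, dtype=float)
    if v.shape != (4,) or signed_S.shape != (4,):
        raise ValueError(
            f"v and S must be 4-vectors, got shapes {v.shape} and {signed_S.shape}"
        )
    return float(v @ signed_S)


def analyze_pair(
    session: SessionTable,
    fill_policy: str = "uniform",
    pair_id: str | None = None,
) -> PairAnalysis:
    """Run recovery, the Markov solve and the fitness computation for one session."""
    if pair_id is None:
        pair_id = f"{session.participant_id}:{session.opponent_label}"
    cells_part, cells_resp = recover_payoff_matrix(session)
    strat_part, strat_resp = estimate_transition_probabilities(session)
    system = solve_system(strat_part, strat_resp, fill_policy=fill_policy)
    S_part = signed_payoff_vector(cells_part)
    S_resp = signed_payoff_vector(cells_resp)
    for cells, S in ((cells_part, S_part), (cells_resp, S_resp)):
        missing = np.isnan(cells.values)
        if missing.any():
            mass = float(system.v[PERSPECTIVE_SWAP][missing].sum()
                         if cells.owner == "responder"
                         else system.v[missing].sum())
            if mass > 0.01:
                logger.warning(
                    "pair %s: stationary mass %.3f on zero-filled %s cells",
                    pair_id, mass, cells.owner,
                )
    payoff_part = stationary_payoff(system.v, S_part)
    payoff_resp = stationary_payoff(system.v, S_resp)
    fitness = FitnessResult(
        pair_id=pair_id,
        opponent_label=session.opponent_label,
        stationary_payoff_participant=payoff_part,
        stationary_payoff_opponent=payoff_resp,
        opponent_prevails=payoff_resp > payoff_part,
        signed_cells_used={"participant": S_part.tolist(), "responder": S_resp.tolist()},
    )
    return PairAnalysis(
        fitness=fitness,
        strategy_participant=strat_part,
        strategy_responder=strat_resp,
        cells_participant=cells_part,
        cells_responder=cells_resp,
        system=system,
    )


def extinction_rate(results, opponent_label: str) -> float:
    """Fraction of pairs against ``opponent_label`` where the opponent strictly prevails.

    Exact payoff ties count as the opponent *not* prevailing.
    """
    flags = [
        r.opponent_prevails for r in results if r.opponent_label == opponent_label
    ]
    if not flags:
        raise ValueError(f"no pairs with opponent label {opponent_label!r}")
    return float(np.mean(flags))


def total_fitness(
    participant_payoffs: tuple[float, float],
    opponent_payoffs: tuple[float, float],
) -> float:
    """Participant's total fitness across both opponents.

    ``participant_payoffs`` holds the participant's stationary payoffs
    (vs individualistic, vs prosocial); ``opponent_payoffs`` the respective
    opponents' stationary payoffs from the same systems.
    """
    return float(sum(participant_payoffs) - sum(opponent_payoffs))


def analyze_cohort(
    cohort: Cohort | list[SessionTable], fill_policy: str = "uniform"
) -> list[PairAnalysis]:
    """Run :func:`analyze_pair` over every session of a cohort."""
    sessions = cohort.sessions if isinstance(cohort, Cohort) else cohort
    return [analyze_pair(s, fill_policy=fill_policy) for s in sessions]


def cohort_summary(results: list[PairAnalysis]) -> tuple[pd.DataFrame, dict]:
    """Tidy per-pair table plus cohort-level summary.

    The summary carries the extinction rate per opponent type and, when each
    participant faced both opponents, the mean total fitness across
    participants.
    """
    rows = [
        {
            "pair_id": r.pair_id,
            "opponent": r.opponent_label,
            "payoff_participant": r.fitness.stationary_payoff_participant,
            "payoff_opponent": r.fitness.stationary_payoff_opponent,
            "opponent_prevails": r.opponent_prevails,
            "stationary_cc": float(r.system.v[0]),
            "fallback_used": r.system.fallback_used,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    labels = sorted(table["opponent"].unique())
    summary: dict = {
        "n_pairs": len(results),
        "extinction_rate": {
            label: extinction_rate(results, label) for label in labels
        },
    }
    if set(labels) >= {"individualistic", "prosocial"}:
        per_participant = []
        pid = table["pair_id"].str.split(":").str[0]
        for _, grp in table.assign(participant=pid).groupby("participant"):
            by_opp = grp.set_index("opponent")
            if {"individualistic", "prosocial"} <= set(by_opp.index):
                per_participant.append(
                    total_fitness(
                        (
                            by_opp.loc["individualistic", "payoff_participant"],
                            by_opp.loc["prosocial", "payoff_participant"],
                        ),
                        (
                            by_opp.loc["individualistic", "payoff_opponent"],
                            by_opp.loc["prosocial", "payoff_opponent"],
                        ),
                    )
                )
        if per_participant:
            summary["mean_total_fitness"] = float(np.mean(per_participant))
    return table, summary
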