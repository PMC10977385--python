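"""Recover a 2x2 evolutionary-game representation from ultimatum sessions.

Each trial is classified into a joint outcome xy in {CC, CD, DC, DD}.  The
proposer's move is cooperation (C) when they chose the offer with the higher
inferred acceptance probability — i.e. the offer friendlier to the opponent —
and defection (D) otherwise; the responder's move is C on accept, D on
reject.  Every 4-vector produced here is stored in its OWNER's perspective:
the first letter is the owner's own move.  The two perspectives of one trial
are transposes of each other (owner CD <-> other DC), and module boundaries
perform explicit index swaps rather than relabelling silently.

From the classified trials the module recovers

* per-agent payoff cells: mean realized rewards per outcome for accepted
  trials, mean *forgone* amounts for rejected trials (marked by
  ``forgone_mask``); and
* memory-one strategies: the conditional probability of cooperating given
  the previous trial's joint outcome (transition probabilities).

Cells never visited carry an explicit NaN, not a silent zero; downstream
consumers decide the fill policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .synthetic_cohort import SessionTable, UGTrial

__all__ = [
    "Outcome",
    "OUTCOME_LABELS",
    "PERSPECTIVE_SWAP",
    "PayoffCells",
    "MemoryOneStrategy",
    "classify_trial",
    "classify_moves",
    "recover_payoff_matrix",
    "estimate_transition_probabilities",
]

OUTCOME_LABELS = ("CC", "CD", "DC", "DD")

#: index permutation taking a 4-vector from one player's perspective to the
#: other's: CC and DD are shared, CD and DC swap.
PERSPECTIVE_SWAP = np.array([0, 2, 1, 3])


class Outcome(IntEnum):
    """Joint outcome of one trial, first letter = perspective owner's move."""

    CC = 0
    CD = 1
    DC = 2
    DD = 3

    @property
    def label(self) -> str:
        return OUTCOME_LABELS[self]

    def transpose(self) -> "Outcome":
        """The same trial seen from the other player's perspective."""
        return Outcome(int(PERSPECTIVE_SWAP[self]))


class ClassificationError(ValueError):
    """Raised when a trial lacks the fields needed for outcome classification."""


@dataclass
class PayoffCells:
    """Mean payoff (or forgone payoff) per joint outcome, owner's perspective.

    ``values[k]`` is NaN when ``counts[k] == 0``.  ``forgone_mask[k]`` is True
    exactly for outcomes in which the responder rejected, where the stored
    mean is a forgone rather than realized amount.
    """

    owner: str  # "participant" | "responder"
    values: np.ndarray
    counts: np.ndarray
    forgone_mask: np.ndarray


@dataclass
class MemoryOneStrategy:
    """Conditional cooperation probabilities, owner's perspective.

    ``p[k]`` = probability the owner cooperates on trial t given joint
    outcome k on trial t-1; NaN where the conditioning outcome was never
    observed (``counts[k] == 0``).
    """

    owner: str
    p: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_probabilities(cls, p, owner: str = "") -> "MemoryOneStrategy":
        """Wrap a fully specified probability 4-vector (e.g. for simulation)."""
        p = np.asarray(p, dtype=float)
        if p.shape != (4,):
            raise ValueError(f"expected 4 probabilities, got shape {p.shape}")
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        return cls(owner=owner, p=p.copy(), counts=np.full(4, -1, dtype=int))

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.p))


def classify_moves(trial: UGTrial) -> tuple[bool, bool]:
    """(participant cooperated, responder cooperated) for one trial.

    Participant C iff the chosen option's inferred acceptance probability is
    >= the unchosen option's (ties count as cooperation: the participant did
    not pick the strictly worse-for-opponent offer).  Responder C iff accept.
    """
    q_chosen, q_other = trial.q_hat_chosen, trial.q_hat_unchosen
    if not (np.isfinite(q_chosen) and np.isfinite(q_other)):
        raise ClassificationError(
            f"trial {trial.trial_index}: inferred acceptance probabilities "
            f"are missing or non-finite ({q_chosen}, {q_other})"
        )
    return q_chosen >= q_other, trial.response == "accept"


def classify_trial(trial: UGTrial, perspective: str) -> Outcome:
    """Joint outcome of ``trial`` in the given perspective's convention."""
    part_c, resp_c = classify_moves(trial)
    if perspective == "participant":
        own, other = part_c, resp_c
    elif perspective == "responder":
        own, other = resp_c, part_c
    else:
        raise ValueError(f"perspective must be 'participant' or 'responder', got {perspective!r}")
    return Outcome((0 if own else 2) + (0 if other else 1))


def _forgone_mask(owner: str) -> np.ndarray:
    # responder defection = rejection: other-player-D cells for the
    # participant (CD, DD), own-D cells for the responder (DC, DD)
    if owner == "participant":
        return np.array([False, True, False, True])
    return np.array([False, False, True, True])


def recover_payoff_matrix(
    session: SessionTable,
) -> tuple[PayoffCells, PayoffCells]:
    """Per-outcome mean payoffs for (participant, responder).

    Accepted trials contribute realized rewards; rejected trials contribute
    the chosen offer's forgone amounts (both players bank nothing when an
    ultimatum is rejected, so the rejected cells record what was sacrificed).
    """
    if len(session) == 0:
        raise ValueError("session has no trials")
    sums = {owner: np.zeros(4) for owner in ("participant", "responder")}
    counts = {owner: np.zeros(4, dtype=int) for owner in ("participant", "responder")}
    for trial in session.trials:
        accepted = trial.response == "accept"
        amount_part = trial.reward_proposer if accepted else trial.forgone_proposer
        amount_resp = trial.reward_responder if accepted else trial.forgone_responder
        for owner, amount in (("participant", amount_part), ("responder", amount_resp)):
            k = classify_trial(trial, owner)
            sums[owner][k] += amount
            counts[owner][k] += 1
    cells = []
    for owner in ("participant", "responder"):
        with np.errstate(invalid="ignore"):
            values = np.where(counts[owner] > 0, sums[owner] / np.maximum(counts[owner], 1), np.nan)
        cells.append(
            PayoffCells(
                owner=owner,
                values=values,
                counts=counts[owner],
                forgone_mask=_forgone_mask(owner),
            )
        )
    return cells[0], cells[1]


def estimate_transition_probabilities(
    session: SessionTable,
) -> tuple[MemoryOneStrategy, MemoryOneStrategy]:
    """Memory-one strategy estimates for (participant, responder).

    ``p[k]`` is the fraction of trials on which the owner cooperated given
    joint outcome k on the previous trial.  The first trial has no
    conditioning outcome and enters only as a conditioning event for the
    second; never-visited conditioning outcomes yield NaN with count 0.
    """
    if len(session) < 2:
        raise ValueError("need at least 2 trials to estimate transition probabilities")
    moves = [classify_moves(t) for t in session.trials]
    strategies = []
    for owner_idx, owner in enumerate(("participant", "responder")):
        coop = np.zeros(4)
        counts = np.zeros(4, dtype=int)
        for t in range(1, len(moves)):
            prev = classify_trial(session.trials[t - 1], owner)
            counts[prev] += 1
            if moves[t][owner_idx]:
                coop[prev] += 1
        with np.errstate(invalid="ignore"):
            p = np.where(counts > 0, coop / np.maximum(counts, 1), np.nan)
        strategies.append(MemoryOneStrategy(owner=owner, p=p, counts=counts))
    return strategies[0], strategies[1]
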