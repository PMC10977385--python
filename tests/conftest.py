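"""Shared fixtures: hand-built sessions and memory-one play simulators."""

from __future__ import annotations

import numpy as np
import pytest

from ipdbridge.ipd_recovery import PERSPECTIVE_SWAP
from ipdbridge.svo_model import Offer
from ipdbridge.synthetic_cohort import SessionTable, UGTrial


def make_trial(
    index: int,
    participant_coop: bool,
    responder_coop: bool,
    r_self: float = 50.0,
    r_other: float = 50.0,
) -> UGTrial:
    """A trial whose classified moves are exactly the two booleans.

    The chosen offer is always the left one; the participant's move is
    encoded through the inferred-acceptance ordering (chosen >= unchosen
    means cooperate) and the responder's through accept/reject.
    """
    q_hat_left, q_hat_right = (0.8, 0.2) if participant_coop else (0.2, 0.8)
    accepted = responder_coop
    return UGTrial(
        trial_index=index,
        left_offer=Offer(r_self, r_other),
        right_offer=Offer(max(0.0, r_self - 10.0), r_other + 10.0),
        q_left=q_hat_left,
        q_right=q_hat_right,
        q_hat_left=q_hat_left,
        q_hat_right=q_hat_right,
        choice="left",
        response="accept" if accepted else "reject",
        reward_proposer=r_other if accepted else 0.0,
        reward_responder=r_self if accepted else 0.0,
        forgone_proposer=0.0 if accepted else r_other,
        forgone_responder=0.0 if accepted else r_self,
    )


def session_from_moves(
    moves: list[tuple[bool, bool]],
    amounts: list[tuple[float, float]] | None = None,
    participant_id: str = "P001",
    opponent_label: str = "individualistic",
) -> SessionTable:
    """Build a session realizing a given (participant, responder) move sequence."""
    trials = []
    for i, (pc, rc) in enumerate(moves, start=1):
        r_self, r_other = amounts[i - 1] if amounts else (50.0, 50.0)
        trials.append(make_trial(i, pc, rc, r_self=r_self, r_other=r_other))
    return SessionTable(
        participant_id=participant_id, opponent_label=opponent_label, trials=trials
    )


def simulate_memory_one_moves(
    p_participant: np.ndarray,
    p_responder: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
) -> list[tuple[bool, bool]]:
    """Joint play of two memory-one strategies, each in its own perspective."""
    moves = [(bool(rng.random() < 0.5), bool(rng.random() < 0.5))]
    for _ in range(n_trials - 1):
        pc, rc = moves[-1]
        state_part = (0 if pc else 2) + (0 if rc else 1)
        state_resp = int(PERSPECTIVE_SWAP[state_part])
        moves.append(
            (
                bool(rng.random() < p_participant[state_part]),
                bool(rng.random() < p_responder[state_resp]),
            )
        )
    return moves


@pytest.fixture(scope="session")
def small_cohort():
    from ipdbridge.synthetic_cohort import generate_cohort

    return generate_cohort(n_participants=5, n_trials=60, seed=11)
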