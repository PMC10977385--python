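"""Synthetic binary-ultimatum cohorts with the structure the analysis assumes.

Each session pits one proposer (the "participant") against one stochastic
responder (:mod:`~ipdbridge.svo_model`).  On every trial the proposer sees two
offers splitting a fixed stake, infers each offer's acceptance probability
(the true probability perturbed by Gaussian belief noise), and chooses via a
softmax over subjectively weighted expected values

    EV(offer) = w(q_hat) * u(r_other),    u(r) = r**gamma,
    w(q) = exp(-(-ln q)**tau)             (Prelec weighting),

after which the responder accepts or rejects stochastically.  The default
cohort shape is 50 participants x 2 opponents (prosocial, individualistic)
x 120 trials, with one offer list shared bit-identically by every session so
that condition differences cannot stem from the stimuli.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .svo_model import Offer, SVOParams, acceptance_probability, preset, respond

__all__ = [
    "ProposerParams",
    "UGTrial",
    "SessionTable",
    "Cohort",
    "generate_offer_set",
    "proposer_choice",
    "simulate_session",
    "generate_cohort",
    "default_proposer_population",
    "cohort_to_dataframe",
    "sessions_from_dataframe",
    "CSV_COLUMNS",
]

#: probability clamp applied before Prelec weighting (w is undefined at q = 0)
PROB_EPS = 1e-6

CSV_COLUMNS = [
    "participant_id",
    "opponent",
    "trial",
    "left_rself",
    "left_rother",
    "right_rself",
    "right_rother",
    "q_left",
    "q_right",
    "qhat_left",
    "qhat_right",
    "choice",
    "response",
    "reward_prop",
    "reward_resp",
    "forgone_prop",
    "forgone_resp",
]


class ConfigurationError(ValueError):
    """Raised when cohort settings are internally inconsistent."""


@dataclass(frozen=True)
class ProposerParams:
    """Configurable stand-in for a proposer's value model.

    gamma : risk-attitude exponent of the power utility u(r) = r**gamma (> 0)
    tau : curvature of the Prelec probability-weighting function (> 0);
        tau = 1 is the identity, tau < 1 gives the inverse-S shape typical
        of human probability weighting
    choice_temperature : softmax temperature in monetary units; 0 means a
        hard argmax (ties broken toward the left offer)
    belief_noise_sd : SD of Gaussian noise on the inferred acceptance
        probability, clamped to [PROB_EPS, 1 - PROB_EPS]
    """

    gamma: float = 1.0
    tau: float = 1.0
    choice_temperature: float = 3.0
    belief_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be >= 0")
        if self.belief_noise_sd < 0:
            raise ValueError("belief_noise_sd must be >= 0")


@dataclass(frozen=True)
class UGTrial:
    """One binary-ultimatum trial.

    Rewards follow the accept/reject bookkeeping of the game: on acceptance
    both sides bank the chosen offer's amounts and the forgone fields are 0;
    on rejection both rewards are 0 and the forgone fields carry the chosen
    offer's amounts.
    """

    trial_index: int
    left_offer: Offer
    right_offer: Offer
    q_left: float
    q_right: float
    q_hat_left: float
    q_hat_right: float
    choice: str  # "left" | "right"
    response: str  # "accept" | "reject"
    reward_proposer: float
    reward_responder: float
    forgone_proposer: float
    forgone_responder: float

    @property
    def chosen_offer(self) -> Offer:
        return self.left_offer if self.choice == "left" else self.right_offer

    @property
    def q_hat_chosen(self) -> float:
        return self.q_hat_left if self.choice == "left" else self.q_hat_right

    @property
    def q_hat_unchosen(self) -> float:
        return self.q_hat_right if self.choice == "left" else self.q_hat_left


@dataclass
class SessionTable:
    """An ordered sequence of trials between one participant and one opponent."""

    participant_id: str
    opponent_label: str
    trials: list[UGTrial]
    seed_record: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "participant_id": self.participant_id,
                    "opponent": self.opponent_label,
                    "trial": t.trial_index,
                    "left_rself": t.left_offer.r_self,
                    "left_rother": t.left_offer.r_other,
                    "right_rself": t.right_offer.r_self,
                    "right_rother": t.right_offer.r_other,
                    "q_left": t.q_left,
                    "q_right": t.q_right,
                    "qhat_left": t.q_hat_left,
                    "qhat_right": t.q_hat_right,
                    "choice": t.choice,
                    "response": t.response,
                    "reward_prop": t.reward_proposer,
                    "reward_resp": t.reward_responder,
                    "forgone_prop": t.forgone_proposer,
                    "forgone_resp": t.forgone_responder,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass
class Cohort:
    """All sessions of a synthetic study plus the settings that produced them."""

    sessions: list[SessionTable]
    metadata: dict

    def __len__(self) -> int:
        return len(self.sessions)


def generate_offer_set(
    n_trials: int,
    stake: float = 100.0,
    grid_step: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[Offer, Offer]]:
    """Draw ``n_trials`` distinct ordered offer pairs on a grid splitting ``stake``.

    Every offer allocates ``r_self + r_other = stake`` with ``r_self`` a
    multiple of ``grid_step``; the two offers within a trial differ.  Pairs
    are sampled without replacement so a cohort never repeats a stimulus, and
    the same list is meant to be reused for every participant x opponent
    condition.
    """
    if rng is None:
        rng = np.random.default_rng()
    if stake <= 0:
        raise ConfigurationError(f"stake must be positive, got {stake}")
    n_steps = stake / grid_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(
            f"grid_step {grid_step} does not divide stake {stake}"
        )
    n_steps = int(round(n_steps))
    offers = [Offer(k * grid_step, stake - k * grid_step) for k in range(n_steps + 1)]
    n_offers = len(offers)
    n_pairs = n_offers * (n_offers - 1)  # ordered pairs, left != right
    if n_trials > n_pairs:
        raise ConfigurationError(
            f"n_trials={n_trials} exceeds the {n_pairs} distinct ordered offer "
            f"pairs available at stake={stake}, grid_step={grid_step}"
        )
    chosen = rng.choice(n_pairs, size=n_trials, replace=False)
    pairs = []
    for idx in chosen:
        i, j = divmod(int(idx), n_offers - 1)
        if j >= i:
            j += 1
        pairs.append((offers[i], offers[j]))
    return pairs


def _prelec_weight(q: float, tau: float) -> float:
    q = min(max(q, PROB_EPS), 1.0 - PROB_EPS)
    return float(np.exp(-((-np.log(q)) ** tau)))


def proposer_choice(
    offers: tuple[Offer, Offer],
    q_hats: tuple[float, float],
    params: ProposerParams,
    rng: np.random.Generator,
) -> str:
    """Choose ``"left"`` or ``"right"`` by softmax over weighted expected values.

    EV = w(q_hat) * r_other**gamma per option.  With temperature 0 the higher
    EV wins deterministically and exact ties go to the left offer.
    """
    for q in q_hats:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"q_hat must lie in [0, 1], got {q}")
    evs = [
        _prelec_weight(q, params.tau) * (offer.r_other ** params.gamma)
        for offer, q in zip(offers, q_hats)
    ]
    if params.choice_temperature == 0:
        return "left" if evs[0] >= evs[1] else "right"
    # logistic form of the two-option softmax, stable for large EV gaps
    p_left = float(
        1.0 / (1.0 + np.exp(-np.clip((evs[0] - evs[1]) / params.choice_temperature, -700, 700)))
    )
    return "left" if rng.random() < p_left else "right"


def simulate_session(
    participant_id: str,
    opponent: SVOParams,
    proposer: ProposerParams,
    offers: Sequence[tuple[Offer, Offer]],
    rng: np.random.Generator,
    opponent_label: str | None = None,
    seed_record: dict | None = None,
) -> SessionTable:
    """Play every offer pair in order and record the resulting trials."""
    if len(offers) == 0:
        raise ValueError("offers must be non-empty")
    trials = []
    for index, (left, right) in enumerate(offers, start=1):
        q_left = acceptance_probability(opponent, left)
        q_right = acceptance_probability(opponent, right)
        if proposer.belief_noise_sd > 0:
            noise = rng.normal(0.0, proposer.belief_noise_sd, size=2)
        else:
            noise = np.zeros(2)
        q_hat_left = float(np.clip(q_left + noise[0], PROB_EPS, 1.0 - PROB_EPS))
        q_hat_right = float(np.clip(q_right + noise[1], PROB_EPS, 1.0 - PROB_EPS))
        choice = proposer_choice(
            (left, right), (q_hat_left, q_hat_right), proposer, rng
        )
        chosen = left if choice == "left" else right
        accepted = respond(opponent, chosen, rng)
        trials.append(
            UGTrial(
                trial_index=index,
                left_offer=left,
                right_offer=right,
                q_left=q_left,
                q_right=q_right,
                q_hat_left=q_hat_left,
                q_hat_right=q_hat_right,
                choice=choice,
                response="accept" if accepted else "reject",
                reward_proposer=chosen.r_other if accepted else 0.0,
                reward_responder=chosen.r_self if accepted else 0.0,
                forgone_proposer=0.0 if accepted else chosen.r_other,
                forgone_responder=0.0 if accepted else chosen.r_self,
            )
        )
    label = opponent_label if opponent_label is not None else opponent.label
    return SessionTable(
        participant_id=str(participant_id),
        opponent_label=label,
        trials=trials,
        seed_record=seed_record or {},
    )


def default_proposer_population(rng: np.random.Generator) -> ProposerParams:
    """Draw one participant's proposer parameters.

    Mild lognormal heterogeneity around risk neutrality and linear weighting:
    gamma, tau ~ LogNormal(0, 0.2); temperature and belief noise fixed at the
    class defaults.
    """
    return ProposerParams(
        gamma=float(rng.lognormal(0.0, 0.2)),
        tau=float(rng.lognormal(0.0, 0.2)),
    )


def generate_cohort(
    n_participants: int = 50,
    n_trials: int = 120,
    stake: float = 100.0,
    grid_step: float = 5.0,
    opponents: Sequence[str] = ("individualistic", "prosocial"),
    proposer_population: Callable[[np.random.Generator], ProposerParams] | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a full cohort: each participant plays every opponent once.

    The offer list is drawn once and reused bit-identically by all sessions.
    Per-participant proposer parameters are drawn once and reused against
    both opponents.  RNG streams are derived from the master seed by
    participant index and opponent index, so sessions are independent and
    the whole cohort is reproducible.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if proposer_population is None:
        proposer_population = default_proposer_population

    offer_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    offers = generate_offer_set(n_trials, stake, grid_step, offer_rng)

    opponent_params = {name: preset(name) for name in opponents}
    sessions = []
    proposer_meta = {}
    for pid in range(1, n_participants + 1):
        prop_rng = np.random.default_rng(np.random.SeedSequence([seed, pid, 1]))
        proposer = proposer_population(prop_rng)
        proposer_meta[f"P{pid:03d}"] = dataclasses.asdict(proposer)
        for opp_idx, opp_name in enumerate(opponents):
            session_seed = [seed, pid, 2 + opp_idx]
            session_rng = np.random.default_rng(np.random.SeedSequence(session_seed))
            sessions.append(
                simulate_session(
                    participant_id=f"P{pid:03d}",
                    opponent=opponent_params[opp_name],
                    proposer=proposer,
                    offers=offers,
                    rng=session_rng,
                    opponent_label=opp_name,
                    seed_record={"seed_sequence": session_seed},
                )
            )
    metadata = {
        "seed": seed,
        "n_participants": n_participants,
        "n_trials": n_trials,
        "stake": stake,
        "grid_step": grid_step,
        "opponents": list(opponents),
        "proposer_params": proposer_meta,
    }
    return Cohort(sessions=sessions, metadata=metadata)


def cohort_to_dataframe(cohort: Cohort) -> pd.DataFrame:
    """Concatenate every session into one trial-level table (the CSV schema)."""
    return pd.concat(
        [s.to_dataframe() for s in cohort.sessions], ignore_index=True
    )


def sessions_from_dataframe(df: pd.DataFrame) -> list[SessionTable]:
    """Rebuild :class:`SessionTable` objects from a trial-level table.

    Accepts any table in the documented CSV schema, including externally
    deposited session files, grouped by (participant_id, opponent).
    """
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    sessions = []
    for (pid, opp), group in df.groupby(["participant_id", "opponent"], sort=True):
        group = group.sort_values("trial")
        trials = [
            UGTrial(
                trial_index=int(row.trial),
                left_offer=Offer(float(row.left_rself), float(row.left_rother)),
                right_offer=Offer(float(row.right_rself), float(row.right_rother)),
                q_left=float(row.q_left),
                q_right=float(row.q_right),
                q_hat_left=float(row.qhat_left),
                q_hat_right=float(row.qhat_right),
                choice=str(row.choice),
                response=str(row.response),
                reward_proposer=float(row.reward_prop),
                reward_responder=float(row.reward_resp),
                forgone_proposer=float(row.forgone_prop),
                forgone_responder=float(row.forgone_resp),
            )
            for row in group.itertuples()
        ]
        sessions.append(
            SessionTable(participant_id=str(pid), opponent_label=str(opp), trials=trials)
        )
    return sessions
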