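"""Synthetic cohort generator: offers, proposer choice, sessions, cohorts."""

import math

import numpy as np
import pytest

from ipdbridge.svo_model import Offer, SVOParams, preset
from ipdbridge.synthetic_cohort import (
    ConfigurationError,
    ProposerParams,
    cohort_to_dataframe,
    generate_cohort,
    generate_offer_set,
    proposer_choice,
    sessions_from_dataframe,
    simulate_session,
)


class TestOfferSet:
    def test_pairs_split_stake_and_are_distinct(self):
        rng = np.random.default_rng(0)
        pairs = generate_offer_set(3, stake=100, grid_step=10, rng=rng)
        assert len(pairs) == 3
        for left, right in pairs:
            assert left.r_self + left.r_other == 100
            assert right.r_self + right.r_other == 100
            assert left != right

    def test_same_seed_same_offers(self):
        a = generate_offer_set(50, rng=np.random.default_rng(9))
        b = generate_offer_set(50, rng=np.random.default_rng(9))
        assert a == b

    def test_indivisible_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="divide"):
            generate_offer_set(10, stake=100, grid_step=7, rng=np.random.default_rng(0))

    def test_too_many_trials_rejected(self):
        # an 11-offer grid has 110 ordered distinct pairs
        with pytest.raises(ConfigurationError, match="exceeds"):
            generate_offer_set(120, stake=100, grid_step=10, rng=np.random.default_rng(0))


class TestProposerChoice:
    def test_higher_qhat_wins_at_equal_rewards(self):
        params = ProposerParams(gamma=1, tau=1, choice_temperature=0, belief_noise_sd=0)
        offers = (Offer(50, 30), Offer(70, 30))
        rng = np.random.default_rng(0)
        assert proposer_choice(offers, (0.8, 0.3), params, rng) == "left"
        assert proposer_choice(offers, (0.3, 0.8), params, rng) == "right"

    def test_expected_value_tradeoff(self):
        # EV reduces to q * r_other: 0.9*10 = 9 < 0.3*40 = 12
        params = ProposerParams(gamma=1, tau=1, choice_temperature=0, belief_noise_sd=0)
        offers = (Offer(90, 10), Offer(60, 40))
        choice = proposer_choice(offers, (0.9, 0.3), params, np.random.default_rng(0))
        assert choice == "right"

    def test_tie_goes_left(self):
        params = ProposerParams(choice_temperature=0)
        offers = (Offer(50, 50), Offer(60, 40))
        # both expected values zero (q_hat at the weighting clamp floor)
        assert proposer_choice(offers, (1e-12, 1e-12), params, np.random.default_rng(0)) == "left"

    def test_infinite_temperature_is_coin_flip(self):
        params = ProposerParams(choice_temperature=1e12)
        offers = (Offer(50, 50), Offer(90, 10))
        rng = np.random.default_rng(5)
        n = 4000
        lefts = sum(
            proposer_choice(offers, (0.9, 0.1), params, rng) == "left" for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(lefts / n - 0.5) < 3 * se

    def test_invalid_qhat_rejected(self):
        params = ProposerParams()
        with pytest.raises(ValueError):
            proposer_choice((Offer(50, 50), Offer(60, 40)), (1.2, 0.5), params,
                            np.random.default_rng(0))


class TestSession:
    def setup_method(self):
        self.offers = generate_offer_set(60, rng=np.random.default_rng(2))

    def test_reward_bookkeeping_and_conservation(self):
        session = simulate_session(
            "P1", preset("prosocial"), ProposerParams(), self.offers,
            np.random.default_rng(1),
        )
        for t in session.trials:
            if t.response == "accept":
                assert t.reward_proposer + t.reward_responder == 100.0
                assert t.reward_proposer == t.chosen_offer.r_other
                assert t.reward_responder == t.chosen_offer.r_self
                assert t.forgone_proposer == t.forgone_responder == 0.0
            else:
                assert t.reward_proposer == t.reward_responder == 0.0
                assert t.forgone_proposer == t.chosen_offer.r_other
                assert t.forgone_responder == t.chosen_offer.r_self

    def test_zero_belief_noise_reveals_true_probabilities(self):
        proposer = ProposerParams(belief_noise_sd=0.0)
        session = simulate_session(
            "P1", preset("individualistic"), proposer, self.offers,
            np.random.default_rng(1),
        )
        for t in session.trials:
            assert t.q_hat_left == pytest.approx(t.q_left, abs=1e-6)
            assert t.q_hat_right == pytest.approx(t.q_right, abs=1e-6)

    def test_indifferent_responder_accepts_half(self):
        opponent = SVOParams(alpha=1.0, delta=0.0, rho=-2.0, beta=0.0, label="coin")
        offers = generate_offer_set(120, rng=np.random.default_rng(3))
        session = simulate_session(
            "P1", opponent, ProposerParams(), offers, np.random.default_rng(8)
        )
        rate = np.mean([t.response == "accept" for t in session.trials])
        se = math.sqrt(0.25 / 120)
        assert abs(rate - 0.5) < 3 * se

    def test_empty_offers_rejected(self):
        with pytest.raises(ValueError):
            simulate_session("P1", preset("prosocial"), ProposerParams(), [],
                             np.random.default_rng(0))


class TestCohort:
    def test_shape_and_shared_offer_list(self):
        cohort = generate_cohort(n_participants=2, n_trials=30, seed=4)
        assert len(cohort) == 4  # each participant vs both presets
        assert all(len(s) == 30 for s in cohort.sessions)
        reference = [(t.left_offer, t.right_offer) for t in cohort.sessions[0].trials]
        for session in cohort.sessions[1:]:
            assert [(t.left_offer, t.right_offer) for t in session.trials] == reference

    def test_single_participant_yields_two_sessions(self):
        assert len(generate_cohort(n_participants=1, n_trials=10, seed=0)) == 2

    def test_identical_seeds_identical_csv(self):
        csv_a = cohort_to_dataframe(generate_cohort(2, 20, seed=5)).to_csv(index=False)
        csv_b = cohort_to_dataframe(generate_cohort(2, 20, seed=5)).to_csv(index=False)
        assert csv_a == csv_b
        csv_c = cohort_to_dataframe(generate_cohort(2, 20, seed=6)).to_csv(index=False)
        assert csv_a != csv_c

    def test_dataframe_roundtrip(self, small_cohort):
        df = cohort_to_dataframe(small_cohort)
        sessions = sessions_from_dataframe(df)
        assert len(sessions) == len(small_cohort)
        original = {(s.participant_id, s.opponent_label): s for s in small_cohort.sessions}
        for s in sessions:
            ref = original[(s.participant_id, s.opponent_label)]
            assert len(s) == len(ref)
            assert [t.choice for t in s.trials] == [t.choice for t in ref.trials]
            assert [t.response for t in s.trials] == [t.response for t in ref.trials]

    def test_missing_columns_rejected(self, small_cohort):
        df = cohort_to_dataframe(small_cohort).drop(columns=["qhat_left"])
        with pytest.raises(ValueError, match="qhat_left"):
            sessions_from_dataframe(df)

    def test_prosocial_opponent_accepts_more(self, small_cohort):
        # chosen offers are identical stimuli across conditions; the prosocial
        # value function rewards the near-equal splits proposers gravitate to
        rates = {}
        for label in ("prosocial", "individualistic"):
            accepts = [
                t.response == "accept"
                for s in small_cohort.sessions
                if s.opponent_label == label
                for t in s.trials
            ]
            rates[label] = (np.mean(accepts), len(accepts))
        diff = rates["prosocial"][0] - rates["individualistic"][0]
        se = math.sqrt(sum(r * (1 - r) / n for r, n in rates.values()))
        assert diff > 3 * se
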