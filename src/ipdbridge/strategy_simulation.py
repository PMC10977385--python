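"""Random memory-one strategy ensembles and long-term cooperation phenotypes.

Draws large ensembles of strategy pairs with all eight conditional
cooperation probabilities i.i.d. uniform(0, 1), solves each pair's joint
chain, ranks pairs by the stationary mutual-cooperation probability (the CC
entry of the stationary vector), and profiles the best and worst tails.
Within-group correlations between conditional cooperation rates and
long-term mutual cooperation are computed within each tail group separately
to avoid Simpson's-paradox artefacts from pooling heterogeneous groups.

The default correlation statistic treats every *agent* in a group as one
observation (a group of 1000 pairs contributes 2000 agents); the pair-mean
variant is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ipd_recovery import OUTCOME_LABELS, PERSPECTIVE_SWAP
from .markov_engine import stationary_vectors_batch

__all__ = [
    "SimulatedPair",
    "StrategyEnsemble",
    "UndefinedCorrelationError",
    "simulate_random_pairs",
    "rank_and_select",
    "group_correlation",
    "group_profiles",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested over a zero-variance feature."""


@dataclass(frozen=True)
class SimulatedPair:
    """One simulated strategy pair and its long-term behaviour."""

    p1: np.ndarray
    p2: np.ndarray
    v: np.ndarray
    cc_longterm: float
    pair_features: np.ndarray  # pair-mean cooperation prob after each outcome


@dataclass
class StrategyEnsemble:
    """A stack of simulated pairs stored column-wise for vectorized analysis."""

    p1: np.ndarray  # (n, 4), player 1's own perspective
    p2: np.ndarray  # (n, 4), player 2's own perspective
    v: np.ndarray  # (n, 4), player 1's perspective
    residuals: np.ndarray

    def __len__(self) -> int:
        return self.p1.shape[0]

    def __getitem__(self, i: int) -> SimulatedPair:
        return SimulatedPair(
            p1=self.p1[i],
            p2=self.p2[i],
            v=self.v[i],
            cc_longterm=float(self.v[i, 0]),
            pair_features=(self.p1[i] + self.p2[i]) / 2.0,
        )

    @property
    def cc_longterm(self) -> np.ndarray:
        return self.v[:, 0]

    @property
    def pair_features(self) -> np.ndarray:
        return (self.p1 + self.p2) / 2.0

    def subset(self, idx: np.ndarray) -> "StrategyEnsemble":
        return StrategyEnsemble(
            p1=self.p1[idx], p2=self.p2[idx], v=self.v[idx], residuals=self.residuals[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for k, lab in enumerate(OUTCOME_LABELS):
            cols[f"p1_{lab}"] = self.p1[:, k]
            cols[f"p2_{lab}"] = self.p2[:, k]
        for k, lab in enumerate(OUTCOME_LABELS):
            cols[f"v_{lab}"] = self.v[:, k]
        cols["cc_longterm"] = self.cc_longterm
        return pd.DataFrame(cols)


def simulate_random_pairs(n: int, seed: int | None = None) -> StrategyEnsemble:
    """Draw ``n`` uniform-random strategy pairs and solve their joint chains."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p1 = rng.uniform(size=(n, 4))
    p2 = rng.uniform(size=(n, 4))
    Ms = _batch_matrices(p1, p2)
    v, residuals = stationary_vectors_batch(Ms)
    return StrategyEnsemble(p1=p1, p2=p2, v=v, residuals=residuals)


def _batch_matrices(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    # vectorized equivalent of markov_engine.build_transition_matrix
    a = p1
    bs = p2[:, PERSPECTIVE_SWAP]
    return np.stack([a * bs, a * (1 - bs), (1 - a) * bs, (1 - a) * (1 - bs)], axis=2)


def rank_and_select(
    ensemble: StrategyEnsemble, fraction: float = 0.05
) -> tuple[StrategyEnsemble, StrategyEnsemble]:
    """Top and bottom ``fraction`` tails ranked by stationary CC probability.

    Sorting is stable and descending, so exact ties keep their original pair
    order.  Each tail has floor(fraction * n) members.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    n_group = int(np.floor(fraction * len(ensemble)))
    if n_group < 2:
        raise ValueError(
            f"fraction {fraction} of {len(ensemble)} pairs leaves fewer than 2 per group"
        )
    order = np.argsort(-ensemble.cc_longterm, kind="stable")
    return ensemble.subset(order[:n_group]), ensemble.subset(order[-n_group:])


def group_correlation(
    group: StrategyEnsemble, feature: str, statistic: str = "per_player"
) -> tuple[float, float]:
    """Pearson correlation of cooperation-after-``feature`` with stationary CC.

    ``feature`` is an outcome label (CC, CD, DC, DD); each agent's
    conditional cooperation probability is taken in its own perspective.
    ``statistic="per_player"`` enters both members of every pair as separate
    observations; ``"pair_mean"`` uses one averaged observation per pair.
    Returns (r, two-sided p-value).
    """
    if feature not in OUTCOME_LABELS:
        raise ValueError(f"feature must be one of {OUTCOME_LABELS}, got {feature!r}")
    if len(group) < 3:
        raise ValueError("group must have at least 3 pairs")
    k = OUTCOME_LABELS.index(feature)
    cc = group.cc_longterm
    if statistic == "per_player":
        x = np.concatenate([group.p1[:, k], group.p2[:, k]])
        y = np.concatenate([cc, cc])
    elif statistic == "pair_mean":
        x = group.pair_features[:, k]
        y = cc
    else:
        raise ValueError(f"statistic must be 'per_player' or 'pair_mean', got {statistic!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {'feature ' + feature if np.ptp(x) == 0 else 'stationary CC'}"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_profiles(
    top: StrategyEnsemble, bottom: StrategyEnsemble
) -> pd.DataFrame:
    """Mean +/- SE profile of each tail group.

    Rows cover, per outcome, the group's mean stationary probability and
    mean (pair-mean) cooperation rate, plus the realized rate of mutual-
    defection escape: the stationary DD occupancy times the cooperation
    probability after DD, i.e. how often a DD-then-cooperate event actually
    occurs at stationarity.
    """
    records = []
    for name, group in (("top", top), ("bottom", bottom)):
        if len(group) == 0:
            raise ValueError(f"{name} group is empty")
        n = len(group)
        for k, lab in enumerate(OUTCOME_LABELS):
            sv = group.v[:, k]
            cf = group.pair_features[:, k]
            records.append(
                {"group": name, "quantity": "stationary", "outcome": lab,
                 "mean": sv.mean(), "sem": sv.std(ddof=1) / np.sqrt(n)}
            )
            records.append(
                {"group": name, "quantity": "cooperation", "outcome": lab,
                 "mean": cf.mean(), "sem": cf.std(ddof=1) / np.sqrt(n)}
            )
        dd_escape = group.v[:, 3] * group.pair_features[:, 3]
        records.append(
            {"group": name, "quantity": "dd_escape", "outcome": "DD",
             "mean": dd_escape.mean(), "sem": dd_escape.std(ddof=1) / np.sqrt(n)}
        )
    return pd.DataFrame.from_records(records)
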