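"""Stochastic social-value responder model for binary ultimatum games.

A computerized responder evaluates an offer splitting a stake into ``r_self``
(its own share, :math:`R_S`) and ``r_other`` (the proposer's share,
:math:`R_O`) through a linear social-value function and accepts with logistic
probability

.. math::

    q_A = \\frac{1}{1 + e^{-\\beta(\\alpha R_S - \\delta R_O
          + \\rho\\,|R_S - R_O|)}},

where :math:`\\alpha` weights the responder's own reward, :math:`\\delta` the
other player's reward, :math:`\\rho` the absolute self--other inequality and
:math:`\\beta` is an inverse temperature (per monetary unit).  Two named
presets, ``"individualistic"`` and ``"prosocial"``, carry the hyper-parameter
vectors of the stochastic opponents emulated throughout this package; they
are loaded from a bundled YAML file so alternative agents can be configured
the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "SVOParams",
    "Offer",
    "acceptance_probability",
    "respond",
    "preset",
    "available_presets",
]


@dataclass(frozen=True)
class SVOParams:
    """Hyper-parameters of a responder's social-value function.

    alpha : weight on own reward (dimensionless)
    delta : weight on the other player's reward (dimensionless)
    rho   : weight on absolute self-other inequality (dimensionless)
    beta  : inverse temperature (per monetary unit), must be >= 0
    label : free-text preset name
    """

    alpha: float
    delta: float
    rho: float
    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "rho", "beta"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"SVOParams.{name} must be finite, got {value!r}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass(frozen=True)
class Offer:
    """A proposed split: ``r_self`` to the responder, ``r_other`` to the proposer."""

    r_self: float
    r_other: float

    def __post_init__(self) -> None:
        for name in ("r_self", "r_other"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"Offer.{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"Offer.{name} must be non-negative, got {value}")


def acceptance_probability(params: SVOParams, offer: Offer) -> float:
    """Probability that a responder with ``params`` accepts ``offer``.

    Evaluates the logistic social-value rule through a numerically stable
    sigmoid; exponent magnitudes beyond ~700 saturate at the 0/1 machine
    boundaries.
    """
    value = (
        params.alpha * offer.r_self
        - params.delta * offer.r_other
        + params.rho * abs(offer.r_self - offer.r_other)
    )
    return float(expit(params.beta * value))


def respond(params: SVOParams, offer: Offer, rng: np.random.Generator) -> bool:
    """Draw an accept (True) / reject (False) decision for ``offer``.

    A single Bernoulli draw with success probability
    :func:`acceptance_probability`; reproducible under a seeded ``rng``.
    """
    return bool(rng.random() < acceptance_probability(params, offer))


@lru_cache(maxsize=1)
def _load_presets() -> dict[str, dict[str, float]]:
    text = resources.files("ipdbridge.data").joinpath("svo_presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    """Names of the bundled social-value presets."""
    return tuple(_load_presets())


def preset(name: str) -> SVOParams:
    """Return a bundled social-value preset by name.

    Raises
    ------
    KeyError
        If ``name`` is not a known preset; the message lists valid names.
    """
    presets = _load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown SVO preset {name!r}; valid presets: {sorted(presets)}"
        )
    entry = presets[name]
    return SVOParams(
        alpha=float(entry["alpha"]),
        delta=float(entry["delta"]),
        rho=float(entry["rho"]),
        beta=float(entry["beta"]),
        label=name,
    )
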