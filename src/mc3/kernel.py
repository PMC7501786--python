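"""Acceptance rules, in log space.

Three rules cover the whole sampler: the plain Metropolis-Hastings
ratio, its heated form (the posterior ratio raised to the chain's
temperature scaler ``beta``; the Hastings factor is never heated), and
the inter-chain swap ratio.  Real posteriors under- and overflow the
printed ratios, so everything is computed and compared in logs; a move
is accepted when ``log(u) < value`` for ``u ~ Uniform(0, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PosteriorEvaluation",
    "mh_log_accept",
    "heated_log_accept",
    "swap_log_accept",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class PosteriorEvaluation:
    """Cached log-likelihood and log-prior of one state."""

    log_likelihood: float
    log_prior: float

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior


def mh_log_accept(log_post_new: float, log_post_old: float, log_hastings: float = 0.0) -> float:
    """Log Metropolis-Hastings acceptance probability (always <= 0)."""
    if log_post_old == _NEG_INF:
        raise ValueError("current state has zero posterior probability; "
                         "chains must be initialized in the support")
    if log_post_new == _NEG_INF:
        return _NEG_INF
    return min(0.0, (log_post_new - log_post_old) + log_hastings)


def heated_log_accept(
    log_post_new: float,
    log_post_old: float,
    log_hastings: float,
    beta: float,
) -> float:
    """Heated acceptance: the posterior ratio is raised to ``beta``, the
    proposal (Hastings) ratio is not.  ``beta = 1`` recovers plain MH."""
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta!r}")
    if log_post_old == _NEG_INF:
        raise ValueError("current state has zero posterior probability; "
                         "chains must be initialized in the support")
    if log_post_new == _NEG_INF:
        return _NEG_INF
    return min(0.0, beta * (log_post_new - log_post_old) + log_hastings)


def swap_log_accept(
    log_post_i: float,
    log_post_j: float,
    beta_i: float,
    beta_j: float,
) -> float:
    """Log acceptance of exchanging the states of two chains.

    This is the log of
    ``P(x_i|D)^beta_j P(x_j|D)^beta_i / (P(x_i|D)^beta_i P(x_j|D)^beta_j)``
    which collapses to ``(beta_i - beta_j) * (log_post_j - log_post_i)``;
    the expression is symmetric in the labelling of the pair.
    """
    if log_post_i == _NEG_INF or log_post_j == _NEG_INF:
        return _NEG_INF
    value = (beta_i - beta_j) * (log_post_j - log_post_i)
    if math.isnan(value):
        return _NEG_INF
    return min(0.0, value)
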