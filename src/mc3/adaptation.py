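"""Locally aware adaptive tuning of the ladder spacing.

The spacing (``dt`` for the incremental scheme, ``b`` for the
beta-quantile scheme) is nudged after every proposed inter-chain
exchange toward a target swap-acceptance probability::

    spacing_new = max(0, spacing + (p_global - p_target) / n_exchanges)

where ``p_global`` is the accepted fraction over *all* proposed
exchanges since the start of the run and ``n_exchanges`` is their total
count, so individual updates shrink like 1/k and the ladder freezes in
the long run.  Two safety devices temper the early, large-step phase:

* the signed step is clamped to ``max_step`` (default 0.001) per update;
* the update only fires after a burn-in of 100 proposed exchanges, and
  only when the global acceptance and a local acceptance over the last
  100 proposed exchanges sit strictly on the same side of the target
  (the "locally aware" gate), which suppresses over-adaptation while
  the heated chains lag behind their new equilibria.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_TARGET_ACCEPTANCE",
    "AdaptationState",
    "update_spacing",
    "adaptation_gate",
    "record_outcome",
]

#: Optimal acceptance probability for many Metropolis proposals; the
#: default target for the exchange move as well.
DEFAULT_TARGET_ACCEPTANCE = 0.234


def update_spacing(
    current: float,
    p_global: float,
    p_target: float,
    n_exchanges: int,
    max_step: float = 0.001,
) -> float:
    """One clamped spacing update; never negative, never moves more than
    ``max_step`` from ``current``."""
    if n_exchanges < 1:
        raise ValueError("n_exchanges must be >= 1")
    step = (p_global - p_target) / n_exchanges
    step = math.copysign(min(abs(step), max_step), step)
    return max(0.0, current + step)


@dataclass
class AdaptationState:
    """Bookkeeping for the swap-acceptance statistics driving adaptation."""

    p_target: float = DEFAULT_TARGET_ACCEPTANCE
    burn_in: int = 100
    local_window: int = 100
    max_step: float = 0.001
    n_proposed: int = 0
    n_accepted: int = 0
    recent_outcomes: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_target < 1.0:
            raise ValueError("p_target must lie in (0, 1)")
        self.recent_outcomes = deque(self.recent_outcomes, maxlen=self.local_window)

    @property
    def p_global(self) -> float:
        """Accepted fraction over all proposed exchanges since run start."""
        if self.n_proposed == 0:
            return math.nan
        return self.n_accepted / self.n_proposed

    @property
    def p_local(self) -> float:
        """Accepted fraction over the most recent ``local_window`` proposals."""
        if not self.recent_outcomes:
            return math.nan
        return sum(self.recent_outcomes) / len(self.recent_outcomes)

    # -- serialization used by checkpoints -------------------------------
    def to_data(self) -> dict:
        return {
            "p_target": self.p_target,
            "burn_in": self.burn_in,
            "local_window": self.local_window,
            "max_step": self.max_step,
            "n_proposed": self.n_proposed,
            "n_accepted": self.n_accepted,
            "recent_outcomes": [int(x) for x in self.recent_outcomes],
        }

    @classmethod
    def from_data(cls, data: dict) -> "AdaptationState":
        recent = [bool(x) for x in data.pop("recent_outcomes")]
        state = cls(**data)
        state.recent_outcomes.extend(recent)
        return state


def record_outcome(state: AdaptationState, accepted: bool) -> AdaptationState:
    """Record one proposed exchange; evicts the oldest local entry at capacity."""
    state.n_proposed += 1
    if accepted:
        state.n_accepted += 1
    state.recent_outcomes.append(bool(accepted))
    return state


def adaptation_gate(state: AdaptationState) -> bool:
    """True iff past burn-in and global/local acceptance sit strictly on
    the same side of the target.  Ties never fire an update."""
    if state.n_proposed <= state.burn_in or not state.recent_outcomes:
        return False
    pg, pl, pt = state.p_global, state.p_local, state.p_target
    return (pg > pt and pl > pt) or (pg < pt and pl < pt)
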