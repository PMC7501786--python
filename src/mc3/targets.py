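"""Built-in toy targets and generic proposal machinery.

A *target* bundles everything the engine needs to run chains against a
model: log-likelihood and log-prior evaluation, an initial state, the
names and values of logged parameters, and (for checkpointing) a
JSON-able encoding of a state.  Toy targets put their whole log density
in the likelihood term and use a flat prior.

Two toy families are provided:

* :class:`MultivariateNormalTarget` — a d-dimensional standard normal.
  The default dimension is large (3000) so that the log-posterior
  fluctuation scale, and with it the equilibrium ladder spacing of the
  exchange move, resembles that of a real phylogenetic posterior rather
  than a textbook 1-D example (whose swap acceptance cannot even fall
  to 0.234 under random pair selection with four chains).

* :func:`make_island_target` — a 1-D chain of narrow, equally weighted
  modes separated by deep log-density valleys: the canonical caricature
  of "tree islands", where a single cold chain gets stuck in one mode
  while heated chains hop freely.
"""

from __future__ import annotations

import math
from typing import Any, Sequence

import numpy as np

__all__ = [
    "Proposal",
    "GaussianRandomWalkProposal",
    "CoordinateUpdateProposal",
    "Target",
    "MultivariateNormalTarget",
    "IslandMixtureTarget",
    "make_island_target",
]


class Proposal:
    """Base class for within-chain proposals.

    ``propose`` returns ``(new_state, log_hastings)``; ``new_state`` may
    be ``None`` as a rejection sentinel for geometrically invalid moves.
    ``default_scale`` is the tuning scalar carried (and exchanged) with
    the chain's temperature; ``None`` marks the proposal untunable.
    """

    name: str = "proposal"
    default_scale: float | None = None

    def propose(self, state: Any, rng: np.random.Generator, scale: float | None):
        raise NotImplementedError


class GaussianRandomWalkProposal(Proposal):
    """Full-vector (or scalar) Gaussian random walk; symmetric."""

    name = "random_walk"

    def __init__(self, scale: float = 0.5):
        self.default_scale = scale

    def propose(self, state, rng, scale):
        if isinstance(state, float):
            return state + scale * rng.standard_normal(), 0.0
        return state + scale * rng.standard_normal(len(state)), 0.0


class CoordinateUpdateProposal(Proposal):
    """Gaussian update of a contiguous (wrap-around) coordinate block;
    symmetric.

    States are ``(x, sumsq)`` pairs so the spherical-Gaussian target can
    re-evaluate in O(block) instead of O(dim); see
    :class:`MultivariateNormalTarget`.  ``scale`` is the per-coordinate
    standard deviation of the update.
    """

    name = "coordinate_update"

    def __init__(self, scale: float = 2.4, block_size: int = 1):
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        self.default_scale = scale
        self.block_size = block_size

    def propose(self, state, rng, scale):
        x, sumsq = state
        d = len(x)
        b = min(self.block_size, d)
        start = int(rng.integers(d))
        idx = np.arange(start, start + b) % d
        old = x[idx]
        new = old + scale * rng.standard_normal(b)
        x2 = x.copy()
        x2[idx] = new
        return (x2, sumsq + float(new @ new - old @ old)), 0.0


class Target:
    """Interface the engine runs against; see module docstring."""

    param_names: Sequence[str] = ()

    def initial_state(self, rng: np.random.Generator) -> Any:
        raise NotImplementedError

    def log_likelihood(self, state: Any) -> float:
        raise NotImplementedError

    def log_prior(self, state: Any) -> float:
        return 0.0

    def param_values(self, state: Any) -> Sequence[float]:
        raise NotImplementedError

    def default_proposals(self) -> list[tuple[Proposal, float]]:
        raise NotImplementedError

    # -- checkpoint encoding --------------------------------------------
    def state_to_data(self, state: Any) -> Any:
        raise NotImplementedError

    def state_from_data(self, data: Any) -> Any:
        raise NotImplementedError


class MultivariateNormalTarget(Target):
    """Standard normal in ``dim`` dimensions, flat prior.

    The state is a ``(x, sumsq)`` pair with ``sumsq = x . x`` cached so
    that single-coordinate updates evaluate in constant time; the log
    density is ``-sumsq / 2`` up to a constant.  Initial states are
    drawn from the target itself (chains start in the typical set, as a
    well-dispersed initialization would in a real analysis).
    """

    def __init__(self, dim: int = 3000, block_size: int = 25):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.block_size = min(block_size, dim)
        # ~2.4 / sqrt(updated dimensions): the usual random-walk scaling
        self.proposal_scale = 2.4 / math.sqrt(self.block_size)
        self.param_names = ("x0", "radius2")

    def initial_state(self, rng):
        x = rng.standard_normal(self.dim)
        return (x, float(x @ x))

    def log_likelihood(self, state):
        return -0.5 * state[1]

    def param_values(self, state):
        return (float(state[0][0]), float(state[1]))

    def default_proposals(self):
        return [(CoordinateUpdateProposal(self.proposal_scale, self.block_size), 1.0)]

    def state_to_data(self, state):
        x, sumsq = state
        return {"x": [float(v) for v in x], "sumsq": float(sumsq)}

    def state_from_data(self, data):
        x = np.asarray(data["x"], dtype=float)
        return (x, float(data["sumsq"]))


class IslandMixtureTarget(Target):
    """1-D mixture of ``n_islands`` narrow normal modes at unit spacing.

    Mode k sits at ``x = k`` with standard deviation ``sd``; all modes
    carry equal weight, so each holds mass ``1 / n_islands`` by
    symmetry.  Between modes the log density is floored at
    ``barrier_depth`` below the peaks (a smooth log-sum-exp bridge over
    ``[-0.5, n_islands - 0.5]``), so the valley depth separating
    adjacent islands is controlled exactly by one parameter.
    """

    def __init__(self, n_islands: int = 3, barrier_depth: float = 25.0, sd: float = 0.05,
                 start_mode: int | None = None):
        if n_islands < 1:
            raise ValueError("n_islands must be >= 1")
        if barrier_depth <= 0:
            raise ValueError("barrier_depth must be positive")
        if start_mode is not None and not 0 <= start_mode < n_islands:
            raise ValueError("start_mode out of range")
        self.n_islands = n_islands
        self.barrier_depth = barrier_depth
        self.sd = sd
        self.start_mode = start_mode
        self.param_names = ("x",)
        self._centres = tuple(float(k) for k in range(n_islands))
        self._lo = -0.5
        self._hi = n_islands - 0.5

    def initial_state(self, rng):
        # overdispersed starts: a uniformly chosen mode centre unless pinned
        if self.start_mode is not None:
            return float(self.start_mode)
        return float(rng.integers(self.n_islands))

    def log_likelihood(self, state):
        x = state
        inv2s2 = 0.5 / (self.sd * self.sd)
        best = -math.inf
        terms = []
        for c in self._centres:
            d = x - c
            terms.append(-d * d * inv2s2)
        if self._lo <= x <= self._hi:
            terms.append(-self.barrier_depth)
        m = max(terms)
        if m == -math.inf:
            return -math.inf
        return m + math.log(sum(math.exp(t - m) for t in terms))

    def param_values(self, state):
        return (float(state),)

    def mode_index(self, x: float) -> int:
        """Nearest-mode assignment used for occupancy statistics."""
        return int(min(range(self.n_islands), key=lambda k: abs(x - k)))

    def default_proposals(self):
        # Small steps relative to the inter-mode distance: a single cold
        # chain cannot cross the valleys by local moves.
        return [(GaussianRandomWalkProposal(0.1), 1.0)]

    def state_to_data(self, state):
        return float(state)

    def state_from_data(self, data):
        return float(data)


def make_island_target(n_islands: int = 3, barrier_depth: float = 25.0) -> IslandMixtureTarget:
    """Convenience constructor for the island toy target."""
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    return IslandMixtureTarget(n_islands=n_islands, barrier_depth=barrier_depth)
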