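"""The Metropolis-coupled MCMC engine.

``n`` chains advance independently between scheduled swap points, each
running plain Metropolis-Hastings against the posterior heated by the
``beta`` of its current temperature rank.  Every ``swap_interval``
iterations one pair of temperature ranks is drawn (uniformly over all
pairs, or over adjacent ranks in neighbour mode) and an exchange of the
two chains' states is proposed.  An accepted exchange swaps the chains'
*temperatures* — their rank labels, operator tuning and logger bindings
— rather than the states themselves, so arbitrarily large states never
move.  After every proposed exchange the ladder spacing is (optionally)
adapted toward the target swap-acceptance probability and the new
temperatures apply to all chains simultaneously.

Reproducibility contract: one master seed spawns a dedicated RNG stream
per chain plus one scheduler stream (pair choice) and one swap-decision
stream.  Chains therefore do not interact between swap points, a run of
``n_chains = 1`` is byte-identical to plain MCMC with the same seed, and
a checkpointed run resumes bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Callable, Sequence

import numpy as np

from .adaptation import AdaptationState, adaptation_gate, record_outcome, update_spacing
from .kernel import swap_log_accept
from .ladder import LADDER_SCHEMES, TemperatureLadder
from .targets import Proposal, Target

__all__ = [
    "RunConfig",
    "ChainState",
    "SwapEvent",
    "RunResult",
    "MC3Engine",
    "run_mc3",
    "run_mcmc",
    "propose_swap_pair",
    "perform_swap",
    "CheckpointError",
]

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    """Raised for unreadable, corrupt or version-incompatible checkpoints."""


@dataclass
class RunConfig:
    """Run configuration; mirrors the flat key/value config file of the CLI."""

    n_chains: int = 4
    chain_length: int = 100_000
    swap_interval: int = 100
    target_acceptance: float = 0.234
    ladder_scheme: str = "incremental"
    initial_spacing: float = 0.01
    swap_mode: str = "random"  # or "neighbour"
    log_every: int | None = None  # default: swap_interval
    adaptive: bool = True
    burn_in_exchanges: int = 100
    local_window: int = 100
    max_step: float = 0.001
    heated_chain_logging: bool = False
    tune_operators: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.swap_interval < 1:
            raise ValueError("swap_interval must be >= 1")
        if self.chain_length % self.swap_interval != 0:
            raise ValueError("chain_length must be a multiple of swap_interval")
        if self.swap_mode not in ("random", "neighbour"):
            raise ValueError(f"unknown swap mode {self.swap_mode!r}")
        if self.ladder_scheme not in LADDER_SCHEMES:
            raise ValueError(f"unknown ladder scheme {self.ladder_scheme!r}")
        if self.log_every is None:
            self.log_every = self.swap_interval
        if self.log_every < 1:
            raise ValueError("log_every must be >= 1")


@dataclass
class ChainState:
    """One chain: its model state, cached evaluation and temperature rank.

    ``temperature_rank`` indexes the ladder (rank 1 = cold) and doubles
    as the logger binding: a chain always writes to the trace of its
    *current* rank, so each log file stays at a fixed temperature.
    """

    chain_id: int
    state: Any
    log_likelihood: float
    log_prior: float
    temperature_rank: int
    operator_tuning: list[float | None]
    n_proposed: int = 0
    n_accepted: int = 0

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    @property
    def logger_binding(self) -> int:
        return self.temperature_rank


@dataclass(frozen=True)
class SwapEvent:
    iteration: int
    pair: tuple[int, int]  # temperature ranks, 1-based
    log_accept: float
    accepted: bool


@dataclass
class RunResult:
    """Everything a finished (segment of a) run produced.

    ``traces[r]`` maps column name -> list of logged values for
    temperature rank ``r + 1``; rank 1 is the posterior sample.  Heated
    ranks are only populated when heated-chain logging is enabled.
    ``snapshots`` holds opaque per-rank state snapshots (e.g. trees)
    when the target provides a ``snapshot`` method.
    """

    config: RunConfig
    seed: int
    traces: list[dict[str, list[float]]]
    snapshots: list[list[Any]]
    swap_events: list[SwapEvent]
    adaptation_trace: list[tuple[int, float, float, float, bool]]
    final_spacing: float
    ladder: TemperatureLadder
    n_swaps_proposed: int
    n_swaps_accepted: int

    @property
    def cold_trace(self) -> dict[str, list[float]]:
        return self.traces[0]

    @property
    def swap_acceptance(self) -> float:
        """Realized global swap acceptance over all proposed exchanges."""
        if self.n_swaps_proposed == 0:
            return math.nan
        return self.n_swaps_accepted / self.n_swaps_proposed


def propose_swap_pair(n_chains: int, mode: str, rng: np.random.Generator) -> tuple[int, int]:
    """Draw the pair of temperature ranks (1-based) for one exchange.

    ``random``: uniform over all C(n, 2) unordered pairs.
    ``neighbour``: uniform over the n - 1 adjacent-rank pairs.
    """
    if n_chains < 2:
        raise ValueError("swaps need at least two chains")
    if mode == "random":
        a = int(rng.integers(n_chains))
        b = int(rng.integers(n_chains - 1))
        if b >= a:
            b += 1
        lo, hi = (a, b) if a < b else (b, a)
        return lo + 1, hi + 1
    if mode == "neighbour":
        a = int(rng.integers(n_chains - 1))
        return a + 1, a + 2
    raise ValueError(f"unknown swap mode {mode!r}")


def perform_swap(chain_a: ChainState, chain_b: ChainState) -> tuple[ChainState, ChainState]:
    """Exchange temperatures (ranks), operator tuning and logger bindings.

    States and cached evaluations stay put — exchanging the small label
    is equivalent to exchanging the possibly huge states.
    """
    if chain_a.chain_id == chain_b.chain_id:
        raise ValueError("cannot swap a chain with itself")
    chain_a.temperature_rank, chain_b.temperature_rank = (
        chain_b.temperature_rank,
        chain_a.temperature_rank,
    )
    chain_a.operator_tuning, chain_b.operator_tuning = (
        chain_b.operator_tuning,
        chain_a.operator_tuning,
    )
    return chain_a, chain_b


def _spawn_rngs(seed: int, n_chains: int) -> tuple[list, Any, Any]:
    children = np.random.SeedSequence(seed).spawn(n_chains + 2)
    chain_rngs = [np.random.Generator(np.random.PCG64(s)) for s in children[:n_chains]]
    scheduler = np.random.Generator(np.random.PCG64(children[n_chains]))
    swap_decision = np.random.Generator(np.random.PCG64(children[n_chains + 1]))
    return chain_rngs, scheduler, swap_decision


class MC3Engine:
    """Stateful engine; create, ``run(n)``, inspect ``result()``, checkpoint."""

    def __init__(
        self,
        target: Target,
        config: RunConfig | None = None,
        proposals: Sequence[tuple[Proposal, float]] | None = None,
        seed: int = 0,
        row_sink: Callable[[int, int, Sequence[float]], None] | None = None,
        _defer_init: bool = False,
    ):
        self.target = target
        self.config = config or RunConfig()
        self.seed = seed
        self.row_sink = row_sink
        props = list(proposals) if proposals is not None else target.default_proposals()
        if not props:
            raise ValueError("at least one proposal is required")
        self.proposals = [p for p, _ in props]
        weights = np.asarray([w for _, w in props], dtype=float)
        if np.any(weights <= 0):
            raise ValueError("proposal weights must be positive")
        self._cum_weights = np.cumsum(weights / weights.sum())
        self._columns = ["Sample", "posterior", "likelihood", "prior", *target.param_names]

        cfg = self.config
        self.adaptation = AdaptationState(
            p_target=cfg.target_acceptance,
            burn_in=cfg.burn_in_exchanges,
            local_window=cfg.local_window,
            max_step=cfg.max_step,
        )
        self.ladder = TemperatureLadder(cfg.n_chains, cfg.ladder_scheme, cfg.initial_spacing)
        self.iteration = 0
        self.swap_events: list[SwapEvent] = []
        self.adaptation_trace: list[tuple[int, float, float, float, bool]] = []
        self._traces: list[dict[str, list[float]]] = [
            {c: [] for c in self._columns} for _ in range(cfg.n_chains)
        ]
        self._snapshots: list[list[Any]] = [[] for _ in range(cfg.n_chains)]
        if _defer_init:
            return
        self._rngs, self._scheduler_rng, self._swap_rng = _spawn_rngs(seed, cfg.n_chains)
        self.chains = []
        for cid in range(1, cfg.n_chains + 1):
            state = target.initial_state(self._rngs[cid - 1])
            ll = target.log_likelihood(state)
            lp = target.log_prior(state)
            if not (ll > -math.inf and lp > -math.inf):
                raise ValueError("initial state has zero posterior probability")
            self.chains.append(
                ChainState(
                    chain_id=cid,
                    state=state,
                    log_likelihood=ll,
                    log_prior=lp,
                    temperature_rank=cid,
                    operator_tuning=[p.default_scale for p in self.proposals],
                )
            )
        self._log_all()  # iteration 0

    # -- logging ---------------------------------------------------------

    def _logged_ranks(self) -> range:
        return range(1, self.config.n_chains + 1) if self.config.heated_chain_logging else range(1, 2)

    def _log_all(self) -> None:
        logged = self._logged_ranks()
        for ch in self.chains:
            rank = ch.temperature_rank
            if rank not in logged:
                continue
            row = (
                float(self.iteration),
                ch.log_posterior,
                ch.log_likelihood,
                ch.log_prior,
                *self.target.param_values(ch.state),
            )
            trace = self._traces[rank - 1]
            for col, val in zip(self._columns, row):
                trace[col].append(val)
            if self.row_sink is not None:
                self.row_sink(rank, self.iteration, row)
            snap = getattr(self.target, "snapshot", None)
            if snap is not None:
                self._snapshots[rank - 1].append(snap(ch.state))

    # -- within-chain advancement ---------------------------------------

    def _advance_chain(self, ch: ChainState, n_steps: int) -> None:
        target = self.target
        rng = self._rngs[ch.chain_id - 1]
        beta = float(self.ladder.betas[ch.temperature_rank - 1])
        proposals = self.proposals
        single = len(proposals) == 1
        cum = self._cum_weights
        log = math.log
        state, ll, lp = ch.state, ch.log_likelihood, ch.log_prior
        post = ll + lp
        rnd = rng.random
        for _ in range(n_steps):
            if single:
                idx = 0
            else:
                idx = int(np.searchsorted(cum, rnd(), side="left"))
            prop = proposals[idx]
            new_state, log_h = prop.propose(state, rng, ch.operator_tuning[idx])
            ch.n_proposed += 1
            if new_state is None:
                continue
            nll = target.log_likelihood(new_state)
            nlp = target.log_prior(new_state)
            npost = nll + nlp
            if npost == -math.inf or math.isnan(npost):
                continue
            la = beta * (npost - post) + log_h
            if la >= 0.0 or log(rnd()) < la:
                state, ll, lp, post = new_state, nll, nlp, npost
                ch.n_accepted += 1
        ch.state, ch.log_likelihood, ch.log_prior = state, ll, lp

    # -- the main loop ---------------------------------------------------

    def run(self, n_iterations: int | None = None) -> "MC3Engine":
        """Advance all chains ``n_iterations`` further (default: one
        ``chain_length``).  Must be a multiple of the swap interval."""
        cfg = self.config
        if n_iterations is None:
            n_iterations = cfg.chain_length
        if n_iterations % cfg.swap_interval != 0:
            raise ValueError("n_iterations must be a multiple of swap_interval")
        interval = cfg.swap_interval
        log_every = cfg.log_every
        end = self.iteration + n_iterations
        while self.iteration < end:
            sub = math.gcd(interval, log_every)
            block_end = self.iteration + interval
            while self.iteration < block_end:
                for ch in self.chains:
                    self._advance_chain(ch, sub)
                self.iteration += sub
                if self.iteration % log_every == 0:
                    self._log_all()
            if cfg.n_chains >= 2:
                self._swap_step()
            if cfg.tune_operators:
                self._tune_operators()
        return self

    def _swap_step(self) -> None:
        cfg = self.config
        ra, rb = propose_swap_pair(cfg.n_chains, cfg.swap_mode, self._scheduler_rng)
        by_rank = {ch.temperature_rank: ch for ch in self.chains}
        ca, cb = by_rank[ra], by_rank[rb]
        betas = self.ladder.betas
        la = swap_log_accept(
            ca.log_posterior, cb.log_posterior, float(betas[ra - 1]), float(betas[rb - 1])
        )
        u = self._swap_rng.random()
        accepted = bool(la >= 0.0 or (u > 0.0 and math.log(u) < la))
        if accepted:
            perform_swap(ca, cb)
        self.swap_events.append(SwapEvent(self.iteration, (ra, rb), la, accepted))
        record_outcome(self.adaptation, accepted)
        ad = self.adaptation
        gate = bool(cfg.adaptive and adaptation_gate(ad))
        if gate:
            new_spacing = update_spacing(
                self.ladder.spacing, ad.p_global, ad.p_target, ad.n_proposed, ad.max_step
            )
            # applied simultaneously to all chains, not just the swapped pair
            self.ladder = self.ladder.with_spacing(new_spacing)
        self.adaptation_trace.append(
            (ad.n_proposed, self.ladder.spacing, ad.p_global, ad.p_local, gate)
        )

    def _tune_operators(self) -> None:
        """Minimal acceptance-window rescaling of tunable proposal scales.

        Chains tuned at different temperatures keep their scales bound to
        the temperature rank (tuning is exchanged on accepted swaps).
        """
        for ch in self.chains:
            if ch.n_proposed < 100:
                continue
            rate = ch.n_accepted / ch.n_proposed
            factor = math.exp(0.1 * (rate - 0.234))
            ch.operator_tuning = [
                None if s is None else s * factor for s in ch.operator_tuning
            ]
            ch.n_proposed = ch.n_accepted = 0

    # -- results ---------------------------------------------------------

    def result(self) -> RunResult:
        ad = self.adaptation
        return RunResult(
            config=self.config,
            seed=self.seed,
            traces=self._traces,
            snapshots=self._snapshots,
            swap_events=self.swap_events,
            adaptation_trace=self.adaptation_trace,
            final_spacing=self.ladder.spacing,
            ladder=self.ladder,
            n_swaps_proposed=ad.n_proposed,
            n_swaps_accepted=ad.n_accepted,
        )

    # -- checkpointing ---------------------------------------------------

    def checkpoint_data(self) -> dict:
        return {
            "version": CHECKPOINT_VERSION,
            "seed": self.seed,
            "iteration": self.iteration,
            "config": asdict(self.config),
            "spacing": self.ladder.spacing,
            "adaptation": self.adaptation.to_data(),
            "chains": [
                {
                    "chain_id": ch.chain_id,
                    "temperature_rank": ch.temperature_rank,
                    "operator_tuning": ch.operator_tuning,
                    "state": self.target.state_to_data(ch.state),
                    "log_likelihood": ch.log_likelihood,
                    "log_prior": ch.log_prior,
                    "n_proposed": ch.n_proposed,
                    "n_accepted": ch.n_accepted,
                    "rng": self._rngs[ch.chain_id - 1].bit_generator.state,
                }
                for ch in self.chains
            ],
            "scheduler_rng": self._scheduler_rng.bit_generator.state,
            "swap_rng": self._swap_rng.bit_generator.state,
        }

    def write_checkpoint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.checkpoint_data(), fh)

    @classmethod
    def resume(
        cls,
        path,
        target: Target,
        proposals: Sequence[tuple[Proposal, float]] | None = None,
        row_sink: Callable[[int, int, Sequence[float]], None] | None = None,
    ) -> "MC3Engine":
        """Rebuild an engine bit-exactly from a checkpoint file.

        The run continues from the checkpointed iteration; already-logged
        rows are not re-emitted.
        """
        try:
            with open(path) as fh:
                data = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        version = data.get("version")
        if version != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"checkpoint version {version!r} not supported "
                f"(expected {CHECKPOINT_VERSION})"
            )
        try:
            config = RunConfig(**data["config"])
            eng = cls(
                target,
                config,
                proposals,
                seed=data["seed"],
                row_sink=row_sink,
                _defer_init=True,
            )
            eng.iteration = data["iteration"]
            eng.ladder = TemperatureLadder(
                config.n_chains, config.ladder_scheme, data["spacing"]
            )
            eng.adaptation = AdaptationState.from_data(data["adaptation"])
            eng.chains = []
            eng._rngs = []
            for cd in data["chains"]:
                rng = np.random.Generator(np.random.PCG64())
                rng.bit_generator.state = cd["rng"]
                eng._rngs.append(rng)
                eng.chains.append(
                    ChainState(
                        chain_id=cd["chain_id"],
                        state=target.state_from_data(cd["state"]),
                        log_likelihood=cd["log_likelihood"],
                        log_prior=cd["log_prior"],
                        temperature_rank=cd["temperature_rank"],
                        operator_tuning=cd["operator_tuning"],
                        n_proposed=cd["n_proposed"],
                        n_accepted=cd["n_accepted"],
                    )
                )
            eng._scheduler_rng = np.random.Generator(np.random.PCG64())
            eng._scheduler_rng.bit_generator.state = data["scheduler_rng"]
            eng._swap_rng = np.random.Generator(np.random.PCG64())
            eng._swap_rng.bit_generator.state = data["swap_rng"]
        except (KeyError, TypeError, ValueError) as exc:
            raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
        return eng


def run_mc3(
    target: Target,
    config: RunConfig | None = None,
    proposals: Sequence[tuple[Proposal, float]] | None = None,
    seed: int = 0,
    row_sink: Callable[[int, int, Sequence[float]], None] | None = None,
) -> RunResult:
    """Run a full Metropolis-coupled MCMC analysis and return its result."""
    eng = MC3Engine(target, config, proposals, seed=seed, row_sink=row_sink)
    eng.run()
    return eng.result()


def run_mcmc(
    target: Target,
    chain_length: int = 100_000,
    proposals: Sequence[tuple[Proposal, float]] | None = None,
    seed: int = 0,
    log_every: int = 100,
) -> RunResult:
    """Plain single-chain MCMC, written as its own minimal loop.

    Uses the same seed-spawning convention as the engine (the chain
    stream is child 0 of the master seed), so an ``n_chains = 1`` MC3
    run with the same seed and cadence produces byte-identical output —
    degenerate Metropolis coupling *is* plain MCMC.
    """
    props = list(proposals) if proposals is not None else target.default_proposals()
    proposal_objs = [p for p, _ in props]
    weights = np.asarray([w for _, w in props], dtype=float)
    cum = np.cumsum(weights / weights.sum())
    rngs, _, _ = _spawn_rngs(seed, 1)
    rng = rngs[0]
    scales = [p.default_scale for p in proposal_objs]

    state = target.initial_state(rng)
    ll = target.log_likelihood(state)
    lp = target.log_prior(state)
    if not (ll > -math.inf and lp > -math.inf):
        raise ValueError("initial state has zero posterior probability")

    columns = ["Sample", "posterior", "likelihood", "prior", *target.param_names]
    trace: dict[str, list[float]] = {c: [] for c in columns}
    snapshots: list[Any] = []
    snap = getattr(target, "snapshot", None)

    def log_row(it: int) -> None:
        row = (float(it), ll + lp, ll, lp, *target.param_values(state))
        for c, v in zip(columns, row):
            trace[c].append(v)
        if snap is not None:
            snapshots.append(snap(state))

    log_row(0)
    post = ll + lp
    for it in range(1, chain_length + 1):
        idx = 0 if len(proposal_objs) == 1 else int(np.searchsorted(cum, rng.random(), side="left"))
        new_state, log_h = proposal_objs[idx].propose(state, rng, scales[idx])
        if new_state is not None:
            nll = target.log_likelihood(new_state)
            nlp = target.log_prior(new_state)
            npost = nll + nlp
            if not (npost == -math.inf or math.isnan(npost)):
                la = (npost - post) + log_h
                if la >= 0.0 or math.log(rng.random()) < la:
                    state, ll, lp, post = new_state, nll, nlp, npost
        if it % log_every == 0:
            log_row(it)

    cfg = RunConfig(
        n_chains=1,
        chain_length=chain_length,
        swap_interval=log_every,
        log_every=log_every,
        adaptive=False,
    )
    return RunResult(
        config=cfg,
        seed=seed,
        traces=[trace],
        snapshots=[snapshots],
        swap_events=[],
        adaptation_trace=[],
        final_spacing=cfg.initial_spacing,
        ladder=TemperatureLadder(1, cfg.ladder_scheme, cfg.initial_spacing),
        n_swaps_proposed=0,
        n_swaps_accepted=0,
    )
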