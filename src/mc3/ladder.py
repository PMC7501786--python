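"""Temperature ladders for Metropolis-coupled MCMC.

A ladder assigns every chain ``i = 1..n`` a temperature scaler
``beta_i`` in ``(0, 1]`` with ``beta_1 = 1`` (the cold chain, which
samples the unheated posterior).  Both schemes are generated by a single
non-negative spacing parameter so that run-time adaptation only ever has
one scalar to tune:

* ``incremental``:  ``beta_i = 1 / (1 + (i - 1) * dt)``
* ``beta_quantile``: ``beta_i = 1 - F((i - 1) / n)`` where ``F`` is the
  Beta(1, b) cumulative distribution function, i.e.
  ``beta_i = (1 - (i - 1) / n) ** b`` in closed form.

The beta-quantile scheme divides by ``n`` (not ``n - 1``), so the
hottest chain keeps ``beta_n = (1 / n) ** b > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "incremental_betas",
    "beta_quantile_betas",
    "TemperatureLadder",
    "LADDER_SCHEMES",
]


def _check_args(n_chains: int, spacing: float) -> None:
    if int(n_chains) != n_chains or n_chains < 1:
        raise ValueError(f"n_chains must be a positive integer, got {n_chains!r}")
    if not np.isfinite(spacing) or spacing < 0:
        raise ValueError(f"spacing must be a finite non-negative real, got {spacing!r}")


def incremental_betas(n_chains: int, delta_t: float) -> np.ndarray:
    """Incremental-heating ladder ``beta_i = 1 / (1 + (i - 1) * delta_t)``."""
    _check_args(n_chains, delta_t)
    i = np.arange(n_chains, dtype=float)
    return 1.0 / (1.0 + i * delta_t)


def beta_quantile_betas(n_chains: int, b: float) -> np.ndarray:
    """Beta(1, b)-quantile ladder ``beta_i = (1 - (i - 1) / n) ** b``."""
    _check_args(n_chains, b)
    i = np.arange(n_chains, dtype=float)
    return (1.0 - i / n_chains) ** b


LADDER_SCHEMES = {
    "incremental": incremental_betas,
    "beta_quantile": beta_quantile_betas,
}


@dataclass(frozen=True)
class TemperatureLadder:
    """An ordered vector of chain temperatures and its generating spacing.

    ``betas[0]`` is the cold chain and equals 1 exactly under both
    schemes; the vector is non-increasing and strictly decreasing for
    ``spacing > 0``.
    """

    n_chains: int
    scheme: str = "incremental"
    spacing: float = 0.01
    betas: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        try:
            fn = LADDER_SCHEMES[self.scheme]
        except KeyError:
            raise ValueError(
                f"unknown ladder scheme {self.scheme!r}; "
                f"expected one of {sorted(LADDER_SCHEMES)}"
            ) from None
        object.__setattr__(self, "betas", fn(self.n_chains, self.spacing))

    def with_spacing(self, spacing: float) -> "TemperatureLadder":
        """Return the same ladder re-parameterized at a new spacing."""
        return TemperatureLadder(self.n_chains, self.scheme, spacing)
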