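"""Convergence and comparison statistics for trace and tree samples.

Covers the three quantities used to evaluate the sampler: effective
sample size (ESS) from the integrated autocorrelation time, the
two-sample Kolmogorov-Smirnov distance between empirical distribution
functions, and posterior clade-support tables with their maximal
between-run difference.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "effective_sample_size",
    "ks_distance",
    "ks_critical_value",
    "clade_frequencies",
    "max_clade_support_difference",
    "reference_clade_table",
    "discard_burn_in",
]

#: Default fraction of each trace discarded before ESS/KS computations.
DEFAULT_BURN_IN_FRACTION = 0.1


def discard_burn_in(values: Sequence[float], fraction: float = DEFAULT_BURN_IN_FRACTION):
    """Drop the first ``fraction`` of a trace."""
    values = np.asarray(values, dtype=float)
    return values[int(len(values) * fraction):]


def effective_sample_size(values: Sequence[float]) -> float:
    """ESS via Geyer's initial-positive-sequence truncation.

    ``N / (1 + 2 sum rho_k)`` with the autocorrelation sum cut before the
    first adjacent-lag pair whose sum is non-positive.  Returns ``nan``
    for a constant trace (autocorrelation undefined), and is clipped to
    ``(0, N]``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        return math.nan
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]

    tau = 0.0
    t = 0
    while 2 * t + 1 < n:
        gamma = rho[2 * t] + rho[2 * t + 1]
        if gamma <= 0.0:
            break
        tau += gamma
        t += 1
    tau = 2.0 * tau - 1.0  # = 1 + 2 sum_{k>=1} rho_k over the kept window
    if tau <= 0.0:
        return float(n)
    return float(min(n / tau, n))


def ks_distance(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Supremum distance between the two empirical CDFs."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())


def ks_critical_value(n: int, m: int, alpha: float = 0.01) -> float:
    """Asymptotic two-sample rejection threshold at level ``alpha``."""
    c = math.sqrt(-0.5 * math.log(alpha / 2.0))
    return c * math.sqrt((n + m) / (n * m))


def clade_frequencies(trees: Iterable) -> dict[frozenset, float]:
    """Fraction of sampled trees containing each rooted clade
    (descendant-taxon set)."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree sample")
    taxa = set(trees[0].taxa)
    counts: dict[frozenset, int] = {}
    for tree in trees:
        if set(tree.taxa) != taxa:
            raise ValueError("all trees must share one taxon set")
        for clade in tree.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return {clade: c / n for clade, c in counts.items()}


def max_clade_support_difference(
    run: Mapping[frozenset, float],
    reference: Mapping[frozenset, float],
) -> float:
    """Max over the union of clades of |f_run - f_ref|; a clade absent
    from a table has frequency 0."""
    taxa_run = frozenset().union(*run) if run else frozenset()
    taxa_ref = frozenset().union(*reference) if reference else frozenset()
    if taxa_run != taxa_ref:
        raise ValueError("clade tables are over different taxon sets")
    out = 0.0
    for clade in set(run) | set(reference):
        out = max(out, abs(run.get(clade, 0.0) - reference.get(clade, 0.0)))
    return out


def reference_clade_table(
    samples: Sequence[Sequence],
    leave_out: int | None = None,
) -> dict[frozenset, float]:
    """Clade table of the concatenation of replicate tree samples,
    optionally leaving one replicate out of its own reference."""
    pooled = []
    for i, sample in enumerate(samples):
        if leave_out is not None and i == leave_out:
            continue
        pooled.extend(sample)
    return clade_frequencies(pooled)
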