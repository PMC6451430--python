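"""Hypergeometric marker-list enrichment (Paneth-cell marker check).

Given a marker gene list, a differentially expressed gene list and a
background universe, the upper-tail hypergeometric probability
P(X >= k) of drawing at least k = |markers ∩ DE| marked genes in
n = |DE| draws from a universe of N genes containing K markers is
computed by log-space summation of the exact PMF, so p-values at the
1e-57 scale survive without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

from .core_io import logger

__all__ = ["EnrichmentResult", "hypergeom_sf", "hypergeom_logsf",
           "marker_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    overlap_k: int
    markers_K: int
    list_n: int
    universe_N: int
    p_value: float
    log10_p: float


def _check_bounds(k: int, N: int, K: int, n: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N (got k={k}, N={N}, K={K}, n={n})")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n) (got k={k}, N={N}, "
                         f"K={K}, n={n})")


def _log_binom(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_logpmf(k, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for the hypergeometric(N, K, n) distribution."""
    k = np.asarray(k, dtype=float)
    return (_log_binom(float(K), k) + _log_binom(float(N - K), n - k)
            - _log_binom(float(N), float(n)))


def hypergeom_logsf(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k), summed in log space over the upper tail."""
    _check_bounds(k, N, K, n)
    upper = min(K, n)
    if k <= max(0, n - (N - K)):
        return 0.0  # whole support is >= k
    support = np.arange(k, upper + 1)
    return float(logsumexp(hypergeom_logpmf(support, N, K, n)))


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail probability P(X >= k); equals 1 when k = 0."""
    return float(min(1.0, np.exp(hypergeom_logsf(k, N, K, n))))


def marker_enrichment(markers: Iterable[str], de_genes: Iterable[str],
                      universe: Iterable[str]) -> EnrichmentResult:
    """Hypergeometric enrichment of a marker list within a DE gene list.

    Inputs are deduplicated; markers or DE genes absent from the universe
    are logged and excluded, so k, K and n are always counted within the
    universe.  Results are invariant to input ordering and duplication.
    """
    uni = set(universe)
    mk = set(markers)
    de = set(de_genes)
    lost_markers = mk - uni
    if lost_markers:
        logger.warning("enrichment: %d markers absent from universe, "
                       "excluded: %s", len(lost_markers),
                       ", ".join(sorted(lost_markers)[:10]))
    lost_de = de - uni
    if lost_de:
        logger.warning("enrichment: %d DE genes absent from universe, "
                       "excluded", len(lost_de))
    mk &= uni
    de &= uni
    k = len(mk & de)
    K = len(mk)
    n = len(de)
    N = len(uni)
    log_p = hypergeom_logsf(k, N, K, n)
    return EnrichmentResult(
        overlap_k=k, markers_K=K, list_n=n, universe_N=N,
        p_value=float(min(1.0, np.exp(log_p))),
        log10_p=log_p / np.log(10.0))
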