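"""Shared numerics: hypergeometric upper tail and BH adjustment.

The same upper-tail probability

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n)

drives both the term-enrichment P-value (observing at least m source genes
inside a term) and the shared-sponge test (two genes sharing at least x
miRNA regulators).  It is evaluated by summing the upper tail directly in
log space, which avoids the catastrophic cancellation of computing
``1 - cdf`` for small tails.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_tail", "bh_adjust"]


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(m: int, N: int, M: int, n: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(population N, marked M, draws n).

    Parameters follow the enrichment convention: ``N`` annotated genes in
    total, ``M`` of them in the term, ``n`` source genes drawn, ``m``
    observed in the term.  ``m = 0`` gives exactly 1 (the empty sum).
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M <= N and 0 <= n <= N, got N={N}, M={M}, n={n}")
    if m < 0 or m > min(n, M):
        raise ValueError(f"require 0 <= m <= min(n, M), got m={m}, n={n}, M={M}")
    if m == 0:
        return 1.0
    # support of X is [max(0, n-(N-M)), min(n, M)]
    lo = max(m, n - (N - M))
    hi = min(n, M)
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1, dtype=float)
    log_terms = (
        _log_binom(float(M), i)
        + _log_binom(float(N - M), float(n) - i)
        - _log_binom(float(N), float(n))
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q in [p, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
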