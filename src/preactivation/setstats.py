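"""Hypergeometric overlap and enrichment statistics.

The upper tail P(X ≥ k) is computed in log space from log-gamma binomial
coefficients and accumulated with a stable log-sum-exp, so overlaps far in
the tail (p well below 1e-300 on the log scale would underflow; anything
representable as a double is returned accurately) keep full relative
structure down to absolute error ~1e-15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GeneSet

__all__ = [
    "OverlapResult",
    "hypergeom_tail_upper",
    "hypergeom_tail_upper_all",
    "overlap_test",
    "enrichment_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class OverlapResult:
    """Counts and upper-tail probability for a two-set overlap.

    k: observed overlap, K: size of set A, n: size of set B, N: universe
    size.  ``expected`` is K·n/N; ``fold_enrichment`` is k/expected (NaN
    when the expectation is zero); ``p_upper`` is P(X ≥ k) under the
    hypergeometric null.
    """

    k: int
    K: int
    n: int
    N: int
    expected: float
    fold_enrichment: float
    p_upper: float

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "K": self.K,
            "n": self.n,
            "N": self.N,
            "expected": self.expected,
            "fold_enrichment": self.fold_enrichment,
            "p_upper": self.p_upper,
        }


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"set sizes exceed universe: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def hypergeom_tail_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    X counts the overlap when a set of size n is drawn uniformly without
    replacement from a universe of N containing K marked elements.
    """
    _check_counts(k, K, n, N)
    k, K, n, N = int(k), int(K), int(n), int(N)
    k_min = max(0, n - (N - K))  # smallest achievable overlap
    if k <= k_min:
        return 1.0
    k_max = min(K, n)
    i = np.arange(k, k_max + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def hypergeom_tail_upper_all(K: int, n: int, N: int) -> np.ndarray:
    """All upper tails P(X ≥ k) for k = 0..min(K, n) in one pass.

    Same log-space terms as :func:`hypergeom_tail_upper`, accumulated from
    the deep end of the tail with log-add-exp so every entry is as accurate
    as the scalar path.
    """
    _check_counts(0, K, n, N)
    K, n, N = int(K), int(n), int(N)
    k_max = min(K, n)
    i = np.arange(k_max + 1)
    with np.errstate(invalid="ignore"):
        log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    log_terms = np.where(n - i <= N - K, log_terms, -np.inf)
    tails = np.exp(np.logaddexp.accumulate(log_terms[::-1])[::-1])
    k_min = max(0, n - (N - K))
    tails[: k_min + 1] = 1.0
    return np.minimum(tails, 1.0)


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Hypergeometric upper-tail test of the overlap |a ∩ b| in a universe.

    Both sets must be contained in the universe.
    """
    for gs in (a, b):
        stray = gs.members - universe.members
        if stray:
            raise ValueError(
                f"gene set {gs.name!r} has members outside the universe: "
                f"{sorted(stray)[:10]}"
            )
    k = len(a.members & b.members)
    K, n, N = len(a), len(b), len(universe)
    expected = K * n / N if N else float("nan")
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(
        k=k,
        K=K,
        n=n,
        N=N,
        expected=expected,
        fold_enrichment=fold,
        p_upper=hypergeom_tail_upper(k, K, n, N),
    )


def enrichment_test(query: GeneSet, targets: GeneSet, universe: GeneSet) -> OverlapResult:
    """Enrichment of a target list inside a query set (e.g. preactivated
    genes against a transcription-factor direct-target list).

    Identical to :func:`overlap_test` with the query required non-empty.
    """
    query.require_nonempty()
    return overlap_test(query, targets, universe)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (helper; off by default in the
    pipeline, which reports raw hypergeometric tails)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
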