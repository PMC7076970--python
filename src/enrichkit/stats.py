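r"""Exact over-representation tests and multiple-testing correction.

The 2×2 table for one functional term is

===============  ============  ================
\                in term       not in term
===============  ============  ================
query            k             n − k
rest of bg       K − k         N − K − n + k
===============  ============  ================

with n the query size within the background, K the background genes carrying
the term, and N the background size.  Under the null that the query is an
unordered random draw from the background, k follows the hypergeometric
distribution ``Hypergeom(N, K, n)``; the enrichment p-value is the upper tail
``P(X ≥ k)``.  The one-sided (greater) Fisher exact test conditions on the
same margins and is mathematically identical; both are implemented here in
log space (log-gamma binomials combined by log-sum-exp), by two independent
computational routes, so that agreement between them is a meaningful check
rather than a tautology.

Multiple-testing correction implements Bonferroni, Benjamini–Hochberg
step-up ("BH"; "FDR" and "fdr_bh" are accepted aliases, mirroring the common
usage in which fdr names the BH procedure), and Benjamini–Yekutieli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

_ADJUST_ALIASES = {
    "bh": "BH",
    "fdr": "BH",
    "fdr_bh": "BH",
    "by": "BY",
    "fdr_by": "BY",
    "bonferroni": "bonferroni",
}


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of one term's 2×2 table.

    k: query genes annotated to the term; n: query genes in background;
    K: background genes annotated to the term; N: background size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        from .errors import ValidationError

        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got N={self.N}")
        if not 0 <= self.n <= self.N:
            raise ValidationError(f"require 0 <= n <= N, got n={self.n}, N={self.N}")
        if not 0 <= self.K <= self.N:
            raise ValidationError(f"require 0 <= K <= N, got K={self.K}, N={self.N}")
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValidationError(
                f"require 0 <= k <= min(n, K), got k={self.k}, n={self.n}, K={self.K}"
            )
        if self.k < self.n + self.K - self.N:
            raise ValidationError(
                f"require k >= n + K - N, got k={self.k}, n={self.n}, "
                f"K={self.K}, N={self.N}"
            )


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_support(N: int, K: int, n: int) -> np.ndarray:
    """All attainable overlap counts k for parameters (N, K, n)."""
    return np.arange(max(0, n + K - N), min(n, K) + 1)


def hypergeom_sf_all_k(N: int, K: int, n: int) -> np.ndarray:
    """Upper-tail probabilities P(X ≥ k) for every k in the support.

    Vectorized log-space computation: log pmf from log-binomials, tail by a
    reverse cumulative log-sum-exp.  Returned array aligns with
    :func:`hypergeom_support`.
    """
    ks = hypergeom_support(N, K, n)
    logpmf = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
    # reverse cumulative logsumexp
    tail = np.exp(np.logaddexp.accumulate(logpmf[::-1])[::-1])
    return np.minimum(tail, 1.0)


def hypergeom_upper_tail(counts: ContingencyCounts) -> float:
    """P(X ≥ k) for X ~ Hypergeom(N, K, n), computed in log space.

    Exactly 1.0 when k is at (or below) the bottom of the support — in
    particular when k == 0.
    """
    ks = hypergeom_support(counts.N, counts.K, counts.n)
    if counts.k <= ks[0]:
        return 1.0
    tail = hypergeom_sf_all_k(counts.N, counts.K, counts.n)
    return float(tail[counts.k - ks[0]])


def fisher_tail_all_k(N: int, K: int, n: int) -> np.ndarray:
    """One-sided (greater) Fisher exact p for every k in the support.

    Each table probability comes from the margin/cell factorial formula —
    a route independent of the binomial-product form used by
    :func:`hypergeom_sf_all_k` — and the greater-direction tail is a reverse
    cumulative log-sum-exp.  Aligns with :func:`hypergeom_support`.
    """
    ks = hypergeom_support(N, K, n)
    # log P(table) = log margins! - log(N! a! b! c! d!)
    log_margins = (
        gammaln(K + 1) + gammaln(N - K + 1) + gammaln(n + 1) + gammaln(N - n + 1)
    )
    log_cells = (
        gammaln(N + 1)
        + gammaln(ks + 1)
        + gammaln(n - ks + 1)
        + gammaln(K - ks + 1)
        + gammaln(N - K - n + ks + 1)
    )
    tail = np.exp(np.logaddexp.accumulate((log_margins - log_cells)[::-1])[::-1])
    return np.minimum(tail, 1.0)


def fisher_exact_greater(counts: ContingencyCounts) -> float:
    """One-sided (greater) Fisher exact p for the table [[k, n−k], [K−k, N−K−n+k]].

    Sums the conditional probability of every table at least as extreme in
    the greater direction.  Mathematically identical to
    :func:`hypergeom_upper_tail` and agrees with it to floating-point
    accuracy, but computed by an independent route (see
    :func:`fisher_tail_all_k`).
    """
    lo = max(0, counts.n + counts.K - counts.N)
    if counts.k <= lo:
        return 1.0
    tail = fisher_tail_all_k(counts.N, counts.K, counts.n)
    return float(tail[counts.k - lo])


def fold_enrichment(counts: ContingencyCounts) -> float:
    """Observed over expected query proportion: (k/n) / (K/N)."""
    from .errors import ValidationError

    if counts.n < 1 or counts.K < 1:
        raise ValidationError("fold enrichment requires n >= 1 and K >= 1")
    return (counts.k / counts.n) / (counts.K / counts.N)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Adjust a vector of p-values for multiple testing.

    method: "BH" (aliases "fdr", "fdr_bh"), "bonferroni", or "BY".  BH is the
    step-up procedure p(i)·m/i with cumulative-minimum monotonicity and a cap
    at 1, returned in the original order; BY multiplies by the harmonic sum
    c(m) = Σ 1/i.
    """
    from .errors import ValidationError

    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    key = method.strip().lower()
    if key not in _ADJUST_ALIASES:
        raise ValidationError(
            f"unknown adjustment method {method!r}; choose from BH, BY, bonferroni"
        )
    canonical = _ADJUST_ALIASES[key]
    m = p.size
    if canonical == "bonferroni":
        return np.minimum(1.0, m * p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    factor = m / np.arange(1, m + 1)
    if canonical == "BY":
        factor = factor * np.sum(1.0 / np.arange(1, m + 1))
    adjusted = np.minimum.accumulate((ranked * factor)[::-1])[::-1]
    adjusted = np.minimum(1.0, adjusted)
    out = np.empty(m)
    out[order] = adjusted
    return out
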