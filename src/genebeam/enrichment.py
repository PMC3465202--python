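"""Pathway over-representation p-values.

Given a universe of N genes of which M belong to a pathway F, and a
selection of K significant genes of which x land in F, the number of
selected genes in F follows a hypergeometric distribution.  Both tails are
exposed: the lower tail P(X <= x) (the probability of x or fewer hits) and
the upper tail P(X >= x), which is the usual enrichment p-value.  For large
N with M/N fixed the distribution tends to Binomial(K, M/N), giving the
cheaper approximation p = P(Bin(K, M/N) >= x).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["EnrichmentQuery", "hypergeom_p", "binomial_p"]


@dataclass(frozen=True)
class EnrichmentQuery:
    """N genes in the universe, M in the pathway, K selected, x hits."""

    N: int
    M: int
    K: int
    x: int

    def __post_init__(self) -> None:
        if not 0 <= self.M <= self.N:
            raise ValueError("need 0 <= M <= N")
        if not 0 <= self.K <= self.N:
            raise ValueError("need 0 <= K <= N")
        if not 0 <= self.x <= min(self.M, self.K):
            raise ValueError("need 0 <= x <= min(M, K)")


def hypergeom_p(q: EnrichmentQuery, tail: str = "upper") -> float:
    """Exact hypergeometric tail probability.

    ``tail="lower"`` returns P(X <= x) = sum_{i=0..x} C(M,i) C(N-M,K-i)
    / C(N,K); ``tail="upper"`` returns P(X >= x).  Computed in log space by
    scipy, so large universes are safe.
    """
    dist = stats.hypergeom(q.N, q.M, q.K)
    if tail == "lower":
        return float(dist.cdf(q.x))
    if tail == "upper":
        return float(dist.sf(q.x - 1))
    raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")


def binomial_p(q: EnrichmentQuery) -> float:
    """Binomial approximation to the upper-tail enrichment p-value.

    p = 1 - sum_{i=0..x-1} C(K,i) (M/N)^i (1 - M/N)^(K-i), i.e.
    P(Bin(K, M/N) >= x); x = 0 gives 1.
    """
    if q.N == 0:
        raise ValueError("empty gene universe")
    if q.x == 0:
        return 1.0
    return float(stats.binom(q.K, q.M / q.N).sf(q.x - 1))
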