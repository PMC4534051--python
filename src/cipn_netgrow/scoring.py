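"""Over-representation scoring of grown gene networks.

A network of ``n`` genes containing ``n_f`` focus genes is scored against
the null that the network is a uniform random draw of ``n`` genes from the
knowledge base's ``N`` genes, of which ``K`` are focus genes.  The p-value
is the right tail of the hypergeometric distribution,

    p = sum_{k = n_f}^{min(n, K)}  C(K, k) C(N-K, n-k) / C(N, n),

computed exactly with big-integer binomials (no normal approximation, no
underflow: the division happens once, at the end).  The network score is
-log10(p); a score above 5 corresponds to p < 1e-5, the nominal
significance level used when selecting networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .core_analysis import GeneNetwork

__all__ = [
    "ScoredNetwork",
    "network_pvalue",
    "network_score",
    "score_network",
    "filter_significant",
    "DEFAULT_SIGNIFICANCE_P",
]

DEFAULT_SIGNIFICANCE_P = 1e-5


@dataclass
class ScoredNetwork:
    """A grown network with its enrichment p-value and score."""

    network: "GeneNetwork"
    n: int
    n_f: int
    p_value: float
    score: float
    significant: bool

    def __post_init__(self) -> None:
        if self.n_f > self.n:
            raise ValueError("focus count cannot exceed network size")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def network_pvalue(N: int, K: int, n: int, n_f: int) -> float:
    """Exact upper-tail hypergeometric probability of ``n_f`` or more focus
    genes among ``n`` genes drawn from ``N`` with ``K`` focus genes total."""
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= n_f <= min(n, K)):
        raise ValueError(f"need 0 <= n_f <= min(n, K), got n_f={n_f}")
    hi = min(n, K)
    lo = max(n_f, n - (N - K))
    numerator = sum(
        math.comb(K, k) * math.comb(N - K, n - k) for k in range(lo, hi + 1)
    )
    return float(numerator / math.comb(N, n))


def network_score(p: float) -> float:
    """Score = -log10(p); used to rank networks."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    return -math.log10(p)


def score_network(
    network: "GeneNetwork",
    N: int,
    K: int,
    significance_p: float = DEFAULT_SIGNIFICANCE_P,
    count_nongene_nodes: bool = True,
    gene_ids: set[str] | None = None,
) -> ScoredNetwork:
    """Score a grown network against a knowledge base population.

    ``N`` is the number of genes in the knowledge base and ``K`` the number
    of mappable focus genes.  By default every network node counts toward
    the network size ``n`` (published networks include complexes and
    chemicals); with ``count_nongene_nodes=False``, ``gene_ids`` restricts
    ``n`` to gene-kind nodes.
    """
    members = list(network.genes)
    if not count_nongene_nodes:
        if gene_ids is None:
            raise ValueError("gene_ids required when count_nongene_nodes=False")
        members = [g for g in members if g in gene_ids]
    n = len(members)
    n_f = len(set(network.focus_genes) & set(members))
    p = network_pvalue(N, K, min(n, N), min(n_f, min(n, K)))
    return ScoredNetwork(
        network=network,
        n=n,
        n_f=n_f,
        p_value=p,
        score=network_score(p),
        significant=p < significance_p,
    )


def filter_significant(
    nets: list[ScoredNetwork], threshold: float = DEFAULT_SIGNIFICANCE_P
) -> list[ScoredNetwork]:
    """Networks with p < ``threshold``, ordered by descending score."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    keep = [s for s in nets if s.p_value < threshold]
    return sorted(keep, key=lambda s: (-s.score, s.n, _first_gene(s)))


def _first_gene(s: ScoredNetwork) -> str:
    genes = list(s.network.genes)
    return min(genes) if genes else ""
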