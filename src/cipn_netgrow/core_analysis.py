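"""Seed-based gene-network generation.

This is the network-growth procedure behind pathway-tool "core analysis":
starting from a set of focus genes (literature-implicated genes for a
phenotype), grow networks that are as densely connected as possible inside
a global molecular-interaction knowledge base.

The procedure runs in four phases:

1. **Rank.**  Focus genes are ranked by decreasing triangular connectivity
   (number of connected neighbor pairs).  Focus genes with no connections
   at all are excluded and reported.
2. **Seed networks.**  The top-ranked uncovered focus gene becomes a seed;
   the remaining uncovered focus genes inside its neighborhood (one
   connection away) join it.  Repeat until every non-excluded focus gene
   belongs to exactly one seed network.
3. **Merge.**  Seed networks are combined through bridging non-focus genes
   adjacent to at least two networks, best bridge first, where "best"
   maximises specific connectivity with respect to the union of the two
   networks, subject to the maximum network size.
4. **Expand.**  Each network is grown one gene at a time: the outside gene
   with the highest specific connectivity — |neighborhood ∩ network| /
   |neighborhood ∪ network| — joins, until the size cap is reached or no
   candidate overlaps the network.  Because the neighborhood size appears
   in the union, the metric inherently prefers genes with few neighbors,
   so no separate neighbor-count criterion is applied.

Ties are broken lexicographically on molecule id throughout, making the
whole analysis deterministic.  Every admitted gene carries a provenance
record (seed, neighborhood, bridge or expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .knowledge_base import KnowledgeBase, neighborhood, triangular_connectivity
from .literature import FocusGeneSet
from .scoring import (
    DEFAULT_SIGNIFICANCE_P,
    ScoredNetwork,
    score_network,
)

__all__ = [
    "AnalysisConfig",
    "GeneNetwork",
    "FocusRanking",
    "CoreAnalysisResult",
    "AnalysisError",
    "map_focus_genes",
    "rank_focus_genes",
    "grow_seed_network",
    "build_seed_networks",
    "specific_connectivity",
    "merge_networks",
    "expand_network",
    "core_analysis",
]


class AnalysisError(RuntimeError):
    """Raised when an analysis cannot proceed (e.g. no mappable focus genes)."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the network-generation run.

    Defaults follow the published analysis: at most 140 genes per network
    (large enough that one network could hold all focus genes), at most 25
    networks per analysis, significance level 1e-5 (score > 5), and hubs
    defined as genes with at least 15 connections.
    """

    max_network_size: int = 140
    max_networks: int = 25
    significance_p: float = DEFAULT_SIGNIFICANCE_P
    hub_min_connections: int = 15
    tie_break: str = "lexicographic"
    count_nongene_nodes: bool = True
    collapse_parallel_edges: bool = True

    def __post_init__(self) -> None:
        if self.max_network_size < 2:
            raise ValueError("max_network_size must be >= 2")
        if self.max_networks < 1:
            raise ValueError("max_networks must be >= 1")
        if not 0.0 < self.significance_p < 1.0:
            raise ValueError("significance_p must lie in (0, 1)")
        if self.hub_min_connections < 1:
            raise ValueError("hub_min_connections must be >= 1")
        if self.tie_break != "lexicographic":
            raise ValueError("only lexicographic tie-breaking is supported")
        if not self.collapse_parallel_edges:
            raise ValueError(
                "parallel-edge (multiplicity-aware) connectivity is not "
                "supported; all metrics use the collapsed simple view"
            )


@dataclass
class GeneNetwork:
    """A grown network: ordered gene members, owned focus subset, and the
    growth log recording which rule admitted each gene."""

    genes: list[str] = field(default_factory=list)
    focus_genes: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[str, int]] = field(default_factory=dict)
    seed: str | None = None

    def __post_init__(self) -> None:
        if not self.focus_genes <= set(self.genes):
            raise ValueError("focus_genes must be a subset of genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance or gene in self.genes

    def add(self, gene: str, rule: str) -> None:
        if gene in self.genes:
            raise ValueError(f"gene {gene!r} already in network")
        self.provenance[gene] = (rule, len(self.genes))
        self.genes.append(gene)


@dataclass
class FocusRanking:
    """Outcome of focus-gene ranking: analysis order, exclusions, and the
    symbols that could not be mapped onto the knowledge base."""

    ranked: list[str]
    excluded: list[str]
    unmapped: list[str]
    connectivity: dict[str, int]


@dataclass
class CoreAnalysisResult:
    """Scored networks plus the focus-gene accounting of the run."""

    networks: list[ScoredNetwork]
    excluded: list[str]
    unmapped: list[str]
    population_size: int
    focus_population: int

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)


# -- phase 1: ranking ------------------------------------------------------


def map_focus_genes(
    kb: KnowledgeBase, focus: FocusGeneSet | Iterable[str]
) -> tuple[list[str], list[str]]:
    """Map focus symbols onto knowledge-base molecule ids.

    A symbol maps to the molecule whose id equals it, or else to a unique
    molecule displaying that symbol.  Returns (mapped ids, unmapped
    symbols); unmapped symbols are reported, never silently dropped.
    """
    symbols = list(focus.genes) if isinstance(focus, FocusGeneSet) else list(focus)
    by_symbol: dict[str, list[str]] = {}
    for mol in kb.molecules.values():
        by_symbol.setdefault(mol.symbol, []).append(mol.id)
    mapped, unmapped = [], []
    for sym in symbols:
        if sym in kb:
            mapped.append(sym)
        elif len(by_symbol.get(sym, [])) == 1:
            mapped.append(by_symbol[sym][0])
        else:
            unmapped.append(sym)
    return mapped, unmapped


def rank_focus_genes(
    kb: KnowledgeBase, focus: FocusGeneSet | Iterable[str]
) -> FocusRanking:
    """Rank focus genes by decreasing triangular connectivity.

    Ties break lexicographically on molecule id.  Focus genes with no
    connections (degree 0 on the simple view) are placed last and flagged
    excluded: genes so unlikely to have biological relationships with the
    network are left out of the analysis.
    """
    mapped, unmapped = map_focus_genes(kb, focus)
    if not mapped:
        raise AnalysisError("no focus genes could be mapped onto the knowledge base")
    tc = {g: triangular_connectivity(kb, g) for g in mapped}
    connected = [g for g in mapped if kb.degree(g) > 0]
    excluded = sorted(g for g in mapped if kb.degree(g) == 0)
    ranked = sorted(connected, key=lambda g: (-tc[g], g))
    return FocusRanking(
        ranked=ranked + excluded,
        excluded=excluded,
        unmapped=unmapped,
        connectivity=tc,
    )


# -- phase 2: seed networks ------------------------------------------------


def grow_seed_network(
    kb: KnowledgeBase, seed: str, remaining_focus: Iterable[str]
) -> GeneNetwork:
    """Seed network: the seed plus the remaining focus genes exactly one
    connection away from it."""
    net = GeneNetwork(seed=seed)
    net.add(seed, "seed")
    net.focus_genes.add(seed)
    hood = neighborhood(kb, seed)
    for g in sorted(set(remaining_focus) & hood - {seed}):
        net.add(g, "neighborhood")
        net.focus_genes.add(g)
    return net


def build_seed_networks(
    kb: KnowledgeBase, focus: FocusGeneSet | Iterable[str]
) -> tuple[list[GeneNetwork], FocusRanking]:
    """Repeatedly seed from the top-ranked uncovered focus gene until every
    non-excluded focus gene is represented in exactly one network."""
    ranking = rank_focus_genes(kb, focus)
    uncovered = [g for g in ranking.ranked if g not in ranking.excluded]
    networks: list[GeneNetwork] = []
    while uncovered:
        seed = uncovered[0]
        net = grow_seed_network(kb, seed, uncovered[1:])
        networks.append(net)
        uncovered = [g for g in uncovered if g not in net.focus_genes]
    return networks, ranking


# -- specific connectivity -------------------------------------------------


def _sc_fraction(kb: KnowledgeBase, gene: str, network_genes: set[str]) -> Fraction:
    hood = neighborhood(kb, gene)
    inter = len(hood & network_genes)
    union = len(hood) + len(network_genes) - inter
    return Fraction(inter, union)


def specific_connectivity(
    kb: KnowledgeBase, gene: str, network_genes: Iterable[str]
) -> float:
    """|neighborhood(gene) ∩ network| / |neighborhood(gene) ∪ network|.

    The greedy admission score for network expansion: large overlap with
    the existing network and few outside neighbors both raise it.
    """
    genes = set(network_genes)
    if not genes:
        raise ValueError("network_genes must be non-empty")
    return float(_sc_fraction(kb, gene, genes))


# -- phase 3: merging ------------------------------------------------------


def merge_networks(
    kb: KnowledgeBase,
    nets: Sequence[GeneNetwork],
    config: AnalysisConfig = AnalysisConfig(),
    focus_ids: set[str] | None = None,
) -> list[GeneNetwork]:
    """Combine seed networks through bridging non-focus genes.

    While some non-focus gene outside every network is adjacent to at least
    two networks (and the merged size fits the cap), the pair whose bridge
    has the highest specific connectivity with respect to the pair's union
    is merged, the bridge joining with provenance ``bridge``.  Greedy, best
    bridge first, re-evaluated after every merge.
    """
    if focus_ids is None:
        focus_ids = set().union(*(n.focus_genes for n in nets)) if nets else set()
    networks = list(nets)
    adj = kb.simple_graph.adj
    while len(networks) > 1:
        member_sets = [set(n.genes) for n in networks]
        # bridge candidates: non-focus genes touching (adjacent to, or member
        # of) at least two networks; a bridge acquired by an earlier merge may
        # connect its network to a further one
        touched: dict[str, list[int]] = {}
        for i, members in enumerate(member_sets):
            reach: set[str] = set(members)
            for x in members:
                reach.update(adj[x])
            for b in reach - focus_ids:
                touched.setdefault(b, []).append(i)
        best = None  # ((-score, bridge, i, j), bridge, i, j), minimized
        for b in sorted(touched):
            nets_idx = touched[b]
            if len(nets_idx) < 2:
                continue
            for ai in range(len(nets_idx)):
                for bi in range(ai + 1, len(nets_idx)):
                    i, j = nets_idx[ai], nets_idx[bi]
                    union = member_sets[i] | member_sets[j]
                    if len(union | {b}) > config.max_network_size:
                        continue
                    sc = _sc_fraction(kb, b, union)
                    key = (-sc, b, i, j)
                    if best is None or key < best[0]:
                        best = (key, b, i, j)
        if best is None:
            break
        _, bridge, i, j = best
        merged = GeneNetwork(seed=networks[i].seed)
        for g in networks[i].genes:
            merged.add(g, networks[i].provenance[g][0])
        if bridge not in merged.provenance:
            merged.add(bridge, "bridge")
        for g in networks[j].genes:
            if g not in merged.provenance:
                merged.add(g, networks[j].provenance[g][0])
        merged.focus_genes = networks[i].focus_genes | networks[j].focus_genes
        networks = [n for k, n in enumerate(networks) if k not in (i, j)]
        networks.insert(0, merged)
    return networks


# -- phase 4: expansion ----------------------------------------------------


def expand_network(
    kb: KnowledgeBase,
    net: GeneNetwork,
    config: AnalysisConfig = AnalysisConfig(),
) -> GeneNetwork:
    """Greedy expansion to the size cap.

    At each step the outside gene with the highest specific connectivity
    joins (lexicographic tie-break); expansion stops at
    ``config.max_network_size`` genes or when the best candidate scores 0.
    Candidates are all knowledge-base molecules outside the network.
    Scores are compared as exact rationals, so equal ratios tie exactly.
    """
    if len(net) > config.max_network_size:
        raise ValueError("network already exceeds max_network_size")
    adj = kb.simple_graph.adj
    members = set(net.genes)
    # inter[c] = |adj(c) & members| = |neighborhood(c) & members| for c outside
    inter: dict[str, int] = {}
    for x in members:
        for c in adj[x]:
            if c not in members:
                inter[c] = inter.get(c, 0) + 1
    while len(members) < config.max_network_size and inter:
        n_members = len(members)
        best_gene = None
        best_sc = Fraction(0)
        for c in sorted(inter):
            sc = Fraction(inter[c], len(adj[c]) + 1 + n_members - inter[c])
            if sc > best_sc:
                best_sc, best_gene = sc, c
        if best_gene is None:
            break
        net.add(best_gene, "expansion")
        members.add(best_gene)
        del inter[best_gene]
        for c in adj[best_gene]:
            if c not in members:
                inter[c] = inter.get(c, 0) + 1
    return net


# -- full pipeline ---------------------------------------------------------


def core_analysis(
    kb: KnowledgeBase,
    focus: FocusGeneSet | Iterable[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> CoreAnalysisResult:
    """Run the full analysis: rank -> seed networks -> merge -> expand ->
    score -> sort by score -> truncate to ``config.max_networks``.

    The scoring population is the knowledge base's gene-kind molecules
    (size N), of which the mappable focus genes form the success class
    (size K).  Deterministic given knowledge base, focus set and config.
    """
    seed_nets, ranking = build_seed_networks(kb, focus)
    focus_ids = {g for g in ranking.ranked if g not in ranking.excluded}
    merged = merge_networks(kb, seed_nets, config, focus_ids=focus_ids)
    expanded = [expand_network(kb, n, config) for n in merged]

    gene_ids = set(kb.gene_ids())
    N = len(gene_ids) if not config.count_nongene_nodes else len(kb)
    K = len(focus_ids) + len(ranking.excluded)
    scored = [
        score_network(
            n,
            N=N,
            K=K,
            significance_p=config.significance_p,
            count_nongene_nodes=config.count_nongene_nodes,
            gene_ids=gene_ids,
        )
        for n in expanded
    ]
    scored.sort(key=lambda s: (-s.score, -s.n_f, min(s.network.genes)))
    return CoreAnalysisResult(
        networks=scored[: config.max_networks],
        excluded=ranking.excluded,
        unmapped=ranking.unmapped,
        population_size=N,
        focus_population=K,
    )
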