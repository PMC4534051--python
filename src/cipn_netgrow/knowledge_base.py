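"""Typed molecular-interaction knowledge base and connectivity primitives.

The knowledge base is a global graph of molecules (genes, chemicals,
complexes, biological processes, protein families, microRNAs) connected by
typed interactions (activation, binding, inhibition, ...).  All connectivity
metrics used by the network-growth algorithm — neighborhoods, triangular
connectivity, induced subgraphs — operate on the *undirected simple view* of
this graph: parallel edges between the same pair of molecules collapse to a
single adjacency and self-loops are dropped.  Relation types and direct/
indirect flags are retained on the interactions for reporting and export,
but do not influence connectivity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "MOLECULE_KINDS",
    "RELATION_TYPES",
    "Molecule",
    "Interaction",
    "KnowledgeBase",
    "KBFormatError",
    "KBIntegrityError",
    "load_kb",
    "save_kb",
    "neighborhood",
    "triangular_connectivity",
    "induced_network",
]

#: Closed vocabulary of node kinds appearing in pathway-analysis networks.
MOLECULE_KINDS = frozenset(
    {"gene", "chemical", "complex", "process", "protein-family", "microRNA"}
)

#: Closed vocabulary of edge (relationship) types.
RELATION_TYPES = frozenset(
    {
        "activation",
        "binding",
        "causation",
        "chemical-chemical interaction",
        "expression",
        "enzyme catalysis",
        "inhibition",
        "biochemical modification",
        "protein-protein binding",
        "transcription",
    }
)


class KBFormatError(ValueError):
    """Raised when a knowledge-base file cannot be parsed."""


class KBIntegrityError(ValueError):
    """Raised when knowledge-base invariants are violated (dangling edges,
    duplicate ids, unknown vocabulary values)."""


@dataclass(frozen=True)
class Molecule:
    """A node of the knowledge base.

    Identity is the ``id`` string (case-sensitive); ``symbol`` is display
    only.  ``is_focus`` marks membership in the focus-gene set of a given
    analysis and is set per analysis, not per knowledge base.
    """

    id: str
    symbol: str | None = None
    molecule_kind: str = "gene"
    is_focus: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise KBIntegrityError("molecule id must be a non-empty string")
        if self.molecule_kind not in MOLECULE_KINDS:
            raise KBIntegrityError(
                f"unknown molecule kind {self.molecule_kind!r}; "
                f"expected one of {sorted(MOLECULE_KINDS)}"
            )
        if self.symbol is None:
            object.__setattr__(self, "symbol", self.id)


@dataclass(frozen=True)
class Interaction:
    """A typed edge of the knowledge base.

    ``direct`` distinguishes direct (solid) from indirect (dashed)
    relationships in the conventional network rendering.
    """

    source: str
    target: str
    relation: str
    direct: bool = True

    def __post_init__(self) -> None:
        if self.relation not in RELATION_TYPES:
            raise KBIntegrityError(
                f"unknown relation type {self.relation!r}; "
                f"expected one of {sorted(RELATION_TYPES)}"
            )


class KnowledgeBase:
    """A molecular-interaction graph with typed edges.

    Parameters
    ----------
    molecules:
        Iterable of :class:`Molecule`; ids must be unique.
    interactions:
        Iterable of :class:`Interaction`; both endpoints must resolve to
        molecules.
    name:
        Free-text label.
    """

    def __init__(
        self,
        molecules: Iterable[Molecule] = (),
        interactions: Iterable[Interaction] = (),
        name: str = "kb",
    ) -> None:
        self.name = name
        self._molecules: dict[str, Molecule] = {}
        self._interactions: list[Interaction] = []
        self._simple: nx.Graph | None = None
        for m in molecules:
            self.add_molecule(m)
        for e in interactions:
            self.add_interaction(e)

    # -- construction -----------------------------------------------------

    def add_molecule(self, molecule: Molecule) -> Molecule:
        if molecule.id in self._molecules:
            raise KBIntegrityError(f"duplicate molecule id {molecule.id!r}")
        self._molecules[molecule.id] = molecule
        self._simple = None
        return molecule

    def ensure_molecule(self, mol_id: str, **kwargs) -> Molecule:
        """Return the molecule with ``mol_id``, creating it if absent."""
        if mol_id not in self._molecules:
            self.add_molecule(Molecule(id=mol_id, **kwargs))
        return self._molecules[mol_id]

    def add_interaction(self, interaction: Interaction) -> Interaction:
        for endpoint in (interaction.source, interaction.target):
            if endpoint not in self._molecules:
                raise KBIntegrityError(
                    f"interaction endpoint {endpoint!r} is not a molecule "
                    f"of knowledge base {self.name!r}"
                )
        self._interactions.append(interaction)
        self._simple = None
        return interaction

    def set_focus(self, focus_ids: Iterable[str]) -> None:
        """Flag the given molecules as focus genes (all others cleared)."""
        focus = set(focus_ids)
        unknown = focus - set(self._molecules)
        if unknown:
            raise KeyError(f"unknown molecule ids: {sorted(unknown)}")
        for mol_id, mol in self._molecules.items():
            flag = mol_id in focus
            if mol.is_focus != flag:
                self._molecules[mol_id] = replace(mol, is_focus=flag)

    # -- access -----------------------------------------------------------

    @property
    def molecules(self) -> dict[str, Molecule]:
        return dict(self._molecules)

    @property
    def interactions(self) -> list[Interaction]:
        return list(self._interactions)

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._molecules

    def __len__(self) -> int:
        return len(self._molecules)

    def __iter__(self) -> Iterator[str]:
        return iter(self._molecules)

    def molecule(self, mol_id: str) -> Molecule:
        try:
            return self._molecules[mol_id]
        except KeyError:
            raise KeyError(
                f"molecule {mol_id!r} not in knowledge base {self.name!r}"
            ) from None

    def gene_ids(self) -> list[str]:
        """Ids of molecules of kind ``gene`` (the scoring population)."""
        return [m.id for m in self._molecules.values() if m.molecule_kind == "gene"]

    @property
    def simple_graph(self) -> nx.Graph:
        """Undirected simple view: one adjacency per connected pair, no
        self-loops.  This is the sole graph used by connectivity metrics."""
        if self._simple is None:
            g = nx.Graph()
            g.add_nodes_from(self._molecules)
            g.add_edges_from(
                (e.source, e.target)
                for e in self._interactions
                if e.source != e.target
            )
            self._simple = g
        return self._simple

    def degree(self, mol_id: str) -> int:
        self.molecule(mol_id)
        return self.simple_graph.degree[mol_id]


# -- connectivity primitives ----------------------------------------------


def neighborhood(kb: KnowledgeBase, mol_id: str) -> set[str]:
    """A gene plus the genes exactly one connection away from it.

    Computed on the simple view; always contains ``mol_id`` itself, so
    ``len(neighborhood(kb, g)) == degree(g) + 1``.
    """
    kb.molecule(mol_id)
    nbrs = set(kb.simple_graph.adj[mol_id])
    nbrs.add(mol_id)
    return nbrs


def triangular_connectivity(kb: KnowledgeBase, mol_id: str) -> int:
    """Number of connected neighbor pairs of ``mol_id`` (triangles through
    it) on the simple view.  Used to rank candidate seed genes."""
    kb.molecule(mol_id)
    return int(nx.triangles(kb.simple_graph, mol_id))


def induced_network(kb: KnowledgeBase, genes: Iterable[str]) -> nx.Graph:
    """Simple-view subgraph induced by ``genes`` (copy, safe to annotate)."""
    gene_set = set(genes)
    for g in gene_set:
        kb.molecule(g)
    return kb.simple_graph.subgraph(gene_set).copy()


# -- I/O -------------------------------------------------------------------

_SIF_DIRECT = {"0": False, "1": True}


def _parse_sif_line(line: str, lineno: int) -> tuple[str, ...] | None:
    stripped = line.strip("\n")
    if not stripped.strip() or stripped.lstrip().startswith("#"):
        return None
    fields = stripped.split("\t")
    if len(fields) == 1:
        # isolated molecule declaration
        if not fields[0]:
            raise KBFormatError(f"line {lineno}: empty molecule id")
        return (fields[0],)
    if len(fields) != 4:
        raise KBFormatError(
            f"line {lineno}: expected 1 or 4 tab-separated fields, got {len(fields)}"
        )
    src, relation, tgt, direct = fields
    if relation not in RELATION_TYPES:
        raise KBFormatError(f"line {lineno}: unknown relation {relation!r}")
    if direct not in _SIF_DIRECT:
        raise KBFormatError(
            f"line {lineno}: direct flag must be 0 or 1, got {direct!r}"
        )
    if not src or not tgt:
        raise KBFormatError(f"line {lineno}: empty interaction endpoint")
    return (src, relation, tgt, direct)


def load_kb(path: str | Path, format: str = "sif-tsv", name: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from ``sif-tsv`` or ``graphml``.

    The sif-tsv dialect is ``source TAB relation TAB target TAB direct(0/1)``,
    UTF-8, one interaction per line, ``#`` comment lines, with bare one-field
    lines declaring isolated molecules.  Round-trips byte-identically through
    :func:`save_kb`.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if format == "sif-tsv":
        kb = KnowledgeBase(name=name)
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parsed = _parse_sif_line(line, lineno)
                if parsed is None:
                    continue
                if len(parsed) == 1:
                    kb.ensure_molecule(parsed[0])
                    continue
                src, relation, tgt, direct = parsed
                kb.ensure_molecule(src)
                kb.ensure_molecule(tgt)
                kb.add_interaction(
                    Interaction(src, tgt, relation, _SIF_DIRECT[direct])
                )
        return kb
    if format == "graphml":
        g = nx.read_graphml(path)
        kb = KnowledgeBase(name=name)
        for node, data in g.nodes(data=True):
            kb.add_molecule(
                Molecule(
                    id=str(node),
                    symbol=data.get("symbol", str(node)),
                    molecule_kind=data.get("molecule_kind", "gene"),
                    is_focus=bool(data.get("is_focus", False)),
                )
            )
        for u, v, data in g.edges(data=True):
            kb.add_interaction(
                Interaction(
                    str(u),
                    str(v),
                    data.get("relation", "binding"),
                    bool(data.get("direct", True)),
                )
            )
        return kb
    raise ValueError(f"unknown knowledge-base format {format!r}")


def save_kb(kb: KnowledgeBase, path: str | Path, format: str = "sif-tsv") -> None:
    """Write ``kb`` to disk; inverse of :func:`load_kb` for sif-tsv."""
    path = Path(path)
    if format == "sif-tsv":
        buf = io.StringIO()
        covered: set[str] = set()
        for e in kb.interactions:
            covered.add(e.source)
            covered.add(e.target)
            buf.write(
                f"{e.source}\t{e.relation}\t{e.target}\t{int(e.direct)}\n"
            )
        for mol_id in kb:
            if mol_id not in covered:
                buf.write(f"{mol_id}\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
        return
    if format == "graphml":
        g = nx.MultiGraph(name=kb.name)
        for mol in kb.molecules.values():
            g.add_node(
                mol.id,
                symbol=mol.symbol,
                molecule_kind=mol.molecule_kind,
                is_focus=mol.is_focus,
            )
        for e in kb.interactions:
            g.add_edge(e.source, e.target, relation=e.relation, direct=e.direct)
        nx.write_graphml(g, path)
        return
    raise ValueError(f"unknown knowledge-base format {format!r}")
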