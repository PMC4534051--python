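"""Curated literature tables for chemotherapy-induced peripheral neuropathy.

Sixty-four genetic-association studies of chemotherapy-induced peripheral
neuropathy (CIPN) were curated from PubMed (human studies, English, through
mid-2014).  This module packages the result of that curation as fixtures —
the study records, the per-agent gene/paper summary matrix, the focus-gene
sets per chemotherapy agent, and the hub tables of the published network
analyses — together with the aggregation operations that tie them together.

The PubMed screening itself is human curation and is not re-executed; its
output is frozen here.  Gene symbols use the pathway-tool ("IPA") spelling
(e.g. KCNN3 rather than SK3, CASP9 rather than "caspase 9").
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AGENT_GROUPS",
    "AGENT_NAMES",
    "ETHNICITY_CODES",
    "StudyRecord",
    "FocusGeneSet",
    "AgentGeneMatrix",
    "HubTable",
    "FixtureIntegrityError",
    "FocusSetUnavailableError",
    "load_fixtures",
    "load_study_records",
    "load_focus_gene_sets",
    "load_agent_gene_matrix",
    "load_hub_tables",
    "focus_genes_for_agent",
    "summarize_by_agent",
    "export_gmt",
]

#: Agent-group codes in the canonical column order of the summary matrix.
AGENT_GROUPS = (
    "P", "T", "P/T", "B", "B/V", "Th", "M", "Cyt", "P/F", "P/S", "T/G",
    "P/F/L", "P/F/I", "Pr/V/M", "P/C", "P/F/I/L", "R/Cyc/D/V/Pr",
)

#: Human-readable agent names keyed by code.
AGENT_NAMES = {
    "P": "platinum",
    "T": "taxane",
    "P/T": "platinum/taxane",
    "B": "bortezomib",
    "B/V": "bortezomib/vincristine",
    "Th": "thalidomide",
    "M": "methotrexate",
    "Cyt": "cytarabine",
    "P/F": "platinum/fluorouracil",
    "P/S": "platinum/S-1",
    "T/G": "taxane/gemcitabine",
    "P/F/L": "platinum/fluorouracil/leucovorin",
    "P/F/I": "platinum/fluorouracil/irinotecan",
    "Pr/V/M": "prednisone/vincristine/methotrexate",
    "P/C": "platinum/capecitabine",
    "P/F/I/L": "platinum/fluorouracil/irinotecan/leucovorin",
    "R/Cyc/D/V/Pr": "rituximab/cyclophosphamide/doxorubicin/vincristine/prednisone",
}

_NAME_TO_CODE = {v: k for k, v in AGENT_NAMES.items()}

ETHNICITY_CODES = frozenset({"W", "A", "AA", "H", "NA"})

_DATA_PACKAGE = "cipn_netgrow.data"
_FIXTURE_FILES = (
    "study_records.tsv",
    "focus_genes.tsv",
    "agent_gene_matrix.tsv",
    "agent_papers.tsv",
    "hub_tables.tsv",
)


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum or invariants."""


class FocusSetUnavailableError(KeyError):
    """Raised when an agent has no curated focus-gene list."""


@dataclass(frozen=True)
class StudyRecord:
    """One curated genetic-association study of CIPN."""

    year: int
    first_author: str
    ethnicity: frozenset[str]
    cancer_type: str
    sample_size: int
    phenotype: str
    significant_genes: frozenset[str]
    agent_group: str

    def __post_init__(self) -> None:
        if not 2003 <= self.year <= 2014:
            raise ValueError(f"study year {self.year} outside curated range")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.agent_group not in AGENT_GROUPS:
            raise ValueError(f"unknown agent group {self.agent_group!r}")
        bad = set(self.ethnicity) - ETHNICITY_CODES
        if bad:
            raise ValueError(f"unknown ethnicity codes {sorted(bad)}")


@dataclass(frozen=True)
class FocusGeneSet:
    """Curated focus genes for one chemotherapy agent, in fixture order."""

    agent: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene symbols in focus set {self.agent!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class AgentGeneMatrix:
    """Gene-by-agent paper counts with per-agent paper totals.

    ``counts`` is a genes x agents integer DataFrame; cell (g, a) is the
    number of curated papers of agent group ``a`` reporting gene ``g`` as
    significant.  ``papers_per_agent`` counts all papers per agent,
    including studies that reported no significant genes.
    """

    counts: pd.DataFrame
    papers_per_agent: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) < 1).any():
            raise ValueError("every listed gene must have at least one paper")
        over = self.counts.gt(self.papers_per_agent, axis=1)
        if over.any().any():
            raise ValueError("cell count exceeds total papers for its agent")

    def genes_per_agent(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    def agents_per_gene(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def genes_for_agent(self, agent: str) -> set[str]:
        code = _agent_code(agent)
        return set(self.counts.index[self.counts[code] > 0])

    def equals(self, other: "AgentGeneMatrix") -> bool:
        a = self.counts.sort_index().sort_index(axis=1)
        b = other.counts.sort_index().sort_index(axis=1)
        return a.equals(b) and self.papers_per_agent.sort_index().equals(
            other.papers_per_agent.sort_index()
        )


@dataclass
class HubTable:
    """Hub genes of a published network: symbol, connection count within the
    network, focus flag; entries sorted by descending connections and all at
    or above the table's own >= 15-connection filter."""

    analysis: str
    entries: list[tuple[str, int, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = [c for _, c, _ in self.entries]
        if any(c < 15 for c in counts):
            raise ValueError("hub table entries must have >= 15 connections")
        if counts != sorted(counts, reverse=True):
            raise ValueError("hub table entries must be sorted by descending count")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _, _ in self.entries]


# -- fixture loading -------------------------------------------------------


def _data_path(filename: str):
    return resources.files(_DATA_PACKAGE).joinpath(filename)


def _verify_checksums() -> None:
    manifest = json.loads(_data_path("MANIFEST.json").read_text(encoding="utf-8"))
    for filename in _FIXTURE_FILES:
        digest = hashlib.sha256(_data_path(filename).read_bytes()).hexdigest()
        if manifest.get(filename) != digest:
            raise FixtureIntegrityError(
                f"fixture {filename!r} fails checksum verification "
                f"(expected {manifest.get(filename)}, got {digest})"
            )


def _read_tsv(filename: str) -> pd.DataFrame:
    with resources.as_file(_data_path(filename)) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_study_records(verify: bool = True) -> list[StudyRecord]:
    if verify:
        _verify_checksums()
    records = []
    for row in _read_tsv("study_records.tsv").itertuples(index=False):
        genes = (
            frozenset()
            if row.significant_genes == "None"
            else frozenset(row.significant_genes.split(","))
        )
        records.append(
            StudyRecord(
                year=int(row.year),
                first_author=row.first_author,
                ethnicity=frozenset(row.ethnicity.split(",")),
                cancer_type=row.cancer_type,
                sample_size=int(row.sample_size),
                phenotype=row.phenotype,
                significant_genes=genes,
                agent_group=row.agent_group,
            )
        )
    return records


def load_focus_gene_sets(verify: bool = True) -> list[FocusGeneSet]:
    if verify:
        _verify_checksums()
    df = _read_tsv("focus_genes.tsv")
    sets = []
    for agent, group in df.groupby("agent_group", sort=False):
        sets.append(FocusGeneSet(agent=agent, genes=tuple(group["gene"])))
    return sets


def load_agent_gene_matrix(verify: bool = True) -> AgentGeneMatrix:
    if verify:
        _verify_checksums()
    counts = _read_tsv("agent_gene_matrix.tsv").set_index("gene").astype(int)
    papers = (
        _read_tsv("agent_papers.tsv")
        .set_index("agent_group")["n_papers"]
        .astype(int)
    )
    return AgentGeneMatrix(counts=counts, papers_per_agent=papers)


def load_hub_tables(verify: bool = True) -> tuple[HubTable, HubTable]:
    if verify:
        _verify_checksums()
    df = _read_tsv("hub_tables.tsv")
    tables = {}
    for analysis, group in df.groupby("analysis", sort=False):
        tables[analysis] = HubTable(
            analysis=analysis,
            entries=[
                (row.symbol, int(row.connections), bool(int(row.is_focus)))
                for row in group.itertuples(index=False)
            ],
        )
    return tables["platinum"], tables["platinum/taxane"]


def load_fixtures() -> tuple[
    list[StudyRecord], AgentGeneMatrix, list[FocusGeneSet], tuple[HubTable, HubTable]
]:
    """Load all packaged curation fixtures (checksum-verified)."""
    _verify_checksums()
    return (
        load_study_records(verify=False),
        load_agent_gene_matrix(verify=False),
        load_focus_gene_sets(verify=False),
        load_hub_tables(verify=False),
    )


# -- operations ------------------------------------------------------------


def _agent_code(agent: str) -> str:
    if agent in AGENT_GROUPS:
        return agent
    if agent in _NAME_TO_CODE:
        return _NAME_TO_CODE[agent]
    raise KeyError(f"unknown agent {agent!r}")


def focus_genes_for_agent(
    sets: list[FocusGeneSet], agent: str
) -> FocusGeneSet:
    """Return the curated focus-gene list for ``agent`` (code or name).

    Only the agents studied often enough to support network analysis have
    curated lists; any other agent raises :class:`FocusSetUnavailableError`.
    """
    for fs in sets:
        if fs.agent == agent:
            return fs
    try:
        code = _agent_code(agent)
    except KeyError:
        code = agent
    for fs in sets:
        if fs.agent == code:
            return fs
    raise FocusSetUnavailableError(
        f"no curated focus-gene list for agent {AGENT_NAMES.get(code, code)!r}"
    )


def summarize_by_agent(records: list[StudyRecord]) -> AgentGeneMatrix:
    """Aggregate study records into the gene-by-agent paper-count matrix.

    Cell (g, a) counts records of agent group ``a`` listing ``g`` among
    their significant genes.  Studies reporting no significant genes
    contribute to the per-agent paper totals but to no cells.
    """
    if not records:
        raise ValueError("no study records to summarize")
    agents = [a for a in AGENT_GROUPS if any(r.agent_group == a for r in records)]
    genes: list[str] = []
    for r in records:
        for g in sorted(r.significant_genes):
            if g not in genes:
                genes.append(g)
    counts = pd.DataFrame(0, index=genes, columns=agents, dtype=int)
    papers = pd.Series(0, index=agents, dtype=int)
    for r in records:
        papers[r.agent_group] += 1
        for g in r.significant_genes:
            counts.loc[g, r.agent_group] += 1
    counts.index.name = "gene"
    return AgentGeneMatrix(counts=counts, papers_per_agent=papers)


def export_gmt(sets: list[FocusGeneSet], path: str | Path) -> None:
    """Write focus-gene sets as GMT (one line per agent: name, description,
    genes, tab-separated)."""
    lines = []
    for fs in sets:
        name = AGENT_NAMES.get(fs.agent, fs.agent)
        desc = f"{name}-induced neuropathy focus genes"
        lines.append("\t".join([name, desc, *fs.genes]) + "\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


def load_gmt(path: str | Path) -> list[FocusGeneSet]:
    """Read GMT gene sets (inverse of :func:`export_gmt`)."""
    sets = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = _NAME_TO_CODE.get(fields[0], fields[0])
        sets.append(FocusGeneSet(agent=name, genes=tuple(fields[2:])))
    return sets
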