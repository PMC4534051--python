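"""Synthetic molecular-interaction knowledge base with planted ground truth.

Real curated interactomes are proprietary, so the network-growth algorithm
is exercised on a simulator that reproduces the structural features the
algorithm relies on: an approximately scale-free scaffold (preferential
attachment, giving the heavy-tailed degree distribution expected of
interactomes), locally dense planted modules that carry designated focus
genes (the "biological function involves locally dense interactions"
working hypothesis), and typed edges drawn from the relationship
vocabulary.  Each planted module is recorded in a :class:`GroundTruth`
object so recovery of the planted focus genes by the analysis can be
measured.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config; identical configs produce byte-identical knowledge bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import yaml

from .knowledge_base import (
    RELATION_TYPES,
    Interaction,
    KnowledgeBase,
    Molecule,
)

__all__ = [
    "PlantedModule",
    "SyntheticKBConfig",
    "GroundTruth",
    "generate_kb",
    "degree_sequence",
    "save_ground_truth",
    "load_config",
    "save_config",
]

_RELATIONS = tuple(sorted(RELATION_TYPES))


@dataclass(frozen=True)
class PlantedModule:
    """A locally dense gene module tied into the scaffold.

    ``module_size`` new genes are added; every pair is connected
    independently with probability ``intra_density``; ``attach_edges``
    random ties anchor the module to scaffold genes; ``focus_count`` of its
    members are designated focus genes in the ground truth.
    """

    module_size: int
    focus_count: int
    intra_density: float = 0.4
    attach_edges: int = 5

    def __post_init__(self) -> None:
        if self.module_size <= 0 or self.attach_edges <= 0:
            raise ValueError("module_size and attach_edges must be positive")
        if not 0 <= self.focus_count <= self.module_size:
            raise ValueError("focus_count must be in [0, module_size]")
        if not 0.0 <= self.intra_density <= 1.0:
            raise ValueError("intra_density must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticKBConfig:
    """Parameters of the synthetic knowledge base.

    Defaults describe a desk-scale stand-in interactome: a 5000-gene
    scaffold grown by preferential attachment with 2 edges per new gene,
    no planted modules, uniform relation-type weights, and a 70 % chance
    that an interaction is flagged direct.
    """

    n_background: int = 5000
    m_attach: int = 2
    planted_modules: tuple[PlantedModule, ...] = ()
    relation_weights: dict[str, float] | None = None
    direct_probability: float = 0.7
    scatter_focus: int = 0  # extra focus genes scattered on the scaffold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background <= 0 or self.m_attach <= 0:
            raise ValueError("n_background and m_attach must be positive")
        if self.m_attach >= self.n_background:
            raise ValueError("m_attach must be smaller than n_background")
        if not 0.0 <= self.direct_probability <= 1.0:
            raise ValueError("direct_probability must lie in [0, 1]")
        if self.scatter_focus < 0:
            raise ValueError("scatter_focus must be non-negative")
        if self.relation_weights is not None:
            unknown = set(self.relation_weights) - RELATION_TYPES
            if unknown:
                raise ValueError(f"unknown relation types: {sorted(unknown)}")
            if any(w < 0 for w in self.relation_weights.values()):
                raise ValueError("relation weights must be non-negative")
            if sum(self.relation_weights.values()) <= 0:
                raise ValueError("relation weights must not all be zero")
        object.__setattr__(self, "planted_modules", tuple(self.planted_modules))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic knowledge base.

    ``modules`` maps module id to the full member set; ``focus`` maps
    module id to the designated focus subset.  ``scatter_focus`` holds
    focus genes scattered on the scaffold as negatives (module id
    ``"background"`` on export).
    """

    modules: dict[str, set[str]] = field(default_factory=dict)
    focus: dict[str, set[str]] = field(default_factory=dict)
    scatter_focus: set[str] = field(default_factory=set)

    def all_focus(self) -> set[str]:
        out: set[str] = set(self.scatter_focus)
        for genes in self.focus.values():
            out |= genes
        return out


def _relation_sampler(config: SyntheticKBConfig, rng: np.random.Generator):
    if config.relation_weights is None:
        weights = np.full(len(_RELATIONS), 1.0 / len(_RELATIONS))
    else:
        weights = np.array(
            [config.relation_weights.get(r, 0.0) for r in _RELATIONS], dtype=float
        )
        weights /= weights.sum()

    def sample() -> tuple[str, bool]:
        rel = _RELATIONS[int(rng.choice(len(_RELATIONS), p=weights))]
        direct = bool(rng.random() < config.direct_probability)
        return rel, direct

    return sample


def generate_kb(config: SyntheticKBConfig) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate a synthetic knowledge base and its planted ground truth.

    The scaffold has ``n_background`` genes and
    ``(n_background - m_attach) * m_attach`` edges (the standard
    preferential-attachment count).  Module members are named
    ``M<k>_<i>``, scaffold genes ``B<i>``.
    """
    rng = np.random.default_rng(config.seed)
    sample_edge = _relation_sampler(config, rng)

    # scaffold by preferential attachment; its own seed derives from rng so
    # everything flows from config.seed
    ba_seed = int(rng.integers(0, 2**31 - 1))
    scaffold = nx.barabasi_albert_graph(config.n_background, config.m_attach, seed=ba_seed)

    width = len(str(config.n_background - 1))
    scaffold_ids = [f"B{i:0{width}d}" for i in range(config.n_background)]

    kb = KnowledgeBase(name=f"synthetic-kb-seed{config.seed}")
    for mol_id in scaffold_ids:
        kb.add_molecule(Molecule(id=mol_id, molecule_kind="gene"))
    for u, v in scaffold.edges():
        rel, direct = sample_edge()
        kb.add_interaction(Interaction(scaffold_ids[u], scaffold_ids[v], rel, direct))

    truth = GroundTruth()
    for k, module in enumerate(config.planted_modules, start=1):
        mwidth = len(str(module.module_size - 1)) if module.module_size > 1 else 1
        member_ids = [f"M{k}_{i:0{mwidth}d}" for i in range(module.module_size)]
        for mol_id in member_ids:
            kb.add_molecule(Molecule(id=mol_id, molecule_kind="gene"))
        # independent intra-module edges at intra_density
        for i in range(module.module_size):
            for j in range(i + 1, module.module_size):
                if rng.random() < module.intra_density:
                    rel, direct = sample_edge()
                    kb.add_interaction(
                        Interaction(member_ids[i], member_ids[j], rel, direct)
                    )
        # ties into the scaffold
        for _ in range(module.attach_edges):
            m_gene = member_ids[int(rng.integers(module.module_size))]
            b_gene = scaffold_ids[int(rng.integers(config.n_background))]
            rel, direct = sample_edge()
            kb.add_interaction(Interaction(m_gene, b_gene, rel, direct))
        module_id = f"module{k}"
        truth.modules[module_id] = set(member_ids)
        focus_idx = rng.choice(
            module.module_size, size=module.focus_count, replace=False
        )
        truth.focus[module_id] = {member_ids[int(i)] for i in sorted(focus_idx)}

    if config.scatter_focus:
        idx = rng.choice(config.n_background, size=config.scatter_focus, replace=False)
        truth.scatter_focus = {scaffold_ids[int(i)] for i in sorted(idx)}

    kb.set_focus(truth.all_focus())
    return kb, truth


def degree_sequence(kb: KnowledgeBase) -> list[int]:
    """Simple-view degrees of all molecules, descending."""
    return sorted((d for _, d in kb.simple_graph.degree()), reverse=True)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as TSV: molecule id, module id, is_focus."""
    lines = ["molecule_id\tmodule_id\tis_focus\n"]
    for module_id in sorted(truth.modules):
        focus = truth.focus.get(module_id, set())
        for mol_id in sorted(truth.modules[module_id]):
            lines.append(f"{mol_id}\t{module_id}\t{int(mol_id in focus)}\n")
    for mol_id in sorted(truth.scatter_focus):
        lines.append(f"{mol_id}\tbackground\t1\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


# -- config round-trip -----------------------------------------------------


def save_config(config: SyntheticKBConfig, path: str | Path) -> None:
    data = {
        "n_background": config.n_background,
        "m_attach": config.m_attach,
        "planted_modules": [
            {
                "module_size": m.module_size,
                "focus_count": m.focus_count,
                "intra_density": m.intra_density,
                "attach_edges": m.attach_edges,
            }
            for m in config.planted_modules
        ],
        "relation_weights": config.relation_weights,
        "direct_probability": config.direct_probability,
        "scatter_focus": config.scatter_focus,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> SyntheticKBConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    modules = tuple(
        PlantedModule(**m) for m in data.pop("planted_modules", []) or []
    )
    return SyntheticKBConfig(planted_modules=modules, **data)
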