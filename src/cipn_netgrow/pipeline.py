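"""End-to-end orchestration: knowledge base -> core analysis -> reports.

A pipeline run loads or simulates a knowledge base, runs the core analysis
for the selected agent's focus genes, scores the networks, reports hubs
and the log-log power-law diagnostic, and writes a manifest (config,
package version, seed, output checksums) sufficient to reproduce every
output byte-for-byte.  A single global seed fans out to stage seeds
through a fixed hash derivation so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core_analysis import AnalysisConfig, CoreAnalysisResult, core_analysis
from .knowledge_base import KnowledgeBase, induced_network, load_kb, save_kb
from .literature import FocusGeneSet, load_focus_gene_sets, focus_genes_for_agent, load_gmt
from .synthetic_kb import SyntheticKBConfig, degree_sequence, generate_kb, save_ground_truth
from .topology import count_connections, find_hubs, loglog_powerlaw_fit

__all__ = ["PipelineConfig", "PipelineError", "derive_seed", "run_pipeline"]

log = logging.getLogger("cipn_netgrow")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def derive_seed(master: int, label: str) -> int:
    """Deterministically derive a stage seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Exactly one knowledge-base source (file path or synthetic config),
    an agent selection, analysis settings, output directory and seed."""

    kb_file: str | None = None
    synthetic: SyntheticKBConfig | None = None
    agent: str = "platinum"
    focus_gmt: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "cipn-netgrow-out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.kb_file is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one knowledge-base source (kb_file or synthetic) "
                "must be specified"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synth = data.pop("synthetic", None)
        if synth is not None:
            from .synthetic_kb import PlantedModule

            modules = tuple(
                PlantedModule(**m) for m in synth.pop("planted_modules", []) or []
            )
            synth = SyntheticKBConfig(planted_modules=modules, **synth)
        analysis = AnalysisConfig(**(data.pop("analysis", None) or {}))
        return cls(synthetic=synth, analysis=analysis, **data)


def _resolve_focus(config: PipelineConfig, truth) -> FocusGeneSet:
    if config.focus_gmt is not None:
        sets = load_gmt(config.focus_gmt)
        for fs in sets:
            if fs.agent == config.agent or config.agent in (fs.agent,):
                return fs
        if len(sets) == 1:
            return sets[0]
        raise PipelineError(f"focus: agent {config.agent!r} not found in GMT")
    if config.agent == "synthetic":
        if truth is None:
            raise PipelineError(
                "focus: agent 'synthetic' requires a synthetic knowledge base"
            )
        return FocusGeneSet(agent="synthetic", genes=tuple(sorted(truth.all_focus())))
    return focus_genes_for_agent(load_focus_gene_sets(), config.agent)


def _networks_payload(result: CoreAnalysisResult) -> dict:
    return {
        "population_size": result.population_size,
        "focus_population": result.focus_population,
        "excluded_focus_genes": result.excluded,
        "unmapped_focus_symbols": result.unmapped,
        "networks": [
            {
                "rank": i + 1,
                "n": s.n,
                "n_f": s.n_f,
                "p_value": s.p_value,
                "score": s.score,
                "significant": s.significant,
                "seed": s.network.seed,
                "genes": list(s.network.genes),
                "focus_genes": sorted(s.network.focus_genes),
                "provenance": {
                    g: {"rule": rule, "order": order}
                    for g, (rule, order) in s.network.provenance.items()
                },
            }
            for i, s in enumerate(result.networks)
        ],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Outputs under ``config.out_dir``: ``kb.tsv`` (when simulated),
    ``networks.json``, ``hubs.tsv``, ``fit.json``, ``exclusions.tsv`` and
    ``manifest.json``.  Returns the manifest dictionary.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # stage: knowledge base
    truth = None
    if config.synthetic is not None:
        synth = dataclasses.replace(
            config.synthetic, seed=derive_seed(config.seed, "synthetic-kb")
        )
        log.info("simulating knowledge base (seed %d)", synth.seed)
        kb, truth = generate_kb(synth)
        save_kb(kb, out / "kb.tsv")
        save_ground_truth(truth, out / "ground_truth.tsv")
        outputs += [out / "kb.tsv", out / "ground_truth.tsv"]
    else:
        path = Path(config.kb_file)
        if not path.exists():
            raise PipelineError(f"knowledge base: file not found: {path}")
        log.info("loading knowledge base from %s", path)
        try:
            kb = load_kb(path)
        except Exception as exc:
            raise PipelineError(f"knowledge base: {exc}") from exc

    # stage: focus genes
    try:
        focus = _resolve_focus(config, truth)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"focus genes: {exc}") from exc

    # stage: core analysis
    try:
        result = core_analysis(kb, focus, config.analysis)
    except Exception as exc:
        raise PipelineError(f"core analysis: {exc}") from exc
    (out / "networks.json").write_text(
        json.dumps(_networks_payload(result), indent=2) + "\n", encoding="utf-8"
    )
    outputs.append(out / "networks.json")

    # stage: hubs
    hub_lines = ["network_rank\tgene\tconnections\tis_focus\n"]
    for i, s in enumerate(result.networks):
        subgraph = induced_network(kb, s.network.genes)
        counts = count_connections(subgraph)
        report = find_hubs(
            counts, config.analysis.hub_min_connections, s.network.focus_genes
        )
        for gene, c, is_focus in report.entries:
            hub_lines.append(f"{i + 1}\t{gene}\t{c}\t{int(is_focus)}\n")
    (out / "hubs.tsv").write_text("".join(hub_lines), encoding="utf-8")
    outputs.append(out / "hubs.tsv")

    # stage: power-law diagnostic on the knowledge base degree distribution
    try:
        fit = loglog_powerlaw_fit(degree_sequence(kb))
        fit_payload = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n_points": len(fit.points),
        }
    except ValueError as exc:
        fit_payload = {"error": str(exc)}
    (out / "fit.json").write_text(
        json.dumps(fit_payload, indent=2) + "\n", encoding="utf-8"
    )
    outputs.append(out / "fit.json")

    # stage: exclusion report
    excl_lines = ["focus_gene\treason\n"]
    for g in result.excluded:
        excl_lines.append(f"{g}\tno connections in knowledge base\n")
    for g in result.unmapped:
        excl_lines.append(f"{g}\tnot mappable to knowledge base\n")
    (out / "exclusions.tsv").write_text("".join(excl_lines), encoding="utf-8")
    outputs.append(out / "exclusions.tsv")

    manifest = {
        "package": "cipn-netgrow",
        "version": __version__,
        "seed": config.seed,
        "config": _config_payload(config),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest


def _config_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    if config.synthetic is not None:
        payload["synthetic"]["planted_modules"] = [
            dataclasses.asdict(m) for m in config.synthetic.planted_modules
        ]
    return payload
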