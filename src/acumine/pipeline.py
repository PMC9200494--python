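"""End-to-end orchestration: summarize -> network -> rules -> clusters.

One config drives all four stages on the same dataset and writes a
machine-readable report bundle. The run log records every threshold and
the seed (and nothing volatile), so identical configs produce
byte-identical bundles.

The preset thresholds mirror the published analysis: minimum support 0.15,
minimum confidence 0.90, lift > 1, minimum network edge weight 30, item
frequency floor 10 (inclusive), 7 clusters.

A fixture-only mode exists because the corpus's per-acupoint marginal
counts are published but its transactions are not: with neither an input
file nor a generator config, the descriptive stage runs from the packaged
registry fixture and the transaction-level stages are skipped with a
logged notice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import clustering, network, rules
from .frequency import summarize
from .prescriptions import PrescriptionDataset, item_frequencies, read_dataset
from .registry import Registry, load_registry
from .rules import MiningConfig
from .synthetic import GeneratorConfig, generate

__all__ = ["PipelineConfig", "run"]

#: Number of prescriptions in the published corpus; the denominator used
#: for fixture-only percentage summaries.
CORPUS_N_PRESCRIPTIONS = 42


@dataclass
class PipelineConfig:
    input_path: str | None = None
    input_format: str | None = None
    generator: GeneratorConfig | None = None
    min_support: float = 0.15
    min_confidence: float = 0.90
    min_lift: float = 1.0
    min_edge_weight: int = 30
    min_item_frequency: int = 10
    k: int = 7
    outdir: str = "acumine-out"
    seed: int = 0


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def run(config: PipelineConfig, registry: Registry | None = None) -> dict:
    """Execute the full analysis; returns a dict of artifact paths."""
    registry = registry or load_registry()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(log, "acumine pipeline run")
    for name in ("min_support", "min_confidence", "min_lift", "min_edge_weight",
                 "min_item_frequency", "k", "seed"):
        _log(log, f"threshold {name} = {getattr(config, name)}")

    if config.input_path is not None and config.generator is not None:
        raise ValueError("give either an input path or a generator config, not both")

    ds: PrescriptionDataset | None
    if config.input_path is not None:
        ds = read_dataset(config.input_path, registry, format=config.input_format)
        ds.validate(registry)
        _log(log, f"input: {config.input_path} ({len(ds)} prescriptions)")
    elif config.generator is not None:
        gen = config.generator
        if gen.seed != config.seed:
            gen = GeneratorConfig(
                n_transactions=gen.n_transactions,
                marginal_targets=gen.marginal_targets,
                blocks=gen.blocks,
                exact_marginals=gen.exact_marginals,
                seed=config.seed,
            )
        ds = generate(gen)
        _log(log, f"input: synthetic ({len(ds)} prescriptions, seed {config.seed})")
    else:
        ds = None
        _log(log, "input: none — fixture-only mode, descriptive stage only")

    artifacts: dict[str, str] = {}

    # Stage 1: descriptive summary
    try:
        if ds is not None:
            freqs = item_frequencies(ds)
            summ = summarize(freqs, registry, len(ds))
        else:
            summ = summarize(
                registry.frequencies(), registry, CORPUS_N_PRESCRIPTIONS
            )
    except Exception as exc:
        raise RuntimeError(f"summarize stage failed: {exc}") from exc
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summ.to_dict(), indent=1, sort_keys=True) + "\n")
    artifacts["summary"] = str(summary_path)
    _log(log, f"summarize: {summ.n_acupoints} acupoints, total {summ.grand_total}")

    if ds is None:
        _log(log, "network/rules/cluster stages skipped: no transaction data")
    else:
        # Stage 2: co-occurrence network
        try:
            edges = network.pair_counts(ds)
            kept, _nodes = network.threshold_network(edges, config.min_edge_weight) \
                if edges else ([], set())
        except Exception as exc:
            raise RuntimeError(f"network stage failed: {exc}") from exc
        edges_path = outdir / "edges.tsv"
        network.write_edge_tsv(kept, edges_path)
        artifacts["edges"] = str(edges_path)
        _log(log, f"network: {len(kept)} edges at weight >= {config.min_edge_weight}")

        # Stage 3: association rules
        try:
            mcfg = MiningConfig(
                min_support=config.min_support,
                min_confidence=config.min_confidence,
                min_item_frequency=config.min_item_frequency,
                min_lift=config.min_lift,
            )
            itemsets = rules.frequent_itemsets(ds, mcfg)
            rule_list = rules.generate_rules(itemsets, mcfg)
        except Exception as exc:
            raise RuntimeError(f"rules stage failed: {exc}") from exc
        rules_path = outdir / "rules.tsv"
        rules.write_rules_tsv(rule_list, rules_path)
        artifacts["rules"] = str(rules_path)
        _log(log, f"rules: {len(rule_list)} rules from {len(itemsets)} itemsets")

        # Stage 4: hierarchical clustering
        try:
            X, codes = clustering.occurrence_matrix(ds, config.min_item_frequency)
            dend = clustering.ward_linkage(X, codes)
            k = min(config.k, len(codes))
            assign = clustering.cut_tree(dend, k)
        except Exception as exc:
            raise RuntimeError(f"cluster stage failed: {exc}") from exc
        newick_path = outdir / "dendrogram.nwk"
        newick_path.write_text(clustering.to_newick(dend) + "\n")
        artifacts["newick"] = str(newick_path)
        clusters_path = outdir / "clusters.tsv"
        with open(clusters_path, "w") as fh:
            fh.write("code\tcluster\n")
            for code in sorted(assign.assignment):
                fh.write(f"{code}\t{assign.assignment[code]}\n")
        artifacts["clusters"] = str(clusters_path)
        _log(log, f"cluster: {len(codes)} acupoints into {k} clusters")

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    artifacts["log"] = str(log_path)
    return artifacts
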