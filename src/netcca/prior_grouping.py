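"""Prior-knowledge graph construction and functional grouping.

A bipartite metabolite-gene reaction layer (which enzymes act on which small
molecules, as substrates or products) is combined with a gene-gene
interaction layer carrying per-channel evidence scores (text mining,
protein-protein interaction, gene proximity). Metabolite classes supplied by
the user (e.g. the saturated / monounsaturated / polyunsaturated fatty-acid
split) seed one functional group each: genes catalysing reactions of the
class metabolites are the seeds, and the set is expanded over high-confidence
interaction edges by network distance, hub detection and membership in
directed circuits. Features assigned to no class fall into a complement
group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph",
    "FunctionalGroup",
    "ExpansionParams",
    "build_knowledge_graph",
    "seed_genes_for_metabolites",
    "expand_gene_set",
    "assign_groups",
]

VALID_ROLES = frozenset({"substrate", "product"})
VALID_CHANNELS = frozenset({"textmining", "ppi", "gene_proximity", "other"})


@dataclass
class KnowledgeGraph:
    """Reaction (metabolite-gene) and interaction (gene-gene) prior edges.

    ``reaction_edges`` rows are ``(metabolite_id, gene_id, reaction_id,
    role)``; ``interaction_edges`` rows are ``(gene_a, gene_b, channel,
    score, directed)`` with scores on [0, 1]. Interaction edges below the
    retention threshold are already filtered out at construction.
    """

    metabolite_nodes: set[str] = field(default_factory=set)
    gene_nodes: set[str] = field(default_factory=set)
    reaction_edges: list[tuple[str, str, str, str]] = field(default_factory=list)
    interaction_edges: list[tuple[str, str, str, float, bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for m, g, _, role in self.reaction_edges:
            if role not in VALID_ROLES:
                raise ValueError(f"unknown reaction role {role!r}")
            if m not in self.metabolite_nodes or g not in self.gene_nodes:
                raise ValueError(f"reaction edge ({m}, {g}) references unknown node")
        for a, b, _, score, _ in self.interaction_edges:
            if a == b:
                raise ValueError(f"self-loop interaction edge on {a!r}")
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"interaction score {score} outside [0, 1]")
            if a not in self.gene_nodes or b not in self.gene_nodes:
                raise ValueError(f"interaction edge ({a}, {b}) references unknown node")

    def interaction_graph(self) -> nx.Graph:
        """Undirected view of retained interaction edges (max score kept)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.gene_nodes))
        for a, b, channel, score, _ in self.interaction_edges:
            if g.has_edge(a, b):
                if score > g[a][b]["score"]:
                    g[a][b].update(score=score, channel=channel)
            else:
                g.add_edge(a, b, score=score, channel=channel)
        return g

    def directed_interaction_graph(self) -> nx.DiGraph:
        """Directed view holding only edges flagged as directed."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.gene_nodes))
        for a, b, _, score, directed in self.interaction_edges:
            if directed:
                g.add_edge(a, b, score=score)
        return g


@dataclass
class FunctionalGroup:
    """A named (metabolite set, gene set) pair with per-gene provenance.

    Provenance tags are ``seed``, ``expanded_distance(d)``, ``expanded_hub``
    or ``expanded_circuit``. The complement group ("Group 4"-style) holds
    every measured feature not claimed by any class group.
    """

    name: str
    metabolite_ids: set[str]
    gene_ids: set[str]
    provenance: dict[str, str] = field(default_factory=dict)
    is_complement: bool = False

    def __post_init__(self) -> None:
        if not self.is_complement:
            if len(self.metabolite_ids) < 1 or len(self.gene_ids) < 2:
                raise ValueError(
                    f"group {self.name!r} needs >=1 metabolite and >=2 genes "
                    f"(got {len(self.metabolite_ids)}, {len(self.gene_ids)})"
                )
        missing = self.gene_ids - set(self.provenance)
        if missing:
            raise ValueError(
                f"group {self.name!r}: provenance missing for {sorted(missing)}"
            )


@dataclass
class ExpansionParams:
    """Knobs for seed-set expansion over the interaction network."""

    max_distance: int = 1
    hub_percentile: float = 95.0
    use_circuits: bool = False
    circuit_length_bound: int = 4

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if not (0.0 < self.hub_percentile <= 100.0):
            raise ValueError("hub_percentile must be in (0, 100]")


def _rows(table) -> list[dict]:
    if isinstance(table, pd.DataFrame):
        return table.to_dict("records")
    return [dict(r) for r in table]


def build_knowledge_graph(
    reaction_table,
    interaction_table,
    score_threshold: float = 0.7,
) -> KnowledgeGraph:
    """Assemble the prior graph, keeping interaction edges with high-quality
    evidence from at least one channel.

    Raw interaction scores may use the 0-1000 combined-score convention;
    this is auto-detected (any score > 1) and rescaled. An edge between two
    genes is retained iff at least one of its channel scores reaches
    ``score_threshold``; nodes referenced anywhere are always created, so
    dropping all edges of a gene leaves it isolated, not absent.
    """
    if not (0.0 <= score_threshold <= 1.0):
        raise ValueError("score_threshold must be in [0, 1]")
    kg_metabolites: set[str] = set()
    kg_genes: set[str] = set()
    reactions: list[tuple[str, str, str, str]] = []
    for row in _rows(reaction_table):
        role = str(row["role"]).strip().lower()
        if role not in VALID_ROLES:
            raise ValueError(f"unknown reaction role {row['role']!r}")
        m, g = str(row["metabolite_id"]), str(row["gene_id"])
        kg_metabolites.add(m)
        kg_genes.add(g)
        reactions.append((m, g, str(row["reaction_id"]), role))

    raw = []
    for row in _rows(interaction_table):
        channel = str(row["channel"]).strip().lower()
        if channel not in VALID_CHANNELS:
            raise ValueError(f"unknown interaction channel {row['channel']!r}")
        score = float(row["score"])
        if not (0.0 <= score <= 1000.0):
            raise ValueError(f"interaction score {score} outside [0, 1000]")
        directed = bool(int(row.get("directed", 0)))
        raw.append((str(row["gene_a"]), str(row["gene_b"]), channel, score, directed))

    scores = [r[3] for r in raw]
    scale = 1000.0 if scores and max(scores) > 1.0 else 1.0
    # Edge retention follows the at-least-one-good-channel rule: group the
    # channel rows per (unordered) gene pair first.
    per_pair: dict[frozenset, list[tuple[str, str, str, float, bool]]] = {}
    for a, b, channel, score, directed in raw:
        if a == b:
            raise ValueError(f"self-loop interaction edge on {a!r}")
        kg_genes.update((a, b))
        per_pair.setdefault(frozenset((a, b)), []).append(
            (a, b, channel, score / scale, directed)
        )
    interactions: list[tuple[str, str, str, float, bool]] = []
    for pair_rows in per_pair.values():
        if max(r[3] for r in pair_rows) >= score_threshold:
            interactions.extend(pair_rows)

    return KnowledgeGraph(
        metabolite_nodes=kg_metabolites,
        gene_nodes=kg_genes,
        reaction_edges=reactions,
        interaction_edges=interactions,
    )


def seed_genes_for_metabolites(
    graph: KnowledgeGraph, metabolite_ids: Iterable[str]
) -> set[str]:
    """Genes of every reaction in which a queried metabolite participates,
    as substrate or product. Unknown metabolites contribute nothing."""
    wanted = set(metabolite_ids)
    if not wanted:
        raise ValueError("metabolite_ids must be nonempty")
    touched_reactions = {
        rid for m, _, rid, _ in graph.reaction_edges if m in wanted
    }
    return {
        g for _, g, rid, _ in graph.reaction_edges if rid in touched_reactions
    }


def expand_gene_set(
    graph: KnowledgeGraph,
    seeds: Iterable[str],
    params: ExpansionParams | None = None,
) -> dict[str, str]:
    """Expand a seed gene set over the interaction network.

    Returns a provenance mapping covering seeds (tag ``seed``) and added
    genes. Additions, with first-applicable tag winning in the order
    distance < hub < circuit:

    - genes within ``max_distance`` hops (undirected, retained edges only)
      of any seed — ``expanded_distance(d)`` with d the shortest distance;
    - non-seed neighbors of seeds whose degree reaches the
      ``hub_percentile`` of the full degree distribution — ``expanded_hub``;
    - if ``use_circuits``, genes sharing a simple directed cycle (length
      bounded) with a seed — ``expanded_circuit``. Only edges flagged
      directed carry direction.

    Seeds absent from the graph pass through untouched.
    """
    if params is None:
        params = ExpansionParams()
    seed_set = set(seeds)
    provenance: dict[str, str] = {g: "seed" for g in seed_set}
    g_und = graph.interaction_graph()
    in_graph = [s for s in seed_set if s in g_und]

    if in_graph and params.max_distance > 0:
        dist: dict[str, int] = {}
        for s in in_graph:
            for node, d in nx.single_source_shortest_path_length(
                g_und, s, cutoff=params.max_distance
            ).items():
                if node not in dist or d < dist[node]:
                    dist[node] = d
        for node in sorted(dist):
            if node not in provenance:
                provenance[node] = f"expanded_distance({dist[node]})"

    if in_graph and g_und.number_of_nodes() > 0:
        degrees = np.array([d for _, d in g_und.degree()], dtype=float)
        cutoff = np.percentile(degrees, params.hub_percentile)
        neighbors: set[str] = set()
        for s in in_graph:
            neighbors.update(g_und.neighbors(s))
        for node in sorted(neighbors - seed_set):
            if node not in provenance and g_und.degree(node) >= cutoff:
                provenance[node] = "expanded_hub"

    if params.use_circuits and in_graph:
        g_dir = graph.directed_interaction_graph()
        for cycle in nx.simple_cycles(g_dir, length_bound=params.circuit_length_bound):
            members = set(cycle)
            if members & seed_set:
                for node in sorted(members - seed_set):
                    provenance.setdefault(node, "expanded_circuit")
    return provenance


def assign_groups(
    metabolite_classes: Mapping[str, Iterable[str]],
    graph: KnowledgeGraph,
    x_features: Sequence[str],
    y_features: Sequence[str],
    params: ExpansionParams | None = None,
    complement_name: str = "complement",
) -> list[FunctionalGroup]:
    """Derive one functional group per metabolite class plus the complement.

    Per class: seed genes come from the reactions of the class metabolites,
    expansion follows :func:`expand_gene_set`, and the resulting gene set is
    intersected with the measured ``x_features``. Genes may belong to
    several groups. The final complement group collects every measured
    feature claimed by no class group. Classes whose metabolites are all
    unmeasured are skipped with a warning.
    """
    class_items = list(metabolite_classes.items())
    seen_met: set[str] = set()
    for cname, mets in class_items:
        mset = set(mets)
        if mset & seen_met:
            raise ValueError(
                f"metabolite classes overlap on {sorted(mset & seen_met)}"
            )
        seen_met |= mset
    x_set, y_set = set(x_features), set(y_features)
    groups: list[FunctionalGroup] = []
    used_genes: set[str] = set()
    used_mets: set[str] = set()
    for cname, mets in class_items:
        class_mets = set(mets) & y_set
        if not class_mets:
            warnings.warn(
                f"metabolite class {cname!r} has no measured metabolites; skipped",
                stacklevel=2,
            )
            continue
        seeds = seed_genes_for_metabolites(graph, class_mets)
        provenance = expand_gene_set(graph, seeds, params)
        genes = {g for g in provenance if g in x_set}
        groups.append(
            FunctionalGroup(
                name=cname,
                metabolite_ids=class_mets,
                gene_ids=genes,
                provenance={g: provenance[g] for g in genes},
                is_complement=False,
            )
        )
        used_genes |= genes
        used_mets |= class_mets
    leftover_genes = x_set - used_genes
    leftover_mets = y_set - used_mets
    groups.append(
        FunctionalGroup(
            name=complement_name,
            metabolite_ids=leftover_mets,
            gene_ids=leftover_genes,
            provenance={g: "seed" for g in leftover_genes},
            is_complement=True,
        )
    )
    return groups
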