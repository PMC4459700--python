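"""Synthetic paired omics data with planted latent-factor structure.

Emulates the shape of a small nutrigenomics study — 40 samples, ~120 genes,
~21 metabolites — in which a few functional groups of genes and metabolites
co-vary through shared latent factors. Each planted group has one standard-
normal factor per sample; a member feature is that factor times a loading
drawn uniformly from [loading_low, loading_high] with random sign, plus
independent Gaussian noise. Background features are pure noise. A matching
prior-knowledge graph is generated so the grouping stage can be tested end
to end: a fraction of each group's genes become reaction-linked seeds, the
rest attach to seeds by high-confidence interaction edges, and low-score
decoy edges are sprinkled among background genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import OmicsBlock, write_omics_matrix
from .prior_grouping import FunctionalGroup, KnowledgeGraph, build_knowledge_graph

__all__ = ["GroupSpec", "SyntheticSpec", "generate_multiomics", "generate_prior_graph", "write_study"]


@dataclass
class GroupSpec:
    """One planted group: sizes, loading range and noise level."""

    n_genes: int = 20
    n_metabolites: int = 5
    loading_low: float = 0.6
    loading_high: float = 0.9
    noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_metabolites < 0:
            raise ValueError("counts must be >= 0")
        if self.loading_low > self.loading_high:
            raise ValueError("loading_low must be <= loading_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticSpec:
    """Study-shaped defaults: 40 samples; 3 groups of 20 genes / 5
    metabolites each plus background to 120 genes and 21 metabolites;
    loadings 0.6-0.9, noise sd 0.6; 30% of each group's genes are reaction
    seeds; 5% decoy edge density among background genes."""

    n_samples: int = 40
    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec(), GroupSpec(), GroupSpec()]
    )
    n_background_genes: int = 60
    n_background_metabolites: int = 6
    seed_gene_fraction: float = 0.3
    decoy_edge_density: float = 0.05
    shared_gene_pairs: int = 0  # genes loading on two factors (APOA1-style)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_background_genes < 0 or self.n_background_metabolites < 0:
            raise ValueError("background counts must be >= 0")
        if not (0.0 < self.seed_gene_fraction <= 1.0):
            raise ValueError("seed_gene_fraction must be in (0, 1]")
        if not (0.0 <= self.decoy_edge_density <= 1.0):
            raise ValueError("decoy_edge_density must be in [0, 1]")


def _gene_id(i: int) -> str:
    return f"G{i:03d}"


def _met_id(i: int) -> str:
    return f"CHEBI:{10000 + i}"


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[OmicsBlock, OmicsBlock, list[FunctionalGroup]]:
    """Generate paired X (genes) and Y (metabolites) blocks plus the planted
    group truth. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_genes = sum(g.n_genes for g in spec.groups) + spec.n_background_genes
    n_mets = sum(g.n_metabolites for g in spec.groups) + spec.n_background_metabolites
    gene_ids = [_gene_id(i) for i in range(n_genes)]
    met_ids = [_met_id(i) for i in range(n_mets)]
    X = np.empty((n, n_genes))
    Y = np.empty((n, n_mets))
    truth: list[FunctionalGroup] = []
    gi = mi = 0
    factors = [rng.standard_normal(n) for _ in spec.groups]
    for g_idx, gspec in enumerate(spec.groups):
        f = factors[g_idx]
        genes = gene_ids[gi : gi + gspec.n_genes]
        for j in range(gspec.n_genes):
            a = rng.uniform(gspec.loading_low, gspec.loading_high)
            a *= rng.choice([-1.0, 1.0])
            X[:, gi + j] = a * f + rng.normal(0.0, gspec.noise_sd, size=n)
        mets = met_ids[mi : mi + gspec.n_metabolites]
        for j in range(gspec.n_metabolites):
            b = rng.uniform(gspec.loading_low, gspec.loading_high)
            b *= rng.choice([-1.0, 1.0])
            Y[:, mi + j] = b * f + rng.normal(0.0, gspec.noise_sd, size=n)
        truth.append(
            FunctionalGroup(
                name=f"planted_{g_idx + 1}",
                metabolite_ids=set(mets),
                gene_ids=set(genes),
                provenance={g: "seed" for g in genes},
                is_complement=False,
            )
        )
        gi += gspec.n_genes
        mi += gspec.n_metabolites
    # a few genes may additionally load on a second factor, emulating genes
    # shared between groups
    for _ in range(spec.shared_gene_pairs):
        if len(spec.groups) < 2 or gi == 0:
            break
        j = int(rng.integers(0, gi))
        other = int(rng.integers(0, len(spec.groups)))
        X[:, j] += rng.uniform(0.3, 0.5) * factors[other]
    X[:, gi:] = rng.standard_normal((n, n_genes - gi))
    Y[:, mi:] = rng.standard_normal((n, n_mets - mi))
    sample_ids = [f"S{i:02d}" for i in range(n)]
    return (
        OmicsBlock(sample_ids, gene_ids, X),
        OmicsBlock(sample_ids, met_ids, Y),
        truth,
    )


def generate_prior_graph(
    truth: list[FunctionalGroup], spec: SyntheticSpec
) -> KnowledgeGraph:
    """Build a prior graph consistent with the planted groups.

    Per group, ceil(seed_gene_fraction * n_genes) genes are reaction-linked
    to every group metabolite (roles alternating substrate/product); the
    remaining group genes are attached to seed genes with score-0.9 ppi
    edges. Background gene pairs get score-0.5 textmining decoy edges at the
    requested density. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    reaction_rows: list[dict] = []
    interaction_rows: list[dict] = []
    grouped_genes: set[str] = set()
    rid = 0
    for group in truth:
        genes = sorted(group.gene_ids)
        mets = sorted(group.metabolite_ids)
        grouped_genes |= set(genes)
        n_seed = math.ceil(spec.seed_gene_fraction * len(genes))
        seeds = genes[:n_seed]
        others = genes[n_seed:]
        for s_idx, g in enumerate(seeds):
            rid += 1
            for m_idx, m in enumerate(mets):
                role = "substrate" if (s_idx + m_idx) % 2 == 0 else "product"
                reaction_rows.append(
                    {
                        "metabolite_id": m,
                        "gene_id": g,
                        "reaction_id": f"R{rid:04d}",
                        "role": role,
                    }
                )
        for j, g in enumerate(others):
            anchor = seeds[j % len(seeds)]
            interaction_rows.append(
                {
                    "gene_a": anchor,
                    "gene_b": g,
                    "channel": "ppi",
                    "score": 0.9,
                    "directed": 0,
                }
            )
    # decoy edges among background genes, low confidence
    n_total = sum(g.n_genes for g in spec.groups) + spec.n_background_genes
    background = [
        _gene_id(i) for i in range(n_total) if _gene_id(i) not in grouped_genes
    ]
    for i in range(len(background)):
        for j in range(i + 1, len(background)):
            if rng.random() < spec.decoy_edge_density:
                interaction_rows.append(
                    {
                        "gene_a": background[i],
                        "gene_b": background[j],
                        "channel": "textmining",
                        "score": 0.5,
                        "directed": 0,
                    }
                )
    return build_knowledge_graph(
        pd.DataFrame(reaction_rows),
        pd.DataFrame(interaction_rows)
        if interaction_rows
        else pd.DataFrame(columns=["gene_a", "gene_b", "channel", "score", "directed"]),
        score_threshold=0.7,
    )


def write_study(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study in the TSV/GMT/YAML formats the
    pipeline reads, plus a truth JSON for tests. Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, Y, truth = generate_multiomics(spec)
    graph = generate_prior_graph(truth, spec)
    paths = {
        "expression": out / "expression.tsv",
        "metabolites": out / "metabolites.tsv",
        "reactions": out / "reactions.tsv",
        "interactions": out / "interactions.tsv",
        "classes": out / "metabolite_classes.yaml",
        "gene_sets": out / "pathways.gmt",
        "truth": out / "truth.json",
    }
    write_omics_matrix(X, paths["expression"])
    write_omics_matrix(Y, paths["metabolites"])
    pd.DataFrame(
        graph.reaction_edges,
        columns=["metabolite_id", "gene_id", "reaction_id", "role"],
    ).to_csv(paths["reactions"], sep="\t", index=False)
    pd.DataFrame(
        graph.interaction_edges,
        columns=["gene_a", "gene_b", "channel", "score", "directed"],
    ).assign(directed=lambda d: d["directed"].astype(int)).to_csv(
        paths["interactions"], sep="\t", index=False
    )
    classes = {g.name: sorted(g.metabolite_ids) for g in truth}
    with open(paths["classes"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(classes, fh, sort_keys=True)
    # pathway sets: each planted gene set as a pathway, plus random decoys
    rng = np.random.default_rng(spec.seed + 2)
    all_genes = list(X.feature_ids)
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        for g in truth:
            members = "\t".join(sorted(g.gene_ids))
            fh.write(f"PATH_{g.name}\tplanted group gene set\t{members}\n")
        for d in range(3):
            members = sorted(rng.choice(all_genes, size=12, replace=False))
            fh.write(f"PATH_decoy_{d}\trandom decoy set\t" + "\t".join(members) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "name": g.name,
                    "metabolite_ids": sorted(g.metabolite_ids),
                    "gene_ids": sorted(g.gene_ids),
                }
                for g in truth
            ],
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
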