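"""Ranking of gene candidates and hypergeometric over-representation.

Genes are ranked by the magnitude of their structural loading on the first
canonical variate (CCA) or first latent variable (PLS); genes removed by the
correlation prefilter re-enter the listing directly after their retained
representative, carrying its score, flagged as proxies. The top fraction of
distinct (non-proxy) genes is then categorized against the prior knowledge
(reaction seeds, lipid pathways, knowledge-base membership) and tested for
pathway over-representation with a one-sided hypergeometric test and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection
from .multivariate import CcaResult, PlsResult, RccaResult
from .prefilter import CONSTANT_SENTINEL, FilterReport

__all__ = [
    "RankedEntry",
    "RankedAssociations",
    "EnrichmentResult",
    "rank_candidates",
    "select_top",
    "categorize_candidates",
    "hypergeometric_enrichment",
]


@dataclass
class RankedEntry:
    gene_id: str
    score: float
    source: str  # "cca" or "pls"
    proxy_for: str | None = None


@dataclass
class RankedAssociations:
    """Ordered gene ranking for one group; scores non-increasing over
    non-proxy entries, proxies carry their representative's score."""

    entries: list[RankedEntry]
    group_name: str = ""

    def genes(self, include_proxies: bool = True) -> list[str]:
        return [
            e.gene_id for e in self.entries if include_proxies or e.proxy_for is None
        ]


@dataclass
class EnrichmentResult:
    """Per-set over-representation rows, sorted by FDR then p-value."""

    rows: list[dict] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [r for r in self.rows if r["fdr"] < alpha]


def rank_candidates(
    result: CcaResult | RccaResult | PlsResult,
    filter_report: FilterReport | None = None,
    feature_ids: list[str] | None = None,
    component: int = 1,
) -> RankedAssociations:
    """Rank X-block genes by |loading| on the chosen variate/component.

    ``feature_ids`` names the rows of the loading matrix (the retained,
    prefiltered features, in order); defaults to positional labels. Each
    prefilter-removed gene is appended directly after its representative
    with ``proxy_for`` set and the representative's score. Ties preserve
    feature input order (stable sort).
    """
    loadings = result.x_loadings
    k = component - 1
    if k < 0 or k >= loadings.shape[1]:
        raise ValueError(
            f"component {component} out of range (1..{loadings.shape[1]})"
        )
    source = "pls" if isinstance(result, PlsResult) else "cca"
    ids = feature_ids if feature_ids is not None else [
        f"x{j}" for j in range(loadings.shape[0])
    ]
    if len(ids) != loadings.shape[0]:
        raise ValueError("feature_ids length does not match loading rows")
    scores = np.abs(loadings[:, k])
    order = np.argsort(-scores, kind="stable")
    proxies: dict[str, list[str]] = {}
    if filter_report is not None:
        for removed, (rep, _r) in filter_report.removed.items():
            if rep != CONSTANT_SENTINEL:
                proxies.setdefault(rep, []).append(removed)
    entries: list[RankedEntry] = []
    for j in order:
        gid = ids[j]
        entries.append(RankedEntry(gid, float(scores[j]), source))
        for removed in proxies.get(gid, []):
            entries.append(
                RankedEntry(removed, float(scores[j]), source, proxy_for=gid)
            )
    return RankedAssociations(entries=entries)


def select_top(ranked: RankedAssociations, fraction: float = 0.10) -> list[str]:
    """First ceil(fraction * #distinct non-proxy genes) non-proxy genes.

    Ties at the boundary (equal scores) are all included.
    """
    if not ranked.entries:
        raise ValueError("ranking is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    non_proxy = [e for e in ranked.entries if e.proxy_for is None]
    k = math.ceil(fraction * len(non_proxy))
    if k >= len(non_proxy):
        return [e.gene_id for e in non_proxy]
    boundary = non_proxy[k - 1].score
    out = [e.gene_id for e in non_proxy[:k]]
    out += [e.gene_id for e in non_proxy[k:] if e.score == boundary]
    return out


def categorize_candidates(
    top: set[str] | list[str],
    seed_reaction_genes: set[str],
    lipid_pathway_genes: set[str],
    kb_universe: set[str],
) -> tuple[int, int, int]:
    """Count top genes (a) in reactions involving the detected metabolites,
    (b) in lipid pathways, (c) absent from the knowledge base. The first two
    categories are not exclusive."""
    top_set = set(top)
    in_reactions = len(top_set & set(seed_reaction_genes))
    in_pathways = len(top_set & set(lipid_pathway_genes))
    not_in_kb = len(top_set - set(kb_universe))
    return in_reactions, in_pathways, not_in_kb


def hypergeometric_enrichment(
    selected: set[str] | list[str],
    sets: GeneSetCollection,
    universe: set[str] | list[str],
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation with BH step-up FDR.

    Gene sets are intersected with the universe before testing; the p-value
    is P(overlap >= observed) under sampling ``|selected|`` genes from the
    universe. Rows are sorted by FDR, then p-value, then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected)
    if not sel <= uni:
        raise ValueError(
            f"selected genes outside universe: {sorted(sel - uni)}"
        )
    names, pvals, rows = [], [], []
    M, N = len(uni), len(sel)
    for name in sets.sets:
        members = sets.members(name) & uni
        n_set = len(members)
        overlap = len(members & sel)
        # P(X >= overlap), X ~ Hypergeom(M, n_set, N)
        p = float(stats.hypergeom.sf(overlap - 1, M, n_set, N))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": n_set,
                "selected_size": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    if rows:
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for row, adj in zip(rows, fdr):
            row["fdr"] = float(adj)
        rows.sort(key=lambda r: (r["fdr"], r["p_value"], r["set_name"]))
    return EnrichmentResult(rows=rows)
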