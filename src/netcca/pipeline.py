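"""End-to-end orchestration: load, group, analyze, null-check, rank, enrich.

The pipeline is a pure function of (input files, config, master seed). Each
randomized stage derives its own seed from the master seed by a fixed
offset, so stages can be re-run in isolation and reproduce the full run.
Results are written as TSV tables plus a single summary JSON whose per-group
entries carry canonical correlations (CV1, CV2) with Bartlett p-values,
aggregate redundancies in both directions, regularized-CCA correlations,
PLS explained-variance percentages for both blocks, retained/total feature
counts, null-model significance and enrichment hits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    GeneSetCollection,
    OmicsBlock,
    harmonize_identifiers,
    normalize_chebi_id,
    read_annotation_map,
    read_gene_sets,
    read_omics_matrix,
)
from .multivariate import (
    compute_cca,
    compute_pls,
    compute_rcca,
    select_lambda,
)
from .null_model import randomized_group_null
from .prefilter import prefilter_correlated
from .prior_grouping import (
    ExpansionParams,
    FunctionalGroup,
    KnowledgeGraph,
    assign_groups,
    build_knowledge_graph,
    seed_genes_for_metabolites,
)
from .ranking_enrichment import (
    categorize_candidates,
    hypergeometric_enrichment,
    rank_candidates,
    select_top,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets derived from the master seed
_SEED_LAMBDA_CV = 101
_SEED_NULL = 211


@dataclass
class PipelineConfig:
    """All inputs and knobs of a pipeline run.

    Paths are resolved relative to the config file when loaded with
    :meth:`from_yaml`. Thresholds default to the workflow's standard
    settings: |r| > 0.7 prefilter, 0.7 interaction-score retention,
    distance-1 network expansion, top 10% candidate fraction, B = 1000
    randomized groups.
    """

    expression: str = ""
    metabolites: str = ""
    reactions: str = ""
    interactions: str = ""
    metabolite_classes: str = ""
    gene_sets: str = ""
    gene_map: str | None = None
    metabolite_map: str | None = None

    correlation_threshold: float = 0.7
    score_threshold: float = 0.7
    max_distance: int = 1
    hub_percentile: float = 95.0
    use_circuits: bool = False
    circuit_length_bound: int = 4

    statistics: list[str] = field(default_factory=lambda: ["cca", "rcca", "pls"])
    rcca_lambda1: float | None = None
    rcca_lambda2: float | None = None
    lambda_grid: list[float] = field(default_factory=lambda: [0.001, 0.01, 0.1])
    lambda_folds: int = 5
    pls_components: int = 2
    pls_mode: str = "canonical"

    null_B: int = 1000
    null_statistics: list[str] = field(
        default_factory=lambda: ["cca_redundancy_y_given_x", "pls_explained_variance_lv1"]
    )
    top_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.correlation_threshold < 1.0):
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        unknown = set(self.statistics) - {"cca", "rcca", "pls"}
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        base = path.parent
        for attr in (
            "expression",
            "metabolites",
            "reactions",
            "interactions",
            "metabolite_classes",
            "gene_sets",
            "gene_map",
            "metabolite_map",
        ):
            val = getattr(cfg, attr)
            if val:
                p = Path(val)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"{attr}: {p}")
                setattr(cfg, attr, str(p))
        return cfg

    def expansion_params(self) -> ExpansionParams:
        return ExpansionParams(
            max_distance=self.max_distance,
            hub_percentile=self.hub_percentile,
            use_circuits=self.use_circuits,
            circuit_length_bound=self.circuit_length_bound,
        )


def _load_classes(path: str) -> dict[str, list[str]]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        str(name): [normalize_chebi_id(m) for m in members]
        for name, members in raw.items()
    }


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    return x


def _analyze_group(
    name: str,
    Xg: OmicsBlock,
    Yg: OmicsBlock,
    config: PipelineConfig,
    seed: int,
    require_cca_shape: bool = False,
) -> dict:
    """Prefilter both blocks and run the configured statistics on one
    (gene set, metabolite set) pair."""
    entry: dict[str, Any] = {
        "name": name,
        "x_total": Xg.n_features,
        "y_total": Yg.n_features,
        "skipped": {},
    }
    Xr, x_report = prefilter_correlated(Xg, config.correlation_threshold)
    Yr, y_report = prefilter_correlated(Yg, config.correlation_threshold)
    entry["x_retained"] = Xr.n_features
    entry["y_retained"] = Yr.n_features
    entry["x_removed"] = {
        f: {"representative": rep, "r": (None if np.isnan(r) else round(float(r), 6))}
        for f, (rep, r) in x_report.removed.items()
    }
    entry["y_removed"] = {
        f: {"representative": rep, "r": (None if np.isnan(r) else round(float(r), 6))}
        for f, (rep, r) in y_report.removed.items()
    }
    entry["_x_report"] = x_report
    entry["_y_report"] = y_report
    entry["_x_block"] = Xr
    entry["_y_block"] = Yr
    # a group whose collinear metabolites collapse to one retained column is
    # still analyzable (q = 1)
    if Xr.n_features < 2 or Yr.n_features < 1:
        entry["skipped"]["all"] = "too few retained features on one side"
        return entry
    n = Xr.n_samples
    if "cca" in config.statistics:
        if require_cca_shape and n <= Xr.n_features + Yr.n_features:
            entry["skipped"]["cca"] = (
                f"classical CCA needs n > p + q (n={n}, p={Xr.n_features}, "
                f"q={Yr.n_features}); structure unsuitable for the undivided set"
            )
        else:
            try:
                cca = compute_cca(Xr.values, Yr.values)
                entry["cca"] = {
                    "cv1": float(cca.correlations[0]),
                    "cv2": float(cca.correlations[1]) if len(cca.correlations) > 1 else None,
                    "p_cv1": float(cca.p_values[0]),
                    "p_cv2": float(cca.p_values[1]) if len(cca.p_values) > 1 else None,
                    "redundancy_y_given_x": cca.redundancy_y_given_x,
                    "redundancy_x_given_y": cca.redundancy_x_given_y,
                }
                entry["_cca"] = cca
            except np.linalg.LinAlgError as exc:
                entry["skipped"]["cca"] = str(exc)
    if "rcca" in config.statistics:
        if config.rcca_lambda1 is not None and config.rcca_lambda2 is not None:
            l1, l2 = config.rcca_lambda1, config.rcca_lambda2
        else:
            l1, l2, _ = select_lambda(
                Xr.values,
                Yr.values,
                config.lambda_grid,
                config.lambda_grid,
                n_folds=config.lambda_folds,
                seed=seed + _SEED_LAMBDA_CV,
            )
        rcca = compute_rcca(Xr.values, Yr.values, l1, l2)
        entry["rcca"] = {
            "cv1": float(rcca.correlations[0]),
            "cv2": float(rcca.correlations[1]) if len(rcca.correlations) > 1 else None,
            "lambda1": float(l1),
            "lambda2": float(l2),
        }
        entry["_rcca"] = rcca
    if "pls" in config.statistics:
        ncomp = min(
            config.pls_components,
            Xr.n_features,
            Yr.n_features if config.pls_mode == "canonical" else Xr.n_features,
            n - 1,
        )
        pls = compute_pls(Xr.values, Yr.values, ncomp, mode=config.pls_mode)
        entry["pls"] = {
            "explained_variance_x": [round(float(v), 6) for v in pls.explained_variance_x],
            "explained_variance_y": [round(float(v), 6) for v in pls.explained_variance_y],
            "n_components": pls.n_components,
        }
        entry["_pls"] = pls
    return entry


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Run the full workflow and write the report bundle to ``out_dir``.

    Stages: load and harmonize the two omics blocks; build the knowledge
    graph; derive functional groups (classes + complement); per group,
    prefilter and run CCA / rCCA / PLS, then the randomized-group null;
    rank candidates, categorize them against the priors and test pathway
    over-representation; finally analyze the undivided data (classical CCA
    only when n > p + q). Returns the summary report dict, also written as
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = config.seed if seed is None else seed

    logger.info("loading omics matrices")
    X = read_omics_matrix(config.expression)
    Y = read_omics_matrix(config.metabolites)
    dropped_genes: list[str] = []
    dropped_mets: list[str] = []
    if config.gene_map:
        X, dropped_genes = harmonize_identifiers(
            X, read_annotation_map(config.gene_map), drop_unmapped=True
        )
    if config.metabolite_map:
        Y, dropped_mets = harmonize_identifiers(
            Y, read_annotation_map(config.metabolite_map, chebi=True), drop_unmapped=True
        )
    Y = OmicsBlock(
        list(Y.sample_ids), [normalize_chebi_id(f) for f in Y.feature_ids], Y.values
    )
    if list(X.sample_ids) != list(Y.sample_ids):
        raise ValueError("expression and metabolite blocks disagree on samples")

    logger.info("building knowledge graph")
    graph = build_knowledge_graph(
        pd.read_csv(config.reactions, sep="\t", dtype=str),
        pd.read_csv(config.interactions, sep="\t"),
        score_threshold=config.score_threshold,
    )
    classes = _load_classes(config.metabolite_classes)
    groups = assign_groups(
        classes,
        graph,
        X.feature_ids,
        Y.feature_ids,
        params=config.expansion_params(),
    )
    logger.info("derived %d groups (incl. complement)", len(groups))

    gene_sets: GeneSetCollection | None = None
    if config.gene_sets:
        gene_sets = read_gene_sets(config.gene_sets)
    universe = set(X.feature_ids)
    lipid_pathway_genes = gene_sets.all_genes() if gene_sets else frozenset()
    kb_universe = set(graph.gene_nodes) | set(lipid_pathway_genes)

    report: dict[str, Any] = {
        "seed": master_seed,
        "n_samples": X.n_samples,
        "n_genes": X.n_features,
        "n_metabolites": Y.n_features,
        "dropped_unmapped_genes": dropped_genes,
        "dropped_unmapped_metabolites": dropped_mets,
        "groups": [],
        "undivided": None,
    }

    for g_idx, group in enumerate(groups):
        genes = sorted(set(group.gene_ids) & set(X.feature_ids))
        mets = sorted(set(group.metabolite_ids) & set(Y.feature_ids))
        entry: dict[str, Any]
        if len(genes) < 2 or len(mets) < 1:
            entry = {
                "name": group.name,
                "is_complement": group.is_complement,
                "skipped": {"all": "needs >= 2 genes and >= 1 metabolite"},
                "x_total": len(genes),
                "y_total": len(mets),
            }
            report["groups"].append(entry)
            continue
        Xg = X.subset([f for f in X.feature_ids if f in set(genes)])
        Yg = Y.subset([f for f in Y.feature_ids if f in set(mets)])
        entry = _analyze_group(group.name, Xg, Yg, config, master_seed)
        entry["is_complement"] = group.is_complement
        entry["provenance"] = dict(sorted(group.provenance.items()))

        # randomized-group null
        entry["null"] = {}
        if config.null_B >= 2 and "skipped" in entry and "all" not in entry["skipped"]:
            for s_idx, stat in enumerate(config.null_statistics):
                needed = "cca" if stat.startswith("cca_") else "pls"
                if needed not in config.statistics or needed not in entry:
                    entry["null"][stat] = {"skipped": f"{needed} not computed"}
                    continue
                try:
                    dist = randomized_group_null(
                        X,
                        Y,
                        group,
                        statistic=stat,
                        B=config.null_B,
                        seed=master_seed + _SEED_NULL + 17 * g_idx + s_idx,
                        threshold=config.correlation_threshold,
                    )
                except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                    entry["null"][stat] = {"skipped": str(exc)}
                    continue
                entry["null"][stat] = dist.summary()
                np.savetxt(
                    out / f"null_{group.name}_{stat}.tsv",
                    dist.null_values,
                    fmt="%.10g",
                    header=stat,
                    comments="",
                )

        # ranking, categorization, enrichment (PLS preferred, CCA fallback)
        rank_source = None
        if "_pls" in entry:
            rank_source = (entry["_pls"], "pls")
        elif "_cca" in entry:
            rank_source = (entry["_cca"], "cca")
        if rank_source is not None:
            result, src = rank_source
            ranked = rank_candidates(
                result,
                filter_report=entry["_x_report"],
                feature_ids=entry["_x_block"].feature_ids,
                component=1,
            )
            ranked.group_name = group.name
            top = select_top(ranked, config.top_fraction)
            seed_genes = (
                seed_genes_for_metabolites(graph, mets) & universe if mets else set()
            )
            cat = categorize_candidates(
                set(top), seed_genes, set(lipid_pathway_genes) & universe, kb_universe
            )
            entry["ranking"] = {
                "source": src,
                "top_fraction": config.top_fraction,
                "top_genes": top,
                "in_seed_reactions": cat[0],
                "in_lipid_pathways": cat[1],
                "not_in_knowledge_base": cat[2],
            }
            pd.DataFrame(
                [
                    {
                        "gene_id": e.gene_id,
                        "score": round(e.score, 6),
                        "source": e.source,
                        "proxy_for": e.proxy_for or "",
                    }
                    for e in ranked.entries
                ]
            ).to_csv(out / f"ranking_{group.name}.tsv", sep="\t", index=False)
            if gene_sets is not None and len(gene_sets) > 0:
                enr = hypergeometric_enrichment(set(top) & universe, gene_sets, universe)
                entry["enrichment"] = [
                    {
                        "set_name": r["set_name"],
                        "overlap": r["overlap"],
                        "p_value": float(f"{r['p_value']:.6g}"),
                        "fdr": float(f"{r['fdr']:.6g}"),
                    }
                    for r in enr.rows
                ]
                pd.DataFrame(enr.rows).to_csv(
                    out / f"enrichment_{group.name}.tsv", sep="\t", index=False
                )

        # per-group loadings table (CCA and rCCA, CV1)
        tables = {}
        for key in ("_cca", "_rcca"):
            if key in entry:
                res = entry[key]
                tables[key.lstrip("_") + "_loading_cv1"] = {
                    fid: round(float(res.x_loadings[j, 0]), 6)
                    for j, fid in enumerate(entry["_x_block"].feature_ids)
                }
        if tables:
            df = pd.DataFrame(tables)
            df.index.name = "feature"
            df.to_csv(out / f"loadings_{group.name}.tsv", sep="\t")

        for k in list(entry):
            if k.startswith("_"):
                del entry[k]
        report["groups"].append(entry)

    # undivided data: rCCA and PLS always; classical CCA only if n > p + q
    und_cfg = config
    entry = _analyze_group(
        "undivided", X, Y, und_cfg, master_seed, require_cca_shape=True
    )
    for k in list(entry):
        if k.startswith("_"):
            del entry[k]
    report["undivided"] = entry

    report = _jsonable(report)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", out / "summary.json")
    return report
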