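"""Aggregation of per-database miRNA->gene target edge lists.

Each source database contributes edges with a kappa-like confidence score;
edges below their database's threshold are dropped at load time. A
(miRNA, gene) pair is then ranked within its miRNA by the number of distinct
databases supporting it (support), breaking ties by the maximum score and
then gene ID, and each miRNA keeps at most a fixed number of targets
(50 by default). Cross-disease target sets are partitioned into Venn cells,
and gene sets can be joined against MeSH-style disease-term annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD",
    "DiseaseTargetSets",
    "load_edge_lists",
    "aggregate_targets",
    "disease_target_sets",
    "annotate_mesh",
]

DEFAULT_THRESHOLD = 0.6
EDGE_COLUMNS = ["mirna_id", "gene_id", "score", "source_db"]


@dataclass
class DiseaseTargetSets:
    sets: dict[str, set[str]]
    unique_per_disease: dict[str, set[str]]
    intersection_all: set[str]
    shared_two_or_more: set[str]
    pairwise_overlap: dict[tuple[str, str], int]
    venn_cells: dict[frozenset, set[str]] = field(default_factory=dict)


def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(Path(source), sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing columns: {missing}")
    return df[EDGE_COLUMNS]


def load_edge_lists(
    sources,
    per_db_thresholds: dict[str, float] | None = None,
    default_threshold: float | None = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Load edge tables, apply per-database score thresholds, dedupe.

    Edges with score below their database's threshold are removed
    (comparison is inclusive: score >= threshold is kept); duplicate
    (mirna, gene) rows within a database collapse to the maximum score.
    """
    per_db_thresholds = per_db_thresholds or {}
    frames = [_as_frame(s) for s in (sources if isinstance(sources, (list, tuple)) else [sources])]
    edges = pd.concat(frames, ignore_index=True)
    if edges.empty:
        raise ValueError("no edges loaded")

    kept = []
    for db, grp in edges.groupby("source_db", sort=False):
        thr = per_db_thresholds.get(db, default_threshold)
        if thr is None:
            raise ValueError(f"no score threshold for database {db!r} and no default")
        grp = grp[grp["score"] >= thr]
        grp = (
            grp.sort_values("score", ascending=False)
            .drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
        )
        kept.append(grp)
    out = pd.concat(kept, ignore_index=True) if kept else edges.iloc[0:0]
    return out.reset_index(drop=True)


def aggregate_targets(edges: pd.DataFrame, cap: int = 50) -> pd.DataFrame:
    """Collapse edges to ranked (miRNA, gene) targets.

    support = number of distinct source databases containing the pair; rank
    within each miRNA by support desc, max score desc, gene ID asc; at most
    ``cap`` targets are retained per miRNA.
    """
    if cap < 1:
        raise ValueError("cap must be at least 1")
    if edges.empty:
        raise ValueError("no edges to aggregate")
    agg = (
        edges.groupby(["mirna_id", "gene_id"], sort=False)
        .agg(support=("source_db", "nunique"), max_score=("score", "max"))
        .reset_index()
    )
    agg = agg.sort_values(
        ["mirna_id", "support", "max_score", "gene_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    agg["rank"] = agg.groupby("mirna_id").cumcount() + 1
    agg = agg[agg["rank"] <= cap].reset_index(drop=True)
    return agg[["mirna_id", "gene_id", "support", "max_score", "rank"]]


def disease_target_sets(per_disease: dict[str, set[str]]) -> DiseaseTargetSets:
    """Venn partition of per-disease predicted target gene sets."""
    if len(per_disease) < 2:
        raise ValueError("at least two diseases are required")
    diseases = list(per_disease)
    sets = {d: set(per_disease[d]) for d in diseases}
    union = set().union(*sets.values())

    cells: dict[frozenset, set[str]] = {}
    for gene in union:
        membership = frozenset(d for d in diseases if gene in sets[d])
        cells.setdefault(membership, set()).add(gene)

    unique = {
        d: cells.get(frozenset([d]), set()) for d in diseases
    }
    inter_all = cells.get(frozenset(diseases), set())
    shared = {g for m, gs in cells.items() if len(m) >= 2 for g in gs}
    pairwise = {}
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    return DiseaseTargetSets(
        sets=sets,
        unique_per_disease=unique,
        intersection_all=inter_all,
        shared_two_or_more=shared,
        pairwise_overlap=pairwise,
        venn_cells=cells,
    )


def annotate_mesh(
    genes,
    gene_to_mesh: pd.DataFrame,
    term_filter: str | list[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, list[str]]]:
    """Join genes against a (gene_id, mesh_term) table.

    ``term_filter`` is a regular expression (case-insensitive) or an explicit
    list of terms; None keeps every term. Returns (per-term gene sets,
    per-gene term lists). An empty result is valid.
    """
    genes = set(genes)
    df = gene_to_mesh[gene_to_mesh["gene_id"].isin(genes)]
    if term_filter is not None:
        if isinstance(term_filter, str):
            pat = re.compile(term_filter, re.IGNORECASE)
            df = df[df["mesh_term"].map(lambda t: bool(pat.search(str(t))))]
        else:
            df = df[df["mesh_term"].isin(set(term_filter))]
    per_term: dict[str, set[str]] = {}
    per_gene: dict[str, list[str]] = {}
    for gene, term in df[["gene_id", "mesh_term"]].itertuples(index=False):
        per_term.setdefault(term, set()).add(gene)
        per_gene.setdefault(gene, []).append(term)
    return per_term, per_gene
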