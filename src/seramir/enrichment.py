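"""Term enrichment of gene sets: two-sided hypergeometric tests with
step-down (Holm) Bonferroni correction, fold-enrichment reporting, and
ontology-level filtering.

A term annotating K of the N population genes and observed in k of the n
study genes gets an over-representation tail P(X >= k), an
under-representation tail P(X <= k), and a two-sided p-value of twice the
smaller tail capped at one. Fold enrichment is observed/expected with
expected = K*n/N. Terms can be restricted to a band of ontology depths,
where a term's level is its shortest-path distance from the root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_enrichment", "holm_adjust", "level_filter", "term_levels"]


def hypergeom_enrichment(
    study_genes,
    annotation: pd.DataFrame,
    population_genes,
    use_binomial: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment/depletion of ``study_genes`` within a population.

    ``annotation`` needs columns gene_id and term_id (term_name optional).
    ``use_binomial`` swaps the hypergeometric tails for their binomial
    approximation with success probability K/N. Terms annotating no
    population gene are skipped. Returns a table sorted by adjusted p with
    observed/expected counts, fold enrichment, direction, raw and Holm
    step-down adjusted p-values, and log10 fold enrichment.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study:
        raise ValueError("empty study gene set")
    if not study <= population:
        extra = sorted(study - population)[:5]
        raise ValueError(f"study genes outside the population: {extra}")

    ann = annotation[annotation["gene_id"].isin(population)]
    names = {}
    if "term_name" in ann.columns:
        names = ann.drop_duplicates("term_id").set_index("term_id")["term_name"].to_dict()

    N, n = len(population), len(study)
    rows = []
    for term, grp in ann.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        if use_binomial:
            p0 = K / N
            over = float(stats.binom.sf(k - 1, n, p0))
            under = float(stats.binom.cdf(k, n, p0))
        else:
            over = float(stats.hypergeom.sf(k - 1, N, K, n))
            under = float(stats.hypergeom.cdf(k, N, K, n))
        p_two = min(1.0, 2.0 * min(over, under))
        expected = K * n / N
        rows.append(
            {
                "term_id": term,
                "term_name": names.get(term, term),
                "observed": k,
                "expected": expected,
                "fold_enrichment": k / expected,
                "direction": "enriched" if k >= expected else "depleted",
                "p_raw": p_two,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "observed", "expected", "fold_enrichment",
                "direction", "p_raw", "p_adj", "log10_fold_enrichment",
            ]
        )
    result["p_adj"] = holm_adjust(result["p_raw"].to_numpy())
    with np.errstate(divide="ignore"):
        result["log10_fold_enrichment"] = np.log10(
            result["fold_enrichment"].replace(0, np.nan)
        )
    return result.sort_values(["p_adj", "p_raw", "term_id"], ignore_index=True)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down ('Bonferroni step down') adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def term_levels(
    ontology_edges: pd.DataFrame, roots: list[str] | None = None
) -> dict[str, int]:
    """Shortest-path depth of each term from the ontology root(s) (root = 0).

    ``ontology_edges`` is a (child_id, parent_id) table; it must be acyclic.
    Roots default to the terms that never appear as a child.
    """
    g = nx.DiGraph()
    for child, parent in ontology_edges[["child_id", "parent_id"]].itertuples(index=False):
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology contains a cycle")
    if roots is None:
        roots = [t for t in g.nodes if g.in_degree(t) == 0]
    if not roots:
        raise ValueError("no root terms found")
    lengths = nx.multi_source_dijkstra_path_length(g, set(roots))
    return {term: int(d) for term, d in lengths.items()}


def level_filter(
    terms,
    ontology_edges: pd.DataFrame,
    min_level: int = 4,
    max_level: int = 16,
    roots: list[str] | None = None,
) -> list:
    """Retain terms whose ontology level lies in [min_level, max_level].

    Terms absent from the ontology are dropped.
    """
    levels = term_levels(ontology_edges, roots=roots)
    return [
        t for t in terms if t in levels and min_level <= levels[t] <= max_level
    ]
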