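"""Over-representation analysis against a hierarchical pathway ontology.

Single-list ORA (one-sided hypergeometric with BH control and a Cramér's V
effect size), pooling of child results onto ancestor pathways where a
parent's significance is that of its most significant child, and a combined
multi-list analysis in which genes shared between query lists contribute
fractionally to per-list pathway pie contributions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr

__all__ = ["ora", "cramers_v", "pool_to_parents", "combined_enrichment"]


def cramers_v(table) -> float:
    """Cramér's V for a contingency table (no continuity correction).

    sqrt(chi^2 / (n * min(rows-1, cols-1))); equals |phi| for 2x2 tables.
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return 0.0
    chi2 = stats.chi2_contingency(t[rows > 0][:, cols > 0], correction=False)[0]
    k = min((rows > 0).sum(), (cols > 0).sum())
    return float(np.sqrt(chi2 / (n * (k - 1))))


def ora(
    query: set,
    universe: set,
    annotations: dict[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    ``annotations`` maps pathway id -> gene set; annotations are intersected
    with the universe, pathways with no universe genes are skipped, and BH
    q-values are computed across the tested pathways.
    """
    query, universe = set(query), set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    n_u, n_q = len(universe), len(query)
    rows = []
    genes_col = []
    for pw, genes in annotations.items():
        ann = genes & universe
        if not ann:
            continue
        overlap_genes = sorted(query & ann)
        k, m = len(overlap_genes), len(ann)
        p = float(stats.hypergeom.sf(k - 1, n_u, m, n_q))
        v = cramers_v([[k, n_q - k], [m - k, n_u - n_q - (m - k)]])
        rows.append((pw, k, n_q, m, n_u, p, v))
        genes_col.append(overlap_genes)
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway", "overlap", "query_size", "pathway_size",
            "universe_size", "p_value", "cramers_v",
        ],
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out["contributing_genes"] = genes_col if len(out) else []
    out["significant"] = out["q_value"] < alpha if len(out) else []
    return out.set_index("pathway")


def _ontology_graph(hierarchy: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(hierarchy[["parent", "child"]].itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("pathway hierarchy contains a cycle")
    return g


def pool_to_parents(
    results: pd.DataFrame, hierarchy: pd.DataFrame, levels: int = 3
) -> pd.DataFrame:
    """Propagate enrichment onto ancestors: parent p = min descendant p.

    For every ancestor within ``levels`` edges above a tested pathway, the
    pooled p-value (and the q-value it carries) is that of its most
    significant tested descendant; pooled contributing genes are the union
    over tested descendants. Tested nodes themselves are retained, so the
    output contains child results alongside pooled ancestors.
    """
    g = _ontology_graph(hierarchy)
    tested = set(results.index)
    pooled: dict[str, dict] = {}
    for node in tested:
        row = results.loc[node]
        pooled[node] = {
            "p_value": float(row["p_value"]),
            "q_value": float(row["q_value"]),
            "contributing_genes": set(row["contributing_genes"]),
            "n_pooled": 1,
            "source": node,
        }
    for node in tested:
        if node not in g:
            continue
        row = results.loc[node]
        frontier = {node}
        for _ in range(levels):
            frontier = {p for c in frontier for p in g.predecessors(c)}
            if not frontier:
                break
            for anc in frontier:
                cur = pooled.get(anc)
                if cur is None:
                    pooled[anc] = {
                        "p_value": float(row["p_value"]),
                        "q_value": float(row["q_value"]),
                        "contributing_genes": set(row["contributing_genes"]),
                        "n_pooled": 1,
                        "source": node,
                    }
                else:
                    cur["contributing_genes"] |= set(row["contributing_genes"])
                    cur["n_pooled"] += 1
                    if float(row["p_value"]) < cur["p_value"]:
                        cur["p_value"] = float(row["p_value"])
                        cur["q_value"] = float(row["q_value"])
                        cur["source"] = node
    out = pd.DataFrame.from_dict(pooled, orient="index")
    out.index.name = "pathway"
    out["contributing_genes"] = out["contributing_genes"].map(sorted)
    return out.sort_values("p_value")


def combined_enrichment(
    lists: dict[str, set],
    universe: set,
    annotations: dict[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA on the union of labeled gene lists with per-list contributions.

    A gene annotated to a pathway contributes 1/(number of lists containing
    it) to each of those lists; per-pathway contributions are normalized by
    the overlap so they sum to 1 over lists.
    """
    union = set().union(*lists.values()) if lists else set()
    if not union:
        raise ValueError("union of query lists is empty")
    res = ora(union, universe, annotations, alpha)
    membership = {
        g: [lab for lab, s in lists.items() if g in s] for g in union
    }
    contribs = []
    for pw, row in res.iterrows():
        overlap_genes = row["contributing_genes"]
        weights = dict.fromkeys(lists, 0.0)
        for g in overlap_genes:
            labs = membership[g]
            for lab in labs:
                weights[lab] += 1.0 / len(labs)
        total = sum(weights.values())
        if total > 0:
            weights = {lab: w / total for lab, w in weights.items()}
        contribs.append(weights)
    res["per_list_contribution"] = contribs
    return res
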