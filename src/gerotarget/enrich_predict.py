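"""GO biological-process enrichment and Group-4 candidate prediction.

Hypergeometric upper-tail enrichment is run separately on three query sets:
lifespan-extending targets (Groups 1 and 2), lifespan-shortening targets
(Group 3), and targets unexplored in lifespan studies (Group 4).  Terms
enriched (BH FDR < 0.05) in BOTH the extenders and Group 4 but NOT in
Group 3 nominate the Group-4 genes annotated to them as unexplored
dual-purpose candidates, each reported with its supporting terms.

Term sets are flat gene sets (no ontology-graph propagation); the universe
defaults to all genes carrying at least one biological-process annotation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

from .meta_rank import bh_fdr

__all__ = [
    "hypergeom_upper_tail",
    "enrich_gene_set",
    "overlap_terms",
    "candidate_genes",
]


class EnrichError(ValueError):
    pass


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed via the stable log-space survival function.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise EnrichError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_set(
    query_genes: Iterable[str],
    term_gene_sets: Mapping[str, Set[str]],
    universe: Iterable[str],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against flat term sets.

    Only terms overlapping the query (k >= 1) are tested; BH FDR is applied
    across tested terms.  Term sets and the query are intersected with the
    universe first.
    """
    universe = set(universe)
    query_genes = set(query_genes)
    query = query_genes & universe
    if not universe:
        raise EnrichError("empty universe")
    if not query:
        raise EnrichError("empty query (after universe intersection)")
    if not query_genes <= universe:
        raise EnrichError("query genes outside the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in term_gene_sets.items():
        members = set(genes) & universe
        k = len(members & query)
        if k == 0:
            continue
        K = len(members)
        rows.append(
            {
                "term_id": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out["enriched"] = out["fdr"] < fdr_cut
        out = out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out


def overlap_terms(
    enriched_extenders: Iterable[str],
    enriched_g3: Iterable[str],
    enriched_g4: Iterable[str],
) -> set:
    """Terms enriched in the lifespan extenders AND Group 4 but NOT Group 3."""
    return (set(enriched_extenders) & set(enriched_g4)) - set(enriched_g3)


def candidate_genes(
    overlap_term_set: Iterable[str],
    group4_genes: Iterable[str],
    term_gene_sets: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Group-4 genes annotated to at least one overlap term.

    Returns one row per candidate with its supporting terms, sorted by the
    number of supporting terms (descending) then gene id.
    """
    overlap = set(overlap_term_set)
    g4 = list(dict.fromkeys(group4_genes))
    rows = []
    for gene in g4:
        support = sorted(t for t in overlap if gene in term_gene_sets.get(t, ()))
        if support:
            rows.append(
                {
                    "gene_id": gene,
                    "supporting_terms": tuple(support),
                    "n_supporting": len(support),
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "supporting_terms", "n_supporting"])
    if len(out):
        out = out.sort_values(
            ["n_supporting", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
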