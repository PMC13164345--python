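"""Hypergeometric over-representation analysis with comparator-specificity filtering.

The query (e.g. the up- or downregulated half of a DEG list) is tested against
each gene set in a user-supplied collection restricted to a universe — by
convention the genes actually tested in the source analysis. The p-value for a
term with K universe members, query size n and overlap k is the hypergeometric
upper tail P(X >= k) on a universe of size N; BH correction runs across the
tested terms of each direction separately.

Drug-specific terms are those significant (FDR and minimum overlap count) in
the primary run but not significant in the comparator run; terms absent from
the comparator table count as not significant.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .countio import GeneSetCollection
from .diffexpr import bh_adjust


class EnrichError(ValueError):
    pass


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    k = overlap, K = gene-set size in the universe, n = query size,
    N = universe size.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise EnrichError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(query: Iterable[str], collection: GeneSetCollection,
            universe: Iterable[str]) -> pd.DataFrame:
    """Over-representation of one query list against every term with at least
    one universe member.

    Returns a frame indexed by term id with columns description, k (overlap),
    K (set size in universe), n (query size), N (universe size), gene_ratio,
    p, fdr and the overlapping gene ids, sorted by p.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        raise EnrichError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for term in collection.term_ids():
        members = collection.members(term) & universe
        K = len(members)
        if K == 0:
            continue
        overlap = members & query
        k = len(overlap)
        rows.append({
            "term_id": term,
            "description": collection.description(term),
            "k": k, "K": K, "n": n, "N": N,
            "gene_ratio": k / n if n else np.nan,
            "p": hypergeom_p(k, K, n, N),
            "genes": ",".join(sorted(overlap)),
        })
    if not rows:
        return pd.DataFrame(
            columns=["description", "k", "K", "n", "N", "gene_ratio", "p", "fdr", "genes"]
        ).rename_axis("term_id")
    table = pd.DataFrame(rows).set_index("term_id")
    table["fdr"] = bh_adjust(table["p"])
    return table.sort_values(["p", "term_id"], kind="stable")


def split_by_direction(de_like: pd.DataFrame, fdr_max: float = 0.05,
                       down_log2fc_max: float | None = None,
                       up_log2fc_min: float | None = None,
                       fc_column: str = "log2fc", fdr_column: str = "fdr",
                       ) -> dict[str, set[str]]:
    """Direction-split query sets from a DE- or meta-result table.

    ``down_log2fc_max`` (e.g. -1.0) additionally requires the downregulated
    query to fall below that log2FC; ``up_log2fc_min`` is the mirror option.
    """
    sig = (de_like[fdr_column] < fdr_max).fillna(False)
    fc = de_like[fc_column]
    up = sig & (fc > (up_log2fc_min if up_log2fc_min is not None else 0.0))
    down = sig & (fc < (down_log2fc_max if down_log2fc_max is not None else 0.0))
    return {"up": set(de_like.index[up]), "down": set(de_like.index[down])}


def run_ora_directional(queries: Mapping[str, Iterable[str]],
                        collection: GeneSetCollection,
                        universe: Iterable[str]) -> dict[str, pd.DataFrame]:
    """One ORA table per direction (BH within each direction)."""
    return {direction: run_ora(genes, collection, universe)
            for direction, genes in queries.items()}


def specificity_filter(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       fdr_max: float = 0.05, min_count: int = 10,
                       annotate_fdr: float | None = None) -> pd.DataFrame:
    """Terms significant in A (fdr < fdr_max and k >= min_count) but not
    significant in B; terms absent from B count as not significant.

    Both tables must come from the same collection run (same universe-restricted
    term statistics are reported side by side). ``annotate_fdr`` adds an
    optional column flagging whether the comparator FDR also exceeds a looser
    reporting threshold (e.g. 0.2)."""
    if len(set(table_a.index) & set(table_b.index)) == 0 and len(table_b):
        raise EnrichError("tables share no terms; were they run on the same collection?")
    keep = table_a[(table_a["fdr"] < fdr_max) & (table_a["k"] >= min_count)]
    b_fdr = table_b["fdr"].reindex(keep.index)
    specific = keep[~(b_fdr < fdr_max).fillna(False)].copy()
    specific["comparator_fdr"] = table_b["fdr"].reindex(specific.index)
    specific["comparator_k"] = table_b["k"].reindex(specific.index)
    if annotate_fdr is not None:
        cf = specific["comparator_fdr"]
        specific[f"comparator_fdr_above_{annotate_fdr}"] = ~(cf < annotate_fdr).fillna(False)
    return specific
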