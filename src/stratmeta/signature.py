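"""Cross-cluster concordance, correlation networks and drug-specific signatures.

Pairwise Pearson correlations of genome-wide log2 fold-change vectors quantify
how concordant the cluster-wise responses are; the correlation structure is
viewed as a complete weighted graph (edge weight |r|) whose betweenness
centrality — computed on shortest paths with distance 1 - |r| — highlights the
contrast most "between" the others. Cross-dataset reproducibility is summarized
by set overlap of retained genes with an externally significant DEG set plus
sign concordance, and drug specificity by set difference of retained sets from
two runs under identical criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .countio import CountMatrix, SampleTable


class SignatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fold-change correlations


def fc_correlations(profile: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Pairwise Pearson r of log2FC vectors with Fisher-z confidence intervals.

    ``profile`` is genes x contrasts; each pair uses its pairwise-complete
    genes. Returns a long frame (contrast_a, contrast_b, r, ci_low, ci_high, n);
    a pair with < 4 complete genes or a constant vector gets r = NaN.
    """
    cols = list(profile.columns)
    zcrit = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = profile[[a, b]].dropna()
            n = len(pair)
            r = np.nan
            lo = hi = np.nan
            if n >= 4 and pair[a].std() > 0 and pair[b].std() > 0:
                r = float(np.corrcoef(pair[a], pair[b])[0, 1])
                if abs(r) < 1 and n > 3:
                    zr = np.arctanh(r)
                    half = zcrit / np.sqrt(n - 3)
                    lo, hi = float(np.tanh(zr - half)), float(np.tanh(zr + half))
            rows.append({"contrast_a": a, "contrast_b": b, "r": r,
                         "ci_low": lo, "ci_high": hi, "n": n})
    return pd.DataFrame(rows)


def correlation_matrix(long: pd.DataFrame, contrasts: list[str] | None = None) -> pd.DataFrame:
    """Square symmetric r matrix from the long-form correlation table."""
    if contrasts is None:
        contrasts = sorted(set(long["contrast_a"]) | set(long["contrast_b"]))
    mat = pd.DataFrame(np.eye(len(contrasts)), index=contrasts, columns=contrasts)
    for _, row in long.iterrows():
        mat.loc[row["contrast_a"], row["contrast_b"]] = row["r"]
        mat.loc[row["contrast_b"], row["contrast_a"]] = row["r"]
    return mat


# ---------------------------------------------------------------------------
# correlation network


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    nodes: pd.DataFrame          # betweenness per contrast
    edges: pd.DataFrame          # r, |r|, distance per pair


def build_network(corr: pd.DataFrame, normalized: bool = False) -> CorrelationNetwork:
    """Weighted graph over contrasts: edge weight |r|, betweenness on 1 - |r|.

    Pairs with missing correlation get no edge. Betweenness is reported as raw
    shortest-path counts by default (``normalized=False``), so a 5-node star's
    center scores C(4,2) = 6.
    """
    contrasts = list(corr.columns)
    if len(contrasts) < 3:
        raise SignatureError("network needs at least 3 contrasts")
    g = nx.Graph()
    g.add_nodes_from(contrasts)
    rows = []
    for i, a in enumerate(contrasts):
        for b in contrasts[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                continue
            dist = 1.0 - abs(float(r))
            g.add_edge(a, b, weight=abs(float(r)), r=float(r), distance=dist)
            rows.append({"contrast_a": a, "contrast_b": b, "r": float(r),
                         "abs_r": abs(float(r)), "distance": dist})
    btw = nx.betweenness_centrality(g, weight="distance", normalized=normalized)
    nodes = pd.DataFrame({"betweenness": pd.Series(btw)}).rename_axis("contrast")
    return CorrelationNetwork(graph=g, nodes=nodes, edges=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# set-level signatures


def intersect_cluster_degs(sig_sets: dict[int, set[str]],
                           de_tables: dict[int, pd.DataFrame] | None = None,
                           ) -> tuple[set[str], pd.DataFrame]:
    """Genes significant in every cluster-wise contrast, with their sign pattern.

    Returns the intersection and, when the DE tables are supplied, a per-gene
    table of log2FC signs per cluster plus a ``concordant`` flag (all signs
    equal)."""
    if len(sig_sets) < 2:
        raise SignatureError("need at least two DEG sets")
    common = set.intersection(*sig_sets.values()) if sig_sets else set()
    if de_tables is None:
        return common, pd.DataFrame(index=pd.Index(sorted(common), name="gene"))
    rows = {}
    for cid, tab in sorted(de_tables.items()):
        rows[f"sign_cluster{cid}"] = np.sign(
            tab["log2fc"].reindex(sorted(common))).astype("Int64")
    signs = pd.DataFrame(rows, index=pd.Index(sorted(common), name="gene"))
    if len(signs.columns):
        arr = signs.to_numpy(dtype=float)
        concordant = np.all(arr == arr[:, [0]], axis=1) & np.all(arr != 0, axis=1)
        signs["concordant"] = concordant
    return common, signs


@dataclass
class OverlapReport:
    """Cross-dataset overlap of a retained meta-signature with an external DE run."""

    shared: set[str]
    concordant: set[str]
    discordant: set[str]
    effects: pd.DataFrame        # per shared gene: pooled vs external log2FC
    meta_retained: set[str] = field(default_factory=set)
    external_significant: set[str] = field(default_factory=set)


def cross_dataset_overlap(meta: pd.DataFrame, external: pd.DataFrame,
                          external_fdr: float = 0.05) -> OverlapReport:
    """shared = retained ∩ externally significant; concordant = sign agreement.

    ``meta`` is a MetaResultTable (needs retained, pooled_log2fc); ``external``
    a DEResultTable (needs fdr, log2fc). The two gene-id namespaces must
    intersect."""
    if not (set(meta.index) & set(external.index)):
        raise SignatureError("no shared gene ids between meta and external tables")
    retained = set(meta.index[meta["retained"]])
    ext_sig = set(external.index[(external["fdr"] < external_fdr).fillna(False)])
    shared = retained & ext_sig
    rows = []
    concordant, discordant = set(), set()
    for g in sorted(shared):
        pm = float(meta.loc[g, "pooled_log2fc"])
        pe = float(external.loc[g, "log2fc"])
        agree = np.sign(pm) == np.sign(pe) and pm != 0 and pe != 0
        (concordant if agree else discordant).add(g)
        rows.append({"gene": g, "pooled_log2fc": pm, "external_log2fc": pe,
                     "concordant": bool(agree)})
    effects = pd.DataFrame(rows).set_index("gene") if rows else \
        pd.DataFrame(columns=["pooled_log2fc", "external_log2fc", "concordant"])
    return OverlapReport(shared=shared, concordant=concordant, discordant=discordant,
                         effects=effects, meta_retained=retained,
                         external_significant=ext_sig)


def drug_specific_genes(primary_retained: set[str], comparator_retained: set[str],
                        primary_criteria=None, comparator_criteria=None,
                        ) -> tuple[set[str], set[str]]:
    """Genes retained under the primary drug but not the comparator.

    Returns (primary-specific, symmetric difference). When criteria objects are
    supplied for both runs they must be identical — the comparison is only
    meaningful like for like."""
    if primary_criteria is not None or comparator_criteria is not None:
        if primary_criteria != comparator_criteria:
            raise SignatureError("retention criteria differ between the two runs")
    specific = set(primary_retained) - set(comparator_retained)
    sym = set(primary_retained) ^ set(comparator_retained)
    return specific, sym


def external_de(m: CountMatrix, samples: SampleTable, drug_label: str,
                vehicle: str = "DMSO", contrast_id: str = "external") -> pd.DataFrame:
    """Unstratified DE with a treatment-only design (no clustering, no covariates)."""
    design = diffexpr.DesignSpec(treatment=drug_label, vehicle=vehicle, covariates=[])
    return diffexpr.run_contrast(m, samples, design, contrast_id=contrast_id)


def fold_change_profile(de_tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Genes x contrasts matrix of log2FC (NaN where untested/unconverged)."""
    cols = {}
    for cid, tab in sorted(de_tables.items()):
        name = str(tab["contrast_id"].iloc[0]) if len(tab) else f"cluster{cid}"
        fc = tab["log2fc"].where(tab["converged"].fillna(False))
        cols[name] = fc
    return pd.DataFrame(cols)


def fc_distribution_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast log2FC distribution summary (median, IQR, n) — the data
    behind violin-style displays."""
    rows = []
    for c in profile.columns:
        v = profile[c].dropna()
        q1, q3 = (np.percentile(v, [25, 75]) if len(v) else (np.nan, np.nan))
        rows.append({"contrast": c, "n": len(v),
                     "median": float(v.median()) if len(v) else np.nan,
                     "q1": q1, "q3": q3,
                     "iqr": q3 - q1 if len(v) else np.nan})
    return pd.DataFrame(rows).set_index("contrast")
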