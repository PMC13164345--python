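"""Inverse-variance fixed-effect meta-analysis of per-cluster effect estimates.

Per gene, the cluster-wise log2 fold-change estimates b_i with standard errors
se_i are pooled with weights w_i = se_i^-2:

    b  = sum(w_i b_i) / sum(w_i)        se = (sum w_i)^(-1/2)
    z  = b / se                          p = two-sided normal
    Q  = sum w_i (b_i - b)^2             I^2 = max(0, (Q - (n-1)) / Q) * 100

A gene is retained as a meta-DEG iff it (1) has estimates in at least
``min_contrasts`` contrasts, (2) at least ``min_sign_consistent`` of its
estimates share the sign of the pooled estimate (exact zeros count as
inconsistent), (3) I^2 < ``i2_max_percent``, and (4) meta p < ``meta_p_max``.
Retained genes absent from every cluster-level FDR-significant DEG list are
classified as meta-only; those present in at least one list as
meta-overlapping.

Criteria (1) and (2) are applied jointly and literally, so with the defaults a
gene measured in only 2–3 contrasts can never be retained (criterion 2
dominates); ``relax_sign_to_available=True`` relaxes criterion 2 to
min(min_sign_consistent, n available) for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class MetaCriteria:
    min_contrasts: int = 2
    min_sign_consistent: int = 4
    i2_max_percent: float = 50.0
    meta_p_max: float = 0.05
    relax_sign_to_available: bool = False

    def __post_init__(self) -> None:
        if self.min_contrasts < 1 or self.min_sign_consistent < 1:
            raise MetaError("criteria counts must be positive")
        if not 0 < self.i2_max_percent <= 100:
            raise MetaError("i2_max_percent must lie in (0, 100]")
        if not 0 < self.meta_p_max <= 1:
            raise MetaError("meta_p_max must lie in (0, 1]")


def fixed_effect_pool(estimates, standard_errors) -> tuple[float, float, float, float]:
    """Closed-form IVW fixed-effect pool: (pooled b, pooled se, z, two-sided p)."""
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if b.size == 0:
        raise MetaError("need at least one estimate")
    if (se <= 0).any() or np.isnan(se).any():
        raise MetaError("all standard errors must be positive")
    w = se**-2
    pooled = float((w * b).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return pooled, pooled_se, float(z), p


def heterogeneity(estimates, standard_errors, pooled: float) -> tuple[float, float]:
    """Cochran's Q and I^2 (percent, clamped to [0, 100]; I^2 = 0 when Q = 0)."""
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if b.size < 2:
        return np.nan, np.nan
    w = se**-2
    Q = float((w * (b - pooled) ** 2).sum())
    if Q == 0:
        return 0.0, 0.0
    i2 = max(0.0, (Q - (b.size - 1)) / Q) * 100.0
    return Q, i2


def apply_criteria(row: pd.Series, criteria: MetaCriteria) -> pd.Series:
    """Evaluate the four retention criteria on one gene's meta row.

    Expects fields n_contrasts, n_sign_consistent, i2_percent, meta_p.
    Genes with < 2 estimates have undefined I^2, so criterion 3 fails for them
    by definition.
    """
    need_consistent = criteria.min_sign_consistent
    if criteria.relax_sign_to_available:
        need_consistent = min(need_consistent, int(row["n_contrasts"]))
    c1 = row["n_contrasts"] >= criteria.min_contrasts
    c2 = row["n_sign_consistent"] >= need_consistent
    i2 = row["i2_percent"]
    c3 = bool(np.isfinite(i2) and i2 < criteria.i2_max_percent)
    p = row["meta_p"]
    c4 = bool(np.isfinite(p) and p < criteria.meta_p_max)
    return pd.Series({
        "pass_min_contrasts": bool(c1),
        "pass_sign_consistency": bool(c2),
        "pass_low_heterogeneity": c3,
        "pass_meta_p": c4,
        "retained": bool(c1 and c2 and c3 and c4),
    })


def run_meta(de_tables: dict[int, pd.DataFrame] | list[pd.DataFrame],
             criteria: MetaCriteria = MetaCriteria(),
             cluster_fdr_max: float = 0.05) -> pd.DataFrame:
    """Pool per-cluster DE tables into a MetaResultTable.

    Genes are aligned by id across contrasts; a gene absent from a contrast
    (or unconverged there) simply contributes no estimate. Output columns:
    pooled_log2fc, pooled_se, z, meta_p, Q, i2_percent, n_contrasts,
    n_sign_consistent, the four criterion flags, retained, and class
    (meta-only / meta-overlapping / not-retained).
    """
    if isinstance(de_tables, dict):
        items = sorted(de_tables.items())
    else:
        items = list(enumerate(de_tables, start=1))
    if len(items) < 2:
        raise MetaError("need at least two contrast tables")

    usable = {}
    sig_sets = {}
    for cid, tab in items:
        ok = tab["converged"].fillna(False) & tab["log2fc"].notna() & (tab["se"] > 0)
        usable[cid] = tab.loc[ok, ["log2fc", "se"]]
        sig_sets[cid] = set(tab.index[(tab["fdr"] < cluster_fdr_max).fillna(False)])

    all_genes = sorted(set().union(*(set(t.index) for t in usable.values())))
    if not all_genes:
        raise MetaError("no gene has a usable estimate in any contrast")

    cids = [cid for cid, _ in items]
    b_mat = pd.DataFrame(np.nan, index=all_genes, columns=cids)
    se_mat = pd.DataFrame(np.nan, index=all_genes, columns=cids)
    for cid, tab in usable.items():
        b_mat.loc[tab.index, cid] = tab["log2fc"]
        se_mat.loc[tab.index, cid] = tab["se"]

    b = b_mat.to_numpy()
    se = se_mat.to_numpy()
    have = np.isfinite(b) & np.isfinite(se) & (se > 0)
    w = np.where(have, 1.0 / np.where(have, se, 1.0) ** 2, 0.0)
    n_contrasts = have.sum(axis=1)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(wsum > 0, (w * np.where(have, b, 0.0)).sum(axis=1) / wsum, np.nan)
        pooled_se = np.where(wsum > 0, wsum**-0.5, np.nan)
        z = pooled / pooled_se
    meta_p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    resid = np.where(have, b - pooled[:, None], 0.0)
    Q = (w * resid**2).sum(axis=1)
    Q = np.where(n_contrasts >= 2, Q, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = np.where(Q > 0, np.maximum(0.0, (Q - (n_contrasts - 1)) / Q) * 100.0, 0.0)
    i2 = np.where(n_contrasts >= 2, i2, np.nan)

    sign_match = have & (np.sign(b) == np.sign(pooled)[:, None]) & (b != 0)
    n_consistent = sign_match.sum(axis=1)

    meta = pd.DataFrame({
        "pooled_log2fc": pooled,
        "pooled_se": pooled_se,
        "z": z,
        "meta_p": meta_p,
        "Q": Q,
        "i2_percent": i2,
        "n_contrasts": n_contrasts,
        "n_sign_consistent": n_consistent,
    }, index=pd.Index(all_genes, name="gene"))

    flags = meta.apply(lambda row: apply_criteria(row, criteria), axis=1)
    meta = pd.concat([meta, flags], axis=1)
    meta["class"] = classify_meta_degs(meta, sig_sets)
    return meta


def classify_meta_degs(meta: pd.DataFrame,
                       cluster_sig_sets: dict[int, set[str]]) -> pd.Series:
    """meta-only (retained, in no cluster DEG list), meta-overlapping
    (retained, in >= 1 list) or not-retained."""
    in_any = pd.Series(False, index=meta.index)
    for genes in cluster_sig_sets.values():
        in_any |= meta.index.isin(list(genes))
    labels = np.where(
        ~meta["retained"], "not-retained",
        np.where(in_any, "meta-overlapping", "meta-only"))
    return pd.Series(labels, index=meta.index, name="class")


def retained_genes(meta: pd.DataFrame) -> set[str]:
    return set(meta.index[meta["retained"]])
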