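"""Model/Results interface for the stratified-control meta-DE workflow.

`StratifiedMetaDE` is built from a count matrix and a sample table and, on
``fit()``, runs the full discovery workflow:

1. median-of-ratios size factors and the log2(count/sf + 1) transform;
2. variable-gene selection and PCA on the vehicle controls only;
3. k-means stratification of the controls in PC space (k fixed, or chosen
   from a stability report), with treated samples projected into the control
   embedding but never clustering;
4. per-cluster negative-binomial Wald contrasts with the design
   intercept + PC1..PCm + treatment;
5. inverse-variance fixed-effect pooling with heterogeneity and the four
   retention criteria.

The returned `StratifiedMetaDEResults` carries the embedding, the cluster
solution, the optional stability report, the per-cluster DE tables and the
meta table, and offers ``summary()`` plus concordance/network accessors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import countio, diffexpr, metapool, signature, stratify
from .countio import CountMatrix, SampleTable


class ModelError(ValueError):
    pass


class StratifiedMetaDE:
    """Stratified-control meta-differential-expression model.

    Parameters
    ----------
    counts
        Raw gene-by-sample counts.
    samples
        Sample metadata with a ``treatment`` column.
    drug
        Treatment label of the drug-treated group.
    vehicle
        Treatment label of the vehicle controls (reference level).
    var_frac, n_pcs
        Fraction of most-variable genes and number of principal components for
        the control embedding.
    k
        Cluster number. ``None`` selects k from a stability report over
        ``k_range`` (slower); an integer fixes it.
    n_covariate_pcs
        Leading PCs used as DE covariates (design PC1..PCm + treatment).
    criteria
        Meta-analysis retention criteria.
    seed
        Master seed; per-stage seeds are derived from it.
    """

    def __init__(self, counts: CountMatrix, samples: SampleTable, drug: str,
                 vehicle: str = "DMSO", var_frac: float = 0.10, n_pcs: int = 20,
                 k: int | None = 5, k_range=range(2, 11),
                 min_cluster_size: int = 15, n_covariate_pcs: int = 3,
                 criteria: metapool.MetaCriteria | None = None,
                 scale_pca: bool = False, kmeans_restarts: int = 25,
                 stability_kwargs: dict | None = None, seed: int = 0) -> None:
        samples.check_matches(counts)
        if len(samples.samples_with(vehicle)) < 2:
            raise ModelError(f"need >= 2 {vehicle!r} samples")
        if len(samples.samples_with(drug)) < 2:
            raise ModelError(f"need >= 2 {drug!r} samples")
        self.counts = counts
        self.samples = samples
        self.drug = drug
        self.vehicle = vehicle
        self.var_frac = var_frac
        self.n_pcs = n_pcs
        self.k = k
        self.k_range = list(k_range)
        self.min_cluster_size = min_cluster_size
        self.n_covariate_pcs = n_covariate_pcs
        self.criteria = criteria or metapool.MetaCriteria()
        self.scale_pca = scale_pca
        self.kmeans_restarts = kmeans_restarts
        self.stability_kwargs = dict(stability_kwargs or {})
        self.seed = int(seed)

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, samples: pd.DataFrame,
                        drug: str, **kwargs) -> "StratifiedMetaDE":
        return cls(CountMatrix(counts), SampleTable(samples), drug, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, compute_stability: bool | None = None) -> "StratifiedMetaDEResults":
        """Run the workflow. ``compute_stability`` defaults to True when k is
        not fixed (it is then needed for selection) and False otherwise."""
        if compute_stability is None:
            compute_stability = self.k is None

        sf = diffexpr.estimate_size_factors(self.counts)
        logmat = countio.log_transform(self.counts, sf)
        control_ids = self.samples.samples_with(self.vehicle)
        drug_ids = self.samples.samples_with(self.drug)
        control_log = logmat[control_ids]

        var_genes = stratify.select_variable_genes(control_log, self.var_frac)
        embedding = stratify.run_pca(control_log.loc[var_genes], n_pcs=self.n_pcs,
                                     scale=self.scale_pca)
        projected = stratify.project_samples(embedding, logmat[drug_ids].loc[var_genes])

        report = None
        if compute_stability:
            report = stratify.build_stability_report(
                embedding.scores, k_range=self.k_range,
                min_cluster_size=self.min_cluster_size,
                seed=stratify._child_seed(self.seed, 11),
                n_restarts=self.kmeans_restarts, **self.stability_kwargs)
        if self.k is None:
            k = stratify.choose_k(report, mode="auto")
        else:
            k = int(self.k)
        solution = stratify.kmeans_cluster(embedding.scores, k,
                                           seed=stratify._child_seed(self.seed, 12),
                                           n_restarts=self.kmeans_restarts)

        # assemble the working sample table: cluster labels for controls,
        # projected covariate scores for treated samples
        meta = self.samples.table.copy()
        meta["cluster"] = pd.Series(solution.assignment, dtype="Int64")
        pc_cols = [f"PC{i + 1}" for i in range(self.n_covariate_pcs)]
        for c in pc_cols:
            meta[c] = np.nan
        meta.loc[embedding.scores.index, pc_cols] = embedding.scores[pc_cols].to_numpy()
        meta.loc[projected.index, pc_cols] = projected[pc_cols].to_numpy()
        working = SampleTable(meta)

        design = diffexpr.DesignSpec(treatment=self.drug, vehicle=self.vehicle,
                                     covariates=pc_cols)
        de_tables, skipped = diffexpr.run_cluster_contrasts(self.counts, working, design)
        if len(de_tables) < 2:
            raise ModelError(f"fewer than two usable cluster contrasts (skipped: {skipped})")
        meta_table = metapool.run_meta(de_tables, self.criteria)

        return StratifiedMetaDEResults(
            model=self, size_factors=sf, embedding=embedding,
            projected_scores=projected, stability=report, clusters=solution,
            sample_table=working, de_tables=de_tables, skipped_contrasts=skipped,
            meta=meta_table, k=k)


@dataclass
class StratifiedMetaDEResults:
    """Fitted results of :class:`StratifiedMetaDE`."""

    model: StratifiedMetaDE
    size_factors: pd.Series
    embedding: stratify.EmbeddingResult
    projected_scores: pd.DataFrame
    stability: stratify.StabilityReport | None
    clusters: stratify.ClusterSolution
    sample_table: SampleTable
    de_tables: dict[int, pd.DataFrame]
    skipped_contrasts: dict[int, str]
    meta: pd.DataFrame
    k: int

    # -- set-level views --------------------------------------------------

    def cluster_deg_sets(self, fdr_max: float = 0.05) -> dict[int, set[str]]:
        return {c: diffexpr.significant_genes(t, fdr_max)
                for c, t in self.de_tables.items()}

    def retained_genes(self) -> set[str]:
        return metapool.retained_genes(self.meta)

    def meta_only_genes(self) -> set[str]:
        return set(self.meta.index[self.meta["class"] == "meta-only"])

    def fold_change_profile(self) -> pd.DataFrame:
        return signature.fold_change_profile(self.de_tables)

    def fc_correlations(self) -> pd.DataFrame:
        return signature.fc_correlations(self.fold_change_profile())

    def network(self) -> signature.CorrelationNetwork:
        corr = signature.correlation_matrix(self.fc_correlations())
        return signature.build_network(corr)

    def intersect_degs(self, fdr_max: float = 0.05):
        return signature.intersect_cluster_degs(self.cluster_deg_sets(fdr_max),
                                                self.de_tables)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = []
        add = lines.append
        add("Stratified-control meta-differential-expression results")
        add("=" * 56)
        n_ctrl = len(m.samples.samples_with(m.vehicle))
        n_trt = len(m.samples.samples_with(m.drug))
        add(f"Drug: {m.drug}   Vehicle: {m.vehicle}")
        add(f"Genes: {m.counts.shape[0]}   Controls: {n_ctrl}   Treated: {n_trt}")
        ve = self.embedding.var_explained
        add(f"Embedding: {len(self.embedding.variable_gene_ids)} variable genes, "
            f"{self.embedding.n_pcs} PCs "
            f"(PC1 {ve[0] * 100:.1f}%, PC2 {ve[1] * 100:.1f}%, "
            f"cumulative {ve.sum() * 100:.1f}%)")
        sizes = self.clusters.cluster_sizes()
        add(f"Control clusters: k = {self.k}, sizes "
            f"{', '.join(f'{c}:{n}' for c, n in sizes.items())}")
        if self.stability is not None:
            row = self.stability.table.loc[self.k]
            add(f"Stability at k={self.k}: silhouette {row['mean_silhouette']:.3f}, "
                f"Jaccard {row['mean_bootstrap_jaccard']:.3f}, "
                f"prediction strength {row['prediction_strength']:.3f}, "
                f"PAC {row['pac']:.3f}")
        add("")
        add("Per-cluster contrasts (FDR < 0.05):")
        for c, tab in sorted(self.de_tables.items()):
            n_sig = len(diffexpr.significant_genes(tab))
            add(f"  cluster {c}: {len(tab)} genes tested, {n_sig} DEGs")
        for c, reason in sorted(self.skipped_contrasts.items()):
            add(f"  cluster {c}: skipped ({reason})")
        add("")
        counts = self.meta["class"].value_counts()
        retained = int(self.meta["retained"].sum())
        add(f"Meta-analysis: {len(self.meta)} genes pooled, {retained} retained meta-DEGs")
        add(f"  meta-only: {counts.get('meta-only', 0)}   "
            f"meta-overlapping: {counts.get('meta-overlapping', 0)}")
        crit = m.criteria
        add(f"  criteria: >={crit.min_contrasts} contrasts, "
            f"sign-consistent >={crit.min_sign_consistent}, "
            f"I2 < {crit.i2_max_percent:g}%, meta p < {crit.meta_p_max:g}")
        i2 = self.meta["i2_percent"].dropna()
        if len(i2):
            add(f"  I2 median {i2.median():.1f}%, "
                f"fraction I2 < 50%: {(i2 < 50).mean():.2f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<StratifiedMetaDEResults k={self.k} "
                f"retained={int(self.meta['retained'].sum())} "
                f"genes={len(self.meta)}>")
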