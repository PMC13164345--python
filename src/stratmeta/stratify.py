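"""Control stratification: variable genes, PCA embedding, k-means, stability metrics.

The vehicle-control pool is embedded by PCA on the top fraction of most
variable genes (variance of log2-normalized expression), clustered by k-means
in the leading principal-component space, and candidate cluster numbers are
scored by within-cluster sum of squares, mean silhouette width, bootstrap
Jaccard stability, prediction strength and the proportion of ambiguous
clustering (PAC) from consensus resampling. Treated samples are projected into
the control embedding but never influence it.

PCA centers genes but does not scale them to unit variance by default:
variable-gene selection already privileges high-variance genes and unit
scaling would undo it (``scale=True`` is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

DEFAULT_MIN_CLUSTER_SIZE = 15


class StratifyError(ValueError):
    pass


class DegenerateDataError(StratifyError):
    """Raised when the data cannot support the requested resampling metric
    (e.g. all points identical)."""


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# variable genes and PCA


def select_variable_genes(logmat: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """Top ``ceil(fraction * n_genes)`` genes by variance of log expression.

    Ties are broken toward the lexicographically smaller gene id so the
    selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise StratifyError("fraction must lie in (0, 1]")
    if logmat.shape[0] < 10:
        raise StratifyError("need at least 10 genes for variable-gene selection")
    variances = logmat.var(axis=1, ddof=1)
    if (variances == 0).all():
        raise StratifyError("all genes have zero variance; nothing to select")
    n_take = math.ceil(fraction * logmat.shape[0])
    order = sorted(logmat.index, key=lambda g: (-variances[g], g))
    return order[:n_take]


@dataclass
class EmbeddingResult:
    """A centered PCA embedding of the control samples on the variable genes."""

    n_pcs: int
    scores: pd.DataFrame              # samples x PCs
    loadings: pd.DataFrame            # genes x PCs
    var_explained: np.ndarray         # per retained PC, fraction of total variance
    center: pd.Series                 # per-gene centering vector
    scale: pd.Series | None           # per-gene scaling vector, or None
    variable_gene_ids: list[str] = field(default_factory=list)

    @property
    def pc_names(self) -> list[str]:
        return list(self.scores.columns)


def run_pca(logmat: pd.DataFrame, n_pcs: int = 20, scale: bool = False) -> EmbeddingResult:
    """PCA (SVD of the gene-centered matrix) on the variable-gene submatrix.

    ``logmat`` is genes x samples, already restricted to the variable genes.
    Variance fractions are relative to the total variance over all components.
    """
    n_genes, n_samples = logmat.shape
    max_pcs = min(n_samples - 1, n_genes)
    if n_pcs > max_pcs:
        raise StratifyError(f"n_pcs={n_pcs} exceeds min(n_samples-1, n_genes)={max_pcs}")
    X = logmat.T.to_numpy(dtype=float)        # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    scale_vec = None
    if scale:
        scale_vec = Xc.std(axis=0, ddof=1)
        scale_vec[scale_vec == 0] = 1.0
        Xc = Xc / scale_vec
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = S**2
    total = eig.sum()
    if total == 0:
        raise StratifyError("matrix has zero total variance")
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_pcs] * S[:n_pcs]
    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    return EmbeddingResult(
        n_pcs=n_pcs,
        scores=pd.DataFrame(scores, index=logmat.columns, columns=pc_names),
        loadings=pd.DataFrame(Vt[:n_pcs].T, index=logmat.index, columns=pc_names),
        var_explained=eig[:n_pcs] / total,
        center=pd.Series(center, index=logmat.index),
        scale=None if scale_vec is None else pd.Series(scale_vec, index=logmat.index),
        variable_gene_ids=list(logmat.index),
    )


def project_samples(embedding: EmbeddingResult, logmat_new: pd.DataFrame) -> pd.DataFrame:
    """Project new samples (genes x samples) into a fitted embedding.

    Uses the training centering/scaling; the embedding itself is unchanged.
    All variable genes must be present.
    """
    missing = [g for g in embedding.variable_gene_ids if g not in logmat_new.index]
    if missing:
        raise StratifyError(f"new samples lack variable genes: {missing[:5]}")
    X = logmat_new.loc[embedding.variable_gene_ids].T.to_numpy(dtype=float)
    Xc = X - embedding.center.to_numpy()
    if embedding.scale is not None:
        Xc = Xc / embedding.scale.to_numpy()
    scores = Xc @ embedding.loadings.to_numpy()
    return pd.DataFrame(scores, index=logmat_new.columns, columns=embedding.pc_names)


# ---------------------------------------------------------------------------
# k-means


@dataclass
class ClusterSolution:
    k: int
    assignment: pd.Series            # per-sample label in 1..k
    centroids: np.ndarray            # k x n_pcs
    seed: int
    wcss: float

    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                random_state=seed, algorithm="lloyd")
    km.fit(X)
    return km


def kmeans_cluster(scores: pd.DataFrame, k: int, seed: int = 0,
                   n_restarts: int = 25) -> ClusterSolution:
    """Best-of-restarts Lloyd k-means (k-means++ seeding) in PC space.

    Labels are 1-based and relabeled by first appearance so that the same
    partition always gets the same labels.
    """
    if not 1 <= k <= len(scores):
        raise StratifyError(f"k={k} out of range for {len(scores)} samples")
    X = scores.to_numpy(dtype=float)
    km = _fit_kmeans(X, k, seed, n_restarts)
    labels = km.labels_
    # relabel by order of first appearance (deterministic given the partition)
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    new_labels = np.array([remap[lab] for lab in labels])
    centroids = np.vstack([X[new_labels == c].mean(axis=0) for c in range(1, k + 1)])
    wcss = float(((X - centroids[new_labels - 1])**2).sum())
    return ClusterSolution(
        k=k,
        assignment=pd.Series(new_labels, index=scores.index, name="cluster"),
        centroids=centroids,
        seed=seed,
        wcss=wcss,
    )


def internal_indices(scores: pd.DataFrame, solution: ClusterSolution) -> tuple[float, float]:
    """(WCSS, mean silhouette) of a clustering in PC space.

    Singleton clusters contribute silhouette 0 for their point.
    """
    X = scores.to_numpy(dtype=float)
    labels = solution.assignment.to_numpy()
    centroids = np.vstack([X[labels == c].mean(axis=0)
                           for c in sorted(np.unique(labels))])
    label_index = {c: i for i, c in enumerate(sorted(np.unique(labels)))}
    idx = np.array([label_index[c] for c in labels])
    wcss = float(((X - centroids[idx])**2).sum())
    if solution.k < 2:
        raise StratifyError("silhouette requires k >= 2")
    sil = float(silhouette_samples(X, labels).mean())
    return wcss, sil


# ---------------------------------------------------------------------------
# resampling stability metrics


def bootstrap_jaccard(scores: pd.DataFrame, k: int, B: int = 200, seed: int = 0,
                      n_restarts: int = 5) -> tuple[pd.Series, float]:
    """Clusterwise bootstrap stability: mean best-match Jaccard index.

    For each of B bootstrap resamples (with replacement) the resample is
    re-clustered at the same k; each reference cluster is compared — over the
    distinct samples present in the resample — with its best-matching new
    cluster by Jaccard similarity. Returns per-cluster means and their overall
    mean.
    """
    if k < 2:
        raise StratifyError("bootstrap_jaccard requires k >= 2")
    if B < 2:
        raise StratifyError("B must be >= 2")
    X = scores.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise DegenerateDataError("all points identical; bootstrap stability undefined")
    n = len(X)
    reference = kmeans_cluster(scores, k, seed=_child_seed(seed, 0)).assignment.to_numpy()
    rng = np.random.default_rng(_child_seed(seed, 1))
    sums = np.zeros(k)
    counts = np.zeros(k)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        km = _fit_kmeans(Xb, k, _child_seed(seed, 2 + b), n_restarts)
        labels_b = km.labels_
        present = np.unique(idx)
        # distinct-sample membership of each new cluster (duplicates of a sample
        # share a position, hence a label)
        first_pos = {}
        for pos, sample in enumerate(idx):
            if sample not in first_pos:
                first_pos[sample] = pos
        new_members = [set() for _ in range(k)]
        for sample in present:
            new_members[labels_b[first_pos[sample]]].add(sample)
        present_set = set(present.tolist())
        for c in range(1, k + 1):
            ref_members = {i for i in np.flatnonzero(reference == c)} & present_set
            if not ref_members:
                continue
            best = max(len(ref_members & m) / len(ref_members | m)
                       for m in new_members if m)
            sums[c - 1] += best
            counts[c - 1] += 1
    per_cluster = pd.Series(
        np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
        index=pd.Index(range(1, k + 1), name="cluster"),
        name="mean_jaccard")
    return per_cluster, float(np.nanmean(per_cluster))


def prediction_strength(scores: pd.DataFrame, k: int, repetitions: int = 100,
                        seed: int = 0, n_restarts: int = 5) -> float:
    """Prediction strength of a candidate k via two-fold resampling.

    Per repetition the samples are split in half; each half in turn serves as
    the training set. Test points are classified to the nearest training
    centroid, and for each test-half cluster with >= 2 points the proportion
    of its point pairs co-assigned by the training classifier is computed.
    The repetition's score for one direction is the minimum over test clusters;
    both directions are averaged, then all repetitions.
    """
    n = len(scores)
    if k < 1:
        raise StratifyError("k must be >= 1")
    if k == 1:
        return 1.0
    if n < 2 * k:
        raise StratifyError(f"need >= 2k samples for prediction strength (n={n}, k={k})")
    X = scores.to_numpy(dtype=float)
    rng = np.random.default_rng(_child_seed(seed, 0))
    rep_scores = []
    for rep in range(repetitions):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2:])
        direction_scores = []
        for d, (train_idx, test_idx) in enumerate(((halves[0], halves[1]),
                                                   (halves[1], halves[0]))):
            km_train = _fit_kmeans(X[train_idx], k, _child_seed(seed, 10 + 2 * rep + d),
                                   n_restarts)
            km_test = _fit_kmeans(X[test_idx], k, _child_seed(seed, 10_000 + 2 * rep + d),
                                  n_restarts)
            d2 = ((X[test_idx][:, None, :] - km_train.cluster_centers_[None, :, :])**2).sum(-1)
            train_assign = d2.argmin(axis=1)
            mins = []
            for c in range(k):
                members = np.flatnonzero(km_test.labels_ == c)
                n_c = len(members)
                if n_c < 2:
                    continue  # excluded from the minimum
                _, counts = np.unique(train_assign[members], return_counts=True)
                same = (counts * (counts - 1) // 2).sum()
                mins.append(same / (n_c * (n_c - 1) / 2))
            if mins:
                direction_scores.append(min(mins))
        if direction_scores:
            rep_scores.append(float(np.mean(direction_scores)))
    if not rep_scores:
        raise StratifyError("prediction strength undefined: no test cluster of size >= 2")
    return float(np.mean(rep_scores))


def pac(scores: pd.DataFrame, k: int, subsample_frac: float = 0.8,
        iterations: int = 200, u1: float = 0.1, u2: float = 0.9,
        seed: int = 0, n_restarts: int = 5) -> float:
    """Proportion of ambiguous clustering from consensus resampling.

    The consensus value of a sample pair is its co-clustering count divided by
    its co-sampling count over the subsampled k-means runs; PAC is the
    fraction of off-diagonal pairs with consensus strictly between u1 and u2.
    Pairs never co-sampled are excluded (with a warning via a returned NaN
    guard upstream if all pairs are excluded).
    """
    if not 0 < subsample_frac < 1:
        raise StratifyError("subsample_frac must lie in (0, 1)")
    if not u1 < u2:
        raise StratifyError("u1 must be < u2")
    n = len(scores)
    X = scores.to_numpy(dtype=float)
    m = max(int(round(subsample_frac * n)), k)
    rng = np.random.default_rng(_child_seed(seed, 0))
    co_sampled = np.zeros((n, n))
    co_clustered = np.zeros((n, n))
    for it in range(iterations):
        idx = rng.choice(n, size=m, replace=False)
        km = _fit_kmeans(X[idx], k, _child_seed(seed, 1 + it), n_restarts)
        ind = np.zeros(n)
        ind[idx] = 1.0
        co_sampled += np.outer(ind, ind)
        for c in range(k):
            members = idx[km.labels_ == c]
            indc = np.zeros(n)
            indc[members] = 1.0
            co_clustered += np.outer(indc, indc)
    iu = np.triu_indices(n, 1)
    counted = co_sampled[iu] > 0
    if not counted.any():
        raise StratifyError("no sample pair was ever co-sampled; increase iterations")
    consensus = co_clustered[iu][counted] / co_sampled[iu][counted]
    return float(((consensus > u1) & (consensus < u2)).mean())


# ---------------------------------------------------------------------------
# stability report and k selection


@dataclass
class StabilityReport:
    """Per-k internal and resampling stability indices plus admissibility."""

    table: pd.DataFrame
    min_cluster_size: int
    solutions: dict[int, ClusterSolution] = field(default_factory=dict)

    def admissible_ks(self) -> list[int]:
        return [int(k) for k in self.table.index[self.table["admissible"]]]


def build_stability_report(scores: pd.DataFrame, k_range=range(2, 11),
                           min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                           seed: int = 0, n_restarts: int = 25,
                           B: int = 200, ps_repetitions: int = 100,
                           pac_iterations: int = 200,
                           subsample_frac: float = 0.8,
                           resample_restarts: int = 5) -> StabilityReport:
    """Score every candidate k with WCSS, silhouette, bootstrap Jaccard,
    prediction strength, PAC and the minimum cluster size; a k is admissible
    iff its smallest cluster has at least ``min_cluster_size`` samples."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise StratifyError("k_range is empty")
    rows = []
    solutions: dict[int, ClusterSolution] = {}
    for k in ks:
        sol = kmeans_cluster(scores, k, seed=_child_seed(seed, 100 + k),
                             n_restarts=n_restarts)
        solutions[k] = sol
        wcss, sil = (sol.wcss, np.nan) if k == 1 else internal_indices(scores, sol)
        _, jaccard = bootstrap_jaccard(scores, k, B=B, seed=_child_seed(seed, 200 + k),
                                       n_restarts=resample_restarts) if k >= 2 else (None, np.nan)
        ps = prediction_strength(scores, k, repetitions=ps_repetitions,
                                 seed=_child_seed(seed, 300 + k),
                                 n_restarts=resample_restarts)
        pac_val = pac(scores, k, subsample_frac=subsample_frac,
                      iterations=pac_iterations, seed=_child_seed(seed, 400 + k),
                      n_restarts=resample_restarts) if k >= 2 else np.nan
        min_size = int(sol.cluster_sizes().min())
        rows.append({
            "k": k, "wcss": wcss, "mean_silhouette": sil,
            "mean_bootstrap_jaccard": jaccard, "prediction_strength": ps,
            "pac": pac_val, "min_cluster_size": min_size,
            "admissible": min_size >= min_cluster_size,
        })
    table = pd.DataFrame(rows).set_index("k")
    return StabilityReport(table=table, min_cluster_size=min_cluster_size,
                           solutions=solutions)


def choose_k(report: StabilityReport, mode: str = "auto",
             fixed_k: int | None = None) -> int:
    """Pick the cluster number from a stability report.

    ``auto`` maximizes prediction strength over admissible ks, breaking ties by
    lower PAC then smaller k — an explicit, documented stand-in for expert
    judgment. ``fixed`` returns a user-specified (admissible) k.
    """
    tab = report.table
    admissible = tab[tab["admissible"]]
    if admissible.empty:
        raise StratifyError("no admissible k: every candidate has an undersized cluster")
    if mode == "fixed":
        if fixed_k is None:
            raise StratifyError("mode='fixed' requires fixed_k")
        if fixed_k not in admissible.index:
            raise StratifyError(f"k={fixed_k} is not admissible "
                                f"(admissible: {list(admissible.index)})")
        return int(fixed_k)
    if mode != "auto":
        raise StratifyError(f"unknown mode {mode!r}")
    ranked = admissible.reset_index().sort_values(
        by=["prediction_strength", "pac", "k"],
        ascending=[False, True, True],
        kind="stable",
    )
    return int(ranked.iloc[0]["k"])
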