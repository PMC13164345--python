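"""Negative-binomial Wald differential expression with covariate adjustment.

The model for gene g and sample j is

    count_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g

with s_j the median-of-ratios size factor and x_j the design row (intercept,
optional covariates such as PC scores, and a 0/1 treatment indicator with the
vehicle as reference). Coefficients are estimated by iteratively reweighted
least squares on the log link; the Wald statistic for the treatment coefficient
uses the expected-information covariance. Gene-wise dispersions are estimated
by a Cox–Reid-adjusted profile likelihood and shrunk toward a log-linear
mean–dispersion trend — a deliberately simpler stabilization than DESeq2's
empirical-Bayes machinery, validated by parameter recovery rather than by
matching DESeq2 output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .countio import CountMatrix, SampleTable

LN2 = float(np.log(2.0))
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


class DEError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Covariate names plus the treatment contrast (vehicle = reference level)."""

    treatment: str
    vehicle: str = "DMSO"
    covariates: list[str] = field(default_factory=list)

    def build_matrix(self, samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Design matrix [1, covariates..., treated] for the given sample rows."""
        cols = [np.ones(len(samples))]
        names = ["intercept"]
        for cov in self.covariates:
            if cov not in samples.columns:
                raise DEError(f"covariate {cov!r} missing from sample table")
            vals = samples[cov].to_numpy(dtype=float)
            if np.isnan(vals).any():
                bad = list(samples.index[np.isnan(vals)])
                raise DEError(f"covariate {cov!r} missing for samples {bad[:5]}")
            cols.append(vals)
            names.append(cov)
        treated = (samples["treatment"] == self.treatment).to_numpy(dtype=float)
        cols.append(treated)
        names.append("treatment")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DEError("design matrix is rank deficient on these samples")
        return X, names


# ---------------------------------------------------------------------------
# size factors


def estimate_size_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes positive in every sample of count_gj / geomean_g.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise DEError("no gene has positive counts in every sample; "
                      "filter samples or genes before size-factor estimation")
    ref = arr[all_pos]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB GLM by IRLS


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood (mean/dispersion parameterization)."""
    if alpha < ALPHA_MIN:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(np.sum(
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def fit_nb_glm(y: np.ndarray, X: np.ndarray, sf: np.ndarray, alpha: float,
               tol: float = 1e-8, max_iter: int = 100,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Fit the NB GLM with log link and offset log(sf).

    Returns (beta, cov, mu, converged); beta on the natural-log scale,
    cov from the expected information (X' W X)^-1 with W = mu / (1 + alpha*mu).
    """
    y = np.asarray(y, dtype=float)
    offset = np.log(sf)
    # initialize from lightly regularized observed rates
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        eta_new = offset + X @ beta_new
        eta_new = np.clip(eta_new, -30.0, 30.0)
        mu = np.exp(eta_new)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta, eta = beta_new, eta_new
        if delta < tol:
            converged = True
            break
    W = mu / (1.0 + alpha * mu)
    info = (X.T * W) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        converged = False
    return beta, cov, mu, converged


# ---------------------------------------------------------------------------
# dispersion estimation


def _mom_alpha(y: np.ndarray, sf: np.ndarray) -> float:
    """Method-of-moments dispersion on normalized counts (fallback/initializer)."""
    q = y / sf
    m = q.mean()
    if m <= 0:
        return ALPHA_MIN
    v = q.var(ddof=1)
    return float(np.clip((v - m) / m**2, ALPHA_MIN, ALPHA_MAX))


def _profile_alpha(y: np.ndarray, X: np.ndarray, mu: np.ndarray, alpha0: float) -> tuple[float, bool]:
    """Cox–Reid adjusted profile likelihood maximization over log10(alpha)."""

    def neg_apl(log10_a: float) -> float:
        a = 10.0 ** log10_a
        W = mu / (1.0 + a * mu)
        sign, logdet = np.linalg.slogdet((X.T * W) @ X)
        if sign <= 0:
            return np.inf
        return -(nb_loglik(y, mu, a) - 0.5 * logdet)

    try:
        res = optimize.minimize_scalar(
            neg_apl, bounds=(np.log10(ALPHA_MIN), np.log10(ALPHA_MAX)),
            method="bounded", options={"xatol": 1e-4})
        if res.success and np.isfinite(res.fun):
            return float(np.clip(10.0 ** res.x, ALPHA_MIN, ALPHA_MAX)), True
    except Exception:
        pass
    return alpha0, False


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series, X: np.ndarray,
                         shrink_weight: float = 0.5,
                         ) -> tuple[pd.Series, pd.DataFrame]:
    """Gene-wise NB dispersions with trend shrinkage.

    Per gene: method-of-moments initializer, preliminary GLM fit for the means,
    Cox–Reid adjusted profile-likelihood maximization in alpha, then shrinkage
    of log(alpha) toward a log-linear trend on mean normalized expression with
    the given fixed weight. Returns the final dispersions and a diagnostics
    frame (raw estimate, trend value, fallback flag).
    """
    if counts.shape[1] - X.shape[1] < 2:
        raise DEError("need >= 2 residual degrees of freedom for dispersion estimation")
    sf_arr = sf.reindex(counts.columns).to_numpy(dtype=float)
    genes = counts.index
    raw = np.empty(len(genes))
    fallback = np.zeros(len(genes), dtype=bool)
    base_mean = (counts.to_numpy(dtype=float) / sf_arr).mean(axis=1)
    arr = counts.to_numpy(dtype=float)
    for i in range(len(genes)):
        y = arr[i]
        a0 = _mom_alpha(y, sf_arr)
        _, _, mu, ok = fit_nb_glm(y, X, sf_arr, a0, tol=1e-6, max_iter=50)
        if not ok or not np.all(np.isfinite(mu)):
            raw[i] = a0
            fallback[i] = True
            continue
        a_hat, ok = _profile_alpha(y, X, mu, a0)
        raw[i] = a_hat
        fallback[i] = not ok

    # log-linear mean–dispersion trend, fitted on genes with informative estimates
    usable = (base_mean > 0) & (raw > ALPHA_MIN * 10)
    log_a = np.log(raw)
    if usable.sum() >= 10:
        A = np.column_stack([np.ones(usable.sum()), np.log(base_mean[usable])])
        coef, *_ = np.linalg.lstsq(A, log_a[usable], rcond=None)
        trend = coef[0] + coef[1] * np.log(np.maximum(base_mean, 1e-8))
    else:
        trend = np.full(len(genes), np.median(log_a[usable]) if usable.any() else np.log(0.1))
    shrunk = np.exp((1.0 - shrink_weight) * log_a + shrink_weight * trend)
    shrunk = np.clip(shrunk, ALPHA_MIN, ALPHA_MAX)
    diag = pd.DataFrame({
        "alpha_raw": raw,
        "alpha_trend": np.exp(trend),
        "base_mean": base_mean,
        "fallback": fallback,
    }, index=genes)
    return pd.Series(shrunk, index=genes, name="dispersion"), diag


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up with monotonicity; NaN in -> NaN out."""
    is_series = isinstance(p, pd.Series)
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    if is_series:
        return pd.Series(out, index=p.index, name="fdr")
    return out


# ---------------------------------------------------------------------------
# contrasts


def run_contrast(m: CountMatrix, samples: SampleTable, design: DesignSpec,
                 contrast_id: str = "contrast",
                 cluster_id: int | None = None,
                 cluster_column: str = "cluster",
                 shrink_weight: float = 0.5,
                 ) -> pd.DataFrame:
    """One NB Wald contrast: drug-treated samples vs (optionally one cluster of)
    vehicle controls.

    When ``cluster_id`` is given, the vehicle side is restricted to controls in
    that cluster while all drug-treated samples are used. Size factors are
    re-estimated on the contrast's sample subset; genes with zero counts across
    the subset are dropped; BH correction runs over converged genes.

    Returns a frame indexed by gene with columns
    baseMean, log2fc, se, p, fdr, contrast_id, converged (log2fc/se in log2 units).
    """
    meta = samples.table
    vehicle_mask = meta["treatment"] == design.vehicle
    if cluster_id is not None:
        if cluster_column not in meta.columns:
            raise DEError(f"sample table has no {cluster_column!r} column")
        vehicle_mask &= meta[cluster_column] == cluster_id
    treated_ids = [s for s in meta.index[meta["treatment"] == design.treatment]
                   if s in m.counts.columns]
    vehicle_ids = [s for s in meta.index[vehicle_mask] if s in m.counts.columns]
    if len(vehicle_ids) < 2:
        raise DEError(f"{contrast_id}: needs >= 2 vehicle samples, got {len(vehicle_ids)}")
    if len(treated_ids) < 2:
        raise DEError(f"{contrast_id}: needs >= 2 treated samples, got {len(treated_ids)}")

    ids = vehicle_ids + treated_ids
    sub = m.counts.loc[:, ids]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if sub.empty:
        raise DEError(f"{contrast_id}: all genes have zero counts on this subset")
    sub_meta = meta.loc[ids]
    X, _ = design.build_matrix(sub_meta)
    sf = estimate_size_factors(CountMatrix(sub))
    sf_arr = sf.to_numpy(dtype=float)

    alpha, _ = estimate_dispersions(sub, sf, X, shrink_weight=shrink_weight)
    arr = sub.to_numpy(dtype=float)
    alpha_arr = alpha.to_numpy()
    n_genes = arr.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    converged = np.zeros(n_genes, dtype=bool)
    tcoef = X.shape[1] - 1
    for i in range(n_genes):
        beta, cov, _, ok = fit_nb_glm(arr[i], X, sf_arr, alpha_arr[i])
        var = cov[tcoef, tcoef]
        if not ok or not np.isfinite(var) or var <= 0:
            continue
        converged[i] = True
        log2fc[i] = beta[tcoef] / LN2
        se[i] = np.sqrt(var) / LN2
        pvals[i] = 2.0 * stats.norm.sf(abs(beta[tcoef]) / np.sqrt(var))

    base_mean = (arr / sf_arr).mean(axis=1)
    result = pd.DataFrame({
        "baseMean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "p": pvals,
        "fdr": bh_adjust(pd.Series(pvals, index=sub.index)).to_numpy(),
        "contrast_id": contrast_id,
        "converged": converged,
    }, index=sub.index.rename("gene"))
    return result


def run_cluster_contrasts(m: CountMatrix, samples: SampleTable, design: DesignSpec,
                          cluster_column: str = "cluster",
                          shrink_weight: float = 0.5,
                          ) -> tuple[dict[int, pd.DataFrame], dict[int, str]]:
    """Run one contrast per control cluster; clusters whose preconditions fail
    are skipped with the reason recorded (mirroring retention of zero-DEG
    clusters in downstream pooling)."""
    meta = samples.table
    if cluster_column not in meta.columns:
        raise DEError(f"sample table has no {cluster_column!r} column")
    clusters = sorted(int(c) for c in
                      meta.loc[meta["treatment"] == design.vehicle, cluster_column]
                      .dropna().unique())
    tables: dict[int, pd.DataFrame] = {}
    skipped: dict[int, str] = {}
    for c in clusters:
        cid = f"cluster{c}_vs_{design.treatment}"
        try:
            tables[c] = run_contrast(m, samples, design, contrast_id=cid,
                                     cluster_id=c, cluster_column=cluster_column,
                                     shrink_weight=shrink_weight)
        except DEError as err:
            skipped[c] = str(err)
    return tables, skipped


def significant_genes(table: pd.DataFrame, fdr_max: float = 0.05) -> set[str]:
    """FDR-thresholded DEG set of one contrast."""
    mask = table["fdr"] < fdr_max
    return set(table.index[mask.fillna(False)])
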