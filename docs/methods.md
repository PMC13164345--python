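# Methods

## Overview

`stratmeta` estimates a drug-associated transcriptomic signature when the
vehicle-control pool is large and heterogeneous: controls are partitioned into
transcriptionally coherent subgroups, the drug effect is estimated against
each subgroup with a negative-binomial Wald model, and the subgroup estimates
are pooled by inverse-variance fixed-effect meta-analysis under explicit
retention criteria. This note records the model, the synthetic-data
generator's assumptions, the numerical choices, and the limitations — in
particular what the procedure's statistical behavior does and does not
guarantee.

## Count model and differential expression

Counts are modeled per gene g and sample j as

    K_gj ~ NB(mu_gj, alpha_g),  Var(K) = mu + alpha * mu^2,
    log mu_gj = log s_j + x_j' beta_g,

with median-of-ratios size factors s_j (the geometric-mean reference is
computed over genes positive in every sample of the contrast; re-estimated on
each contrast's sample subset) and design row x_j = (1, PC1_j, PC2_j, PC3_j,
t_j), where t_j indicates treatment (vehicle is the reference level) and the
PC scores are the *global* control-embedding scores — controls use their
training scores, treated samples their projections. Including three PCs
absorbs residual baseline structure within each contrast; within-cluster
re-computation of PCs is deliberately not the default (the global embedding
keeps the covariate meaning identical across contrasts).

Coefficients are fitted by IRLS on the log link (relative tolerance 1e-8,
at most 100 iterations, offset log s_j); the covariance comes from the
expected information (X'WX)^-1 with W = mu/(1 + alpha*mu). The treatment
coefficient and its standard error are reported in log2 units; the Wald
p-value uses the normal reference; BH correction runs across the contrast's
converged genes. No fold-change threshold is applied at testing; magnitude
filters appear only downstream (the ORA down-query uses log2FC < -1.0).

Gene-wise dispersions: a method-of-moments estimate initializes a preliminary
GLM fit; alpha is then estimated by maximizing the Cox–Reid-adjusted profile
likelihood l(alpha) - 0.5 log det(X'WX) over log10(alpha) in [1e-8, 10]; a
log-linear trend of log(alpha) on log mean normalized expression is fitted
across genes; and each gene's log-dispersion is shrunk halfway (weight 0.5)
toward the trend. This is a deliberately simple stabilization in the spirit
of empirical-Bayes dispersion moderation, validated by parameter recovery
(Poisson data give median alpha < 0.01; alpha = 0.2 data are recovered within
[0.1, 0.3] at n = 100) rather than by matching any particular tool's output.
Genes that fail the optimization fall back to the moment estimate and are
flagged; genes with all-zero counts in a contrast are dropped from that
contrast. At 60 vs 20 samples with alpha = 0.1, the null type-I error at
p < 0.05 is ~0.05–0.06 and a planted log2FC of 1.0 is recovered with median
error < 0.01 (both recomputed by `scripts/acceptance.py`).

## Stratification

Variable genes are the top ceil(0.10 * n_genes) by variance of
log2(count/sf + 1) across controls, ties broken lexicographically. PCA
centers genes but does not scale them to unit variance: the variance ranking
just privileged high-variance genes and unit scaling would undo it
(`scale=True` is available). Variance fractions are relative to the total
over all components; the first 20 PCs are retained by default. Component
signs are fixed by making each component's largest-magnitude loading
positive, so embeddings are reproducible.

k-means (k-means++ seeding, Lloyd iterations, best of 25 restarts by WCSS)
runs in the PC space; labels are 1-based and renumbered by first appearance.
Candidate k are scored by:

* **WCSS** and **mean silhouette** (PC-space Euclidean distances; a
  singleton cluster's point contributes silhouette 0; duplicate points with
  zero within-cluster distance contribute 1).
* **Bootstrap Jaccard** (default B = 200): the reference clustering is
  compared, over the distinct samples present in each bootstrap resample,
  with the best-matching cluster of a re-clustering of the resample; the
  statistic is the mean over resamples, per cluster and overall.
* **Prediction strength** (default 100 repetitions): half-splits, both fold
  directions per repetition; test clusters of size < 2 are excluded from the
  minimum; k = 1 is exactly 1.
* **PAC** (default 80% subsampling, 200 iterations, thresholds 0.1/0.9, the
  common convention): consensus = co-clustering count / co-sampling count;
  pairs never co-sampled are excluded.

A k whose smallest cluster is below 15 samples is inadmissible. `choose_k`
in `auto` mode maximizes prediction strength over admissible k, breaking ties
by lower PAC then smaller k — an explicit, documented stand-in for expert
judgment; `fixed` mode pins a (necessarily admissible) k. All resampling
metrics derive their per-iteration seeds from one input seed and are
bit-reproducible.

## Meta-analysis and retention

Per gene, contrasts contribute (b_i, se_i) when the GLM converged with a
positive variance. Pooling is the closed-form inverse-variance fixed effect;
heterogeneity is Cochran's Q with I² = max(0, (Q-(n-1))/Q)*100 (0 when
Q = 0; undefined below two estimates, which fails the heterogeneity
criterion by definition). Retention requires all four of: estimates in ≥ 2
contrasts; ≥ 4 estimates sharing the pooled sign (exact zeros count as
inconsistent; the reference direction is the pooled estimate's sign);
I² < 50%; meta p < 0.05 (two-sided normal). Criteria 1 and 2 are applied
jointly and literally, so a gene measured in 2–3 contrasts can never be
retained under the defaults; `relax_sign_to_available=True` relaxes
criterion 2 to min(4, n_available) for sensitivity analyses. Retained genes
absent from every cluster-level FDR < 0.05 list are classified meta-only;
present in at least one, meta-overlapping.

## Signatures, networks, enrichment

Fold-change concordance uses Pearson r on pairwise-complete genes with
Fisher-z 95% CIs (r is undefined below 4 complete genes or for constant
vectors). The contrast network is the complete weighted graph with edge
weight |r|; betweenness centrality is computed on shortest paths under
distance 1 - |r| and reported unnormalized (a 5-node star's center scores
C(4,2) = 6). Cross-dataset overlap intersects the retained set with an
external treatment-only DE run's FDR < 0.05 set and splits it by sign
agreement of the pooled versus external log2FC. Drug-specific genes are the
set difference of retained sets from two runs under identical criteria (the
criteria objects are compared and must match).

ORA uses the hypergeometric upper tail P(X >= k) with the universe defined
as the genes actually tested in the source analysis — the conservative
convention, configurable — and BH within each direction. Gene-set content is
never bundled; any GMT file works, which makes results independent of
annotation-database versions by construction. The specificity filter keeps
terms at FDR < 0.05 with overlap ≥ 10 in the primary run that are not
FDR < 0.05 in the comparator run (absent terms count as not significant); a
looser comparator reporting threshold (e.g. 0.2) is available as an
annotation column only.

## Synthetic-data generator

The generator emulates the screen geometry the workflow targets: counts

    K ~ NB(mean = s_j * 2^(mu_g + delta_gc + t_j * beta_gc), alpha_g)

with baseline log2 expression mu_g ~ Uniform(0, 10) (count means ~1–1000),
gene-wise dispersions alpha_g ~ LogNormal(-2.3, 0.6) (median ~0.1),
per-gene-per-subgroup baseline offsets delta_gc ~ N(0, 0.5 log2 units) —
large enough for k-means to recover the subgroups from the embedding, which
the tests verify — library sizes s_j ~ LogNormal(0, 0.5), and drug effects
beta_gc = beta_g + eta_gc where |beta_g| equals `effect_mean_log2` (default
1.0) with random sign for a `frac_de` fraction of genes (default 0.1) and
eta_gc ~ N(0, tau) adds subgroup-specific heterogeneity to effect genes
(default tau 0.25). The study-scale configuration places 464 controls in
five subgroups of 60/60/60/72/212 samples (median 60) against 20 treated
samples, which are apportioned to the latent subgroups proportionally to the
control subgroup sizes — the treated arm inherits the control pool's
substructure, a modeling choice, since how treated samples relate to control
structure is not observable from a vehicle-only clustering. A second treated
arm (a comparator drug) can be drawn against the same simulated controls via
`simulate_arm`, reusing the stored gene-level parameters.

Deliberately not simulated: gene–gene correlation beyond the shared subgroup
offsets, batch-by-GC artifacts, splicing, and compositional effects. Passing
tests therefore demonstrate the pipeline's behavior under NB noise with
planted mixture structure, not performance on any particular real dataset.

## Statistical behavior and known limitations

Two properties of the procedure itself — not of this implementation — are
worth stating plainly, because the synthetic ground truth makes them
measurable:

* **Pooling over contrasts that share the treated group is anticonservative
  under the null.** Every cluster-wise contrast reuses the same treated
  samples, so the five effect estimates share the treated-group sampling
  noise (pairwise correlation roughly 0.6–0.8 at 20 treated vs 60–212
  controls). Inverse-variance pooling treats them as independent and
  understates the pooled SE by roughly a factor of two; combined with a raw
  (not FDR-adjusted) meta-p cutoff and the fact that sign consistency is
  nearly automatic when estimates share noise, about 7–10% of null genes
  pass all four retention criteria in the study-scale simulation, versus the
  nominal 5% suggested by the meta-p criterion alone. The retained set
  should therefore be read as an enriched candidate list, not an
  FDR-controlled one.

* **The I² criterion screens against reference-dependence, at a cost in
  recall.** The treated group is a fixed mixture of all latent subgroups, so
  subgroup baseline offsets leak into every cluster-wise estimate; three PC
  covariates span only part of the subgroup-contrast space, and for
  high-expression genes (tiny SEs) the residual leakage dominates Q. Under a
  homogeneous planted effect the workflow recovers ~60% of effect genes, and
  nearly every miss fails the I² < 50% criterion rather than significance.
  This is the filter doing its stated job — discarding genes whose apparent
  effect depends on the reference cluster — but it means recall is bounded
  by baseline heterogeneity, not by power, and is insensitive to effect
  size. The heterogeneity response itself is sound: the I² median over
  effect genes rises from ~25–35 (tau = 0) to ~84 (tau = 1).

Other limitations: the dispersion moderation is a fixed-weight trend
shrinkage (no outlier handling, no independent filtering, no fold-change
shrinkage); the Wald reference is the normal distribution (no t correction
at small n); meta-analysis is fixed-effect only (no random-effects or
small-study diagnostics); figures are exported as tables (fold-change
distributions with IQRs, forest-plot tables), not rendered.

## Problem sizes and determinism

The test suite and the acceptance script use the study-scale design
(2000 genes, 464 + 20 samples) for pipeline-level checks and reduced
resampling replicates for the stability suite (B = 50 bootstraps, 30
prediction-strength repetitions, 100 consensus iterations) — the library
defaults remain the full B = 200 / 100 / 200. One global seed deterministically
derives per-stage seeds by stage-name hashing; every output table carries the
configuration's manifest hash in its header comment, and two `run_all`
executions with the same config and seed are byte-identical.
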