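"""Synthetic count datasets with latent control subgroups and heterogeneous drug effects.

The generator emulates a perturbation screen in which a small drug-treated group
is compared against a much larger vehicle (DMSO) control pool that is itself a
mixture of several latent transcriptional subgroups. For gene g, subgroup c and
sample j the count is drawn

    count ~ NB(mean = s_j * 2^(mu_g + delta_gc + t_j * beta_gc), dispersion alpha_g)

with Var = mean + alpha_g * mean^2 (the same mean/dispersion convention used by
the differential-expression model), where

* mu_g is the gene's baseline log2 expression (uniform over ~1–1000 counts),
* delta_gc ~ N(0, subgroup_shift_sd) is a per gene x subgroup baseline offset
  that creates PCA-detectable control substructure,
* beta_gc = beta_g + eta_gc is the realized drug effect in subgroup c:
  a shared component beta_g (magnitude effect_mean_log2, random sign, nonzero
  for a frac_de fraction of genes) plus subgroup heterogeneity
  eta_gc ~ N(0, effect_heterogeneity_tau) drawn for DE genes only,
* s_j is a log-normal library-size factor and t_j the treatment indicator,
* alpha_g is a log-normal gene-wise dispersion.

All draws are deterministic given the config seed, and the ground truth
(per-gene effects, per-subgroup realized effects, latent subgroup labels and
the gene-level simulation parameters) is returned alongside the counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .countio import CountMatrix, SampleTable

VEHICLE_LABEL = "DMSO"


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults are deliberately modest; :func:`default_study_config` returns
    the study-scale configuration (464 controls in 5 subgroups vs 20 treated).
    """

    n_genes: int = 1000
    n_subgroups: int = 5
    controls_per_subgroup: list[int] = field(default_factory=lambda: [30, 30, 30, 30, 30])
    n_treated: int = 20
    frac_de: float = 0.1
    effect_mean_log2: float = 1.0
    effect_heterogeneity_tau: float = 0.25
    subgroup_shift_sd: float = 0.5
    dispersion_lognormal: tuple[float, float] = (-2.3, 0.6)
    libsize_log_sd: float = 0.5
    baseline_log2_range: tuple[float, float] = (0.0, 10.0)
    treatment_label: str = "ponatinib"
    seed: int = 0

    def __post_init__(self) -> None:
        self.controls_per_subgroup = [int(n) for n in self.controls_per_subgroup]
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_subgroups < 1:
            raise ConfigurationError("n_subgroups must be positive")
        if len(self.controls_per_subgroup) != self.n_subgroups:
            raise ConfigurationError(
                f"controls_per_subgroup has {len(self.controls_per_subgroup)} entries "
                f"for {self.n_subgroups} subgroups")
        if any(n <= 0 for n in self.controls_per_subgroup):
            raise ConfigurationError("every control subgroup must have > 0 samples")
        if self.n_treated <= 0:
            raise ConfigurationError("n_treated must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError("frac_de must lie in [0, 1]")
        for name in ("effect_heterogeneity_tau", "subgroup_shift_sd", "libsize_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        meanlog, sdlog = self.dispersion_lognormal
        if sdlog < 0:
            raise ConfigurationError("dispersion sdlog must be nonnegative")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["dispersion_lognormal"] = list(self.dispersion_lognormal)
        data["baseline_log2_range"] = list(self.baseline_log2_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
        for key in ("dispersion_lognormal", "baseline_log2_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Latent state of a simulated dataset.

    ``subgroup_effects_log2`` holds the realized effect beta_gc per gene and
    subgroup; ``subgroup_of_sample`` the latent label of every sample (controls
    and treated). The gene-level simulation parameters (baseline, subgroup
    baseline offsets, dispersions) are kept so further treated arms can be
    drawn against the same controls (:func:`simulate_arm`).
    """

    is_de: pd.Series
    true_effect_log2: pd.Series
    subgroup_effects_log2: pd.DataFrame
    subgroup_of_sample: pd.Series
    baseline_log2: pd.Series
    subgroup_offsets_log2: pd.DataFrame
    dispersions: pd.Series

    def de_gene_ids(self) -> list[str]:
        return list(self.is_de.index[self.is_de])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "is_de": self.is_de.astype(int),
            "true_effect_log2": self.true_effect_log2,
            "baseline_log2": self.baseline_log2,
            "dispersion": self.dispersions,
        })
        for c in self.subgroup_effects_log2.columns:
            df[f"effect_{c}"] = self.subgroup_effects_log2[c]
        return df


def default_study_config(seed: int = 0) -> SimConfig:
    """Study-scale configuration: 464 vehicle controls in five latent subgroups
    (sizes 60–212, median 60) against 20 drug-treated samples."""
    return SimConfig(
        n_genes=2000,
        n_subgroups=5,
        controls_per_subgroup=[60, 60, 60, 72, 212],
        n_treated=20,
        frac_de=0.1,
        effect_mean_log2=1.0,
        effect_heterogeneity_tau=0.25,
        subgroup_shift_sd=0.5,
        dispersion_lognormal=(-2.3, 0.6),
        libsize_log_sd=0.5,
        seed=seed,
    )


def _proportional_assignment(sizes: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n samples to subgroups by size."""
    quota = n * sizes / sizes.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) with Var = mean + alpha*mean^2; Poisson limit for tiny alpha."""
    alpha = np.broadcast_to(alpha, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        size = 1.0 / alpha[~tiny]
        p = size / (size + mean[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def simulate(config: SimConfig) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw one dataset: counts, sample metadata and ground truth.

    Treated samples are apportioned to the latent subgroups proportionally to
    the control subgroup sizes (largest remainder), so the treated arm inherits
    the control pool's substructure.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    K = config.n_subgroups
    sizes = np.asarray(config.controls_per_subgroup)
    n_ctrl = int(sizes.sum())

    gene_ids = [f"G{i:05d}" for i in range(G)]
    lo, hi = config.baseline_log2_range
    mu = rng.uniform(lo, hi, size=G)
    meanlog, sdlog = config.dispersion_lognormal
    alpha = rng.lognormal(meanlog, sdlog, size=G)
    delta = rng.normal(0.0, config.subgroup_shift_sd, size=(G, K)) \
        if config.subgroup_shift_sd > 0 else np.zeros((G, K))

    n_de = config.n_de
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    beta = np.zeros(G)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        beta[de_idx] = signs * config.effect_mean_log2
    eta = np.zeros((G, K))
    if n_de and config.effect_heterogeneity_tau > 0:
        eta[de_idx] = rng.normal(0.0, config.effect_heterogeneity_tau, size=(n_de, K))
    beta_gc = beta[:, None] + eta
    beta_gc[beta == 0] = 0.0  # heterogeneity applies to DE genes only

    ctrl_subgroup = np.repeat(np.arange(K), sizes)
    trt_counts = _proportional_assignment(sizes, config.n_treated)
    trt_subgroup = np.repeat(np.arange(K), trt_counts)
    subgroup = np.concatenate([ctrl_subgroup, trt_subgroup])
    treated = np.concatenate([np.zeros(n_ctrl, bool), np.ones(config.n_treated, bool)])
    n_samples = n_ctrl + config.n_treated

    s = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples)) \
        if config.libsize_log_sd > 0 else np.ones(n_samples)

    log2_mean = mu[:, None] + delta[:, subgroup]
    log2_mean = log2_mean + np.where(treated[None, :], beta_gc[:, subgroup], 0.0)
    mean = s[None, :] * np.exp2(log2_mean)
    counts = _nb_draw(rng, mean, alpha[:, None])

    sample_ids = ([f"C{i:04d}" for i in range(n_ctrl)] +
                  [f"T{i:04d}" for i in range(config.n_treated)])
    subgroup_cols = [f"S{c + 1}" for c in range(K)]

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    st = SampleTable(pd.DataFrame({
        "treatment": np.where(treated, config.treatment_label, VEHICLE_LABEL),
        "latent_subgroup": subgroup + 1,
    }, index=pd.Index(sample_ids, name="sample")))
    gt = GroundTruth(
        is_de=pd.Series(beta != 0, index=gene_ids),
        true_effect_log2=pd.Series(beta, index=gene_ids),
        subgroup_effects_log2=pd.DataFrame(beta_gc, index=gene_ids, columns=subgroup_cols),
        subgroup_of_sample=pd.Series(subgroup + 1, index=sample_ids),
        baseline_log2=pd.Series(mu, index=gene_ids),
        subgroup_offsets_log2=pd.DataFrame(delta, index=gene_ids, columns=subgroup_cols),
        dispersions=pd.Series(alpha, index=gene_ids),
    )
    return cm, st, gt


def simulate_arm(truth: GroundTruth, config: SimConfig, label: str,
                 n_treated: int, frac_de: float, effect_mean_log2: float,
                 effect_heterogeneity_tau: float, seed: int,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw an additional treated arm (e.g. a comparator drug) against the
    controls of an existing simulation.

    Reuses the gene baselines, subgroup offsets and dispersions stored in
    ``truth`` but draws independent effects, library sizes and counts. Returns
    the new arm's counts (genes x new samples), its sample metadata rows, and
    a GroundTruth describing the new arm's effects.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.baseline_log2.index)
    G = len(gene_ids)
    K = truth.subgroup_offsets_log2.shape[1]
    sizes = truth.subgroup_of_sample.value_counts().sort_index().to_numpy()[:K]

    n_de = int(round(frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    beta = np.zeros(G)
    if n_de:
        beta[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * effect_mean_log2
    eta = np.zeros((G, K))
    if n_de and effect_heterogeneity_tau > 0:
        eta[de_idx] = rng.normal(0.0, effect_heterogeneity_tau, size=(n_de, K))
    beta_gc = beta[:, None] + eta
    beta_gc[beta == 0] = 0.0

    trt_counts = _proportional_assignment(sizes, n_treated)
    subgroup = np.repeat(np.arange(K), trt_counts)
    s = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_treated)) \
        if config.libsize_log_sd > 0 else np.ones(n_treated)

    mu = truth.baseline_log2.to_numpy()
    delta = truth.subgroup_offsets_log2.to_numpy()
    alpha = truth.dispersions.to_numpy()
    log2_mean = mu[:, None] + delta[:, subgroup] + beta_gc[:, subgroup]
    mean = s[None, :] * np.exp2(log2_mean)
    counts = _nb_draw(rng, mean, alpha[:, None])

    sample_ids = [f"{label[:1].upper()}{i:04d}" for i in range(n_treated)]
    arm_counts = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    arm_samples = pd.DataFrame({
        "treatment": label,
        "latent_subgroup": subgroup + 1,
    }, index=pd.Index(sample_ids, name="sample"))
    subgroup_cols = list(truth.subgroup_offsets_log2.columns)
    arm_truth = GroundTruth(
        is_de=pd.Series(beta != 0, index=gene_ids),
        true_effect_log2=pd.Series(beta, index=gene_ids),
        subgroup_effects_log2=pd.DataFrame(beta_gc, index=gene_ids, columns=subgroup_cols),
        subgroup_of_sample=pd.Series(subgroup + 1, index=sample_ids),
        baseline_log2=truth.baseline_log2,
        subgroup_offsets_log2=truth.subgroup_offsets_log2,
        dispersions=truth.dispersions,
    )
    return arm_counts, arm_samples, arm_truth


def merge_arm(counts: CountMatrix, samples: SampleTable,
              arm_counts: pd.DataFrame, arm_samples: pd.DataFrame,
              ) -> tuple[CountMatrix, SampleTable]:
    """Append a simulated arm's samples to an existing dataset."""
    merged = pd.concat([counts.counts, arm_counts], axis=1)
    meta = pd.concat([samples.table, arm_samples], axis=0)
    return CountMatrix(merged), SampleTable(meta)
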