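"""End-to-end orchestration: simulate/load -> stratify -> DE -> meta -> signature -> ORA.

A single :class:`PipelineConfig` (YAML-serializable, unknown keys rejected)
drives the whole run. One global seed deterministically derives per-stage
seeds by stage-name hashing, so stages can be rerun in isolation and two runs
with the same config and seed produce byte-identical outputs. Every output
table carries a header comment with the tool version, the seed and the
manifest hash of the configuration; ``manifest.json`` records parameters and
SHA-256 checksums of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, countio, enrich, metapool, signature, syndata
from .model import StratifiedMetaDE
from .syndata import SimConfig


class PipelineError(ValueError):
    pass


def derive_stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed (stage-name hashing)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the discovery workflow."""

    # data: either file paths or a simulation config
    counts_path: str | None = None
    samples_path: str | None = None
    counts_format: str = "tsv"
    sim: SimConfig | None = None
    sim_comparator_n_treated: int = 0       # >0 adds a simulated comparator arm
    sim_comparator_frac_de: float = 0.0
    sim_comparator_effect_log2: float = 1.0
    sim_comparator_tau: float = 0.25

    vehicle: str = "DMSO"
    drug: str = "ponatinib"
    comparator: str | None = None

    var_frac: float = 0.10
    n_pcs: int = 20
    k: int | None = 5
    k_range: list[int] = field(default_factory=lambda: list(range(2, 11)))
    min_cluster_size: int = 15
    n_covariate_pcs: int = 3
    compute_stability: bool = False
    bootstrap_B: int = 200
    ps_repetitions: int = 100
    pac_iterations: int = 200
    pac_subsample_frac: float = 0.8
    kmeans_restarts: int = 25

    min_contrasts: int = 2
    min_sign_consistent: int = 4
    i2_max_percent: float = 50.0
    meta_p_max: float = 0.05

    external_counts_path: str | None = None
    external_samples_path: str | None = None
    external_fdr: float = 0.05
    gmt_path: str | None = None
    ora_down_log2fc_max: float = -1.0

    seed: int = 0

    def criteria(self) -> metapool.MetaCriteria:
        return metapool.MetaCriteria(
            min_contrasts=self.min_contrasts,
            min_sign_consistent=self.min_sign_consistent,
            i2_max_percent=self.i2_max_percent,
            meta_p_max=self.meta_p_max)

    def validate(self) -> None:
        has_files = self.counts_path is not None and self.samples_path is not None
        if not has_files and self.sim is None:
            raise PipelineError("config needs counts_path+samples_path or a sim block")
        if has_files and self.sim is not None:
            raise PipelineError("give either file paths or a sim block, not both")
        if not 0 < self.var_frac <= 1:
            raise PipelineError("var_frac must lie in (0, 1]")
        if (self.external_counts_path is None) != (self.external_samples_path is None):
            raise PipelineError("external dataset needs both counts and samples paths")

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        if self.sim is not None:
            sim = dataclasses.asdict(self.sim)
            sim["dispersion_lognormal"] = list(self.sim.dispersion_lognormal)
            sim["baseline_log2_range"] = list(self.sim.baseline_log2_range)
            data["sim"] = sim
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if data.get("sim") is not None:
            sim = dict(data["sim"])
            for key in ("dispersion_lognormal", "baseline_log2_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimConfig(**sim)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def manifest_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Execute the full workflow and write all artifacts under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mhash = config.manifest_hash()
    header = f"stratmeta {__version__} seed={config.seed} manifest={mhash}"
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index_label: str = "gene") -> None:
        path = out / name
        countio.write_table(df, path, header_comment=header, index_label=index_label)
        written.append(path)

    # -- data -------------------------------------------------------------
    truth = None
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=derive_stage_seed(config.seed, "simulate"))
        counts, samples, truth = syndata.simulate(sim)
        if config.sim_comparator_n_treated > 0:
            if config.comparator is None:
                raise PipelineError("simulated comparator arm needs a comparator label")
            arm_counts, arm_samples, _ = syndata.simulate_arm(
                truth, sim, config.comparator,
                n_treated=config.sim_comparator_n_treated,
                frac_de=config.sim_comparator_frac_de,
                effect_mean_log2=config.sim_comparator_effect_log2,
                effect_heterogeneity_tau=config.sim_comparator_tau,
                seed=derive_stage_seed(config.seed, "simulate-comparator"))
            counts, samples = syndata.merge_arm(counts, samples, arm_counts, arm_samples)
        countio.write_counts(counts, out / "counts.tsv", header_comment=header)
        countio.write_samples(samples, out / "samples.tsv", header_comment=header)
        emit(truth.to_frame(), "ground_truth.tsv")
        written.extend([out / "counts.tsv", out / "samples.tsv"])
    else:
        counts = countio.read_counts(config.counts_path, format=config.counts_format)
        samples = countio.read_samples(config.samples_path)

    # -- primary drug ------------------------------------------------------
    stability_kwargs = dict(B=config.bootstrap_B, ps_repetitions=config.ps_repetitions,
                            pac_iterations=config.pac_iterations,
                            subsample_frac=config.pac_subsample_frac)
    model = StratifiedMetaDE(
        counts, samples, config.drug, vehicle=config.vehicle,
        var_frac=config.var_frac, n_pcs=config.n_pcs, k=config.k,
        k_range=config.k_range, min_cluster_size=config.min_cluster_size,
        n_covariate_pcs=config.n_covariate_pcs, criteria=config.criteria(),
        kmeans_restarts=config.kmeans_restarts,
        stability_kwargs=stability_kwargs,
        seed=derive_stage_seed(config.seed, "stratify"))
    results = model.fit(compute_stability=config.compute_stability or config.k is None)

    emit(results.embedding.scores, "embedding_scores.tsv", index_label="sample")
    emit(results.projected_scores, "projected_scores.tsv", index_label="sample")
    emit(results.sample_table.table, "sample_assignments.tsv", index_label="sample")
    if results.stability is not None:
        emit(results.stability.table, "stability_report.tsv", index_label="k")
    for c, tab in sorted(results.de_tables.items()):
        emit(tab, f"de_cluster{c}.tsv")
    emit(results.meta, "meta.tsv")

    corr = results.fc_correlations()
    emit(corr.set_index("contrast_a"), "correlations.tsv", index_label="contrast_a")
    net = results.network()
    emit(net.nodes, "network_nodes.tsv", index_label="contrast")
    emit(net.edges.set_index("contrast_a"), "network_edges.tsv", index_label="contrast_a")
    emit(signature.fc_distribution_summary(results.fold_change_profile()),
         "fc_summary.tsv", index_label="contrast")
    common, signs = results.intersect_degs()
    emit(signs, "cluster_deg_intersection.tsv")

    with open(out / "summary.txt", "w") as fh:
        fh.write(f"# {header}\n")
        fh.write(results.summary() + "\n")
    written.append(out / "summary.txt")

    manifest: dict = {
        "tool": "stratmeta",
        "version": __version__,
        "seed": config.seed,
        "manifest_hash": mhash,
        "parameters": config.to_dict(),
        "k": results.k,
        "n_retained": int(results.meta["retained"].sum()),
        "n_meta_only": int((results.meta["class"] == "meta-only").sum()),
        "cluster_deg_counts": {str(c): len(s)
                               for c, s in results.cluster_deg_sets().items()},
        "n_intersection": len(common),
    }

    # -- comparator drug (same clusters, identical parameters) -------------
    comparator_results = None
    if config.comparator is not None and \
            len(samples.samples_with(config.comparator)) >= 2:
        comp_model = StratifiedMetaDE(
            counts, samples, config.comparator, vehicle=config.vehicle,
            var_frac=config.var_frac, n_pcs=config.n_pcs, k=results.k,
            k_range=config.k_range, min_cluster_size=config.min_cluster_size,
            n_covariate_pcs=config.n_covariate_pcs, criteria=config.criteria(),
            kmeans_restarts=config.kmeans_restarts,
            stability_kwargs=stability_kwargs,
            seed=derive_stage_seed(config.seed, "stratify"))
        comparator_results = comp_model.fit(compute_stability=False)
        for c, tab in sorted(comparator_results.de_tables.items()):
            emit(tab, f"de_comparator_cluster{c}.tsv")
        emit(comparator_results.meta, "meta_comparator.tsv")
        specific, sym = signature.drug_specific_genes(
            results.retained_genes(), comparator_results.retained_genes(),
            config.criteria(), config.criteria())
        with open(out / "specific_genes.txt", "w") as fh:
            fh.write(f"# {header}\n")
            for g in sorted(specific):
                fh.write(g + "\n")
        written.append(out / "specific_genes.txt")
        manifest["n_comparator_retained"] = int(comparator_results.meta["retained"].sum())
        manifest["n_drug_specific"] = len(specific)

    # -- external dataset --------------------------------------------------
    external_table = None
    if config.external_counts_path is not None:
        ext_counts = countio.read_counts(config.external_counts_path,
                                         format=config.counts_format)
        ext_samples = countio.read_samples(config.external_samples_path)
        external_table = signature.external_de(ext_counts, ext_samples, config.drug,
                                               vehicle=config.vehicle)
        emit(external_table, "external_de.tsv")
        report = signature.cross_dataset_overlap(results.meta, external_table,
                                                 external_fdr=config.external_fdr)
        emit(report.effects, "overlap.tsv")
        manifest["n_shared"] = len(report.shared)
        manifest["n_concordant"] = len(report.concordant)

    # -- enrichment --------------------------------------------------------
    if config.gmt_path is not None:
        collection = countio.read_gmt(config.gmt_path)
        universe = set(results.meta.index)
        retained_meta = results.meta[results.meta["retained"]]
        queries = enrich.split_by_direction(
            retained_meta, fdr_max=1.0,  # retention already filtered
            down_log2fc_max=config.ora_down_log2fc_max,
            fc_column="pooled_log2fc", fdr_column="meta_p")
        tables = enrich.run_ora_directional(queries, collection, universe)
        for direction, tab in tables.items():
            emit(tab, f"ora_{direction}.tsv", index_label="term_id")
        if comparator_results is not None:
            comp_meta = comparator_results.meta[comparator_results.meta["retained"]]
            comp_queries = enrich.split_by_direction(
                comp_meta, fdr_max=1.0,
                down_log2fc_max=config.ora_down_log2fc_max,
                fc_column="pooled_log2fc", fdr_column="meta_p")
            comp_tables = enrich.run_ora_directional(
                comp_queries, collection, set(comparator_results.meta.index))
            for direction in tables:
                spec = enrich.specificity_filter(tables[direction],
                                                 comp_tables[direction])
                emit(spec, f"ora_{direction}_specific.tsv", index_label="term_id")

    manifest["checksums"] = {p.name: _sha256(p) for p in sorted(set(written))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
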