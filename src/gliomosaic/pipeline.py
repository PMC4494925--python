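"""End-to-end orchestration of the spatial multi-omic analysis.

Stage order follows the analysis: synthetic cohort (or file input) ->
copy-number profiles -> sample structure (PCA/HCPC/gene scores) ->
differential expression -> co-expression network -> methylation
anti-correlation -> key-gene signature -> subtype assignment.  All
outputs are flat TSV files with sorted, stable row ordering, plus a JSON
manifest recording parameters, per-stage seeds, and output hashes, so a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna as cna_mod
from . import de as de_mod
from . import methylation as meth_mod
from . import network as net_mod
from . import signature as sig_mod
from . import structure as struct_mod
from .synthetic import Cohort, CohortConfig, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_matrix",
           "read_cna_probes", "read_gmt"]

log = logging.getLogger("gliomosaic")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All stage parameters and toggles of the pipeline.

    Defaults are the study settings: 4 sample clusters, top 8000 genes,
    soft power 12, minimum module size 175, DE at adjusted p < 0.001 and
    |FC| > 2, anti-correlation at r < -0.6 with a 1000-draw null, 25
    signature genes per significant module.
    """

    outdir: str | Path = "results"
    seed: int = 0
    # inputs: simulate by default, or read TSVs
    simulate: bool = True
    cohort: CohortConfig | None = None
    expression_path: str | None = None
    methylation_path: str | None = None
    cna_path: str | None = None
    annotation_path: str | None = None
    centroids_path: str | None = None
    gene_sets_path: str | None = None   # GMT alternative to centroids
    # stage toggles
    run_cna: bool = True
    run_structure: bool = True
    run_de: bool = True
    run_network: bool = True
    run_methylation: bool = True
    run_signature: bool = True
    run_subtype: bool = True
    # stage parameters
    k: int = 4
    scale_pca: bool = True
    top_n: int = 8000
    seg_fdr: float = 0.05
    mcr_n_perm: int = 1000
    mcr_alpha: float = 0.05
    p_adj_threshold: float = 0.001
    min_fc: float = 2.0
    beta: int = 12
    min_module_size: int = 175
    module_n_perm: int = 1000
    module_alpha: float = 0.05
    knn_k: int = 10
    anticorr_r: float = -0.6
    n_boot: int = 1000
    boot_ci: float = 0.99
    per_module: int = 25
    signature_contrast: tuple[int, int] | None = None

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["cohort", "mcr", "modules", "bootstrap"]
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in
                zip(names, children)}


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort | None
    tables: dict[str, object] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_cna_probes(path: str | Path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    return {s: g.drop(columns="sample").reset_index(drop=True)
            for s, g in long.groupby("sample", sort=True)}


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write results + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "parameters": {
            f.name: str(getattr(config, f.name))
            for f in dataclasses.fields(config) if f.name not in ("cohort",)
        },
        "seeds": seeds,
        "files": {},
        "counts": {},
    }
    files = manifest["files"]
    result = PipelineResult(config=config, cohort=None, manifest=manifest)
    tables = result.tables

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        cc = config.cohort or CohortConfig(seed=seeds["cohort"])
        cohort = generate_cohort(cc)
        result.cohort = cohort
        expression, methylation = cohort.expression, cohort.methylation
        cna_tracks, annotation = cohort.cna, cohort.annotation
        write_cohort(cohort, outdir / "cohort")
    else:
        if config.expression_path is None or config.annotation_path is None:
            raise ValueError("expression and annotation paths are required "
                             "when simulation is disabled")
        expression = read_matrix(config.expression_path)
        annotation = pd.read_csv(config.annotation_path, sep="\t", index_col=0)
        methylation = (read_matrix(config.methylation_path)
                       if config.methylation_path else None)
        cna_tracks = (read_cna_probes(config.cna_path)
                      if config.cna_path else None)
    manifest["counts"]["genes"] = int(expression.shape[0])
    manifest["counts"]["samples"] = int(expression.shape[1])
    log.info("input: %d genes x %d samples", *expression.shape)

    # ---- copy-number profiles -------------------------------------------
    if config.run_cna and cna_tracks is not None:
        profiles: dict[str, cna_mod.CallProfile] = {}
        summaries = []
        for sample in sorted(cna_tracks):
            track = cna_mod.normalize_track(cna_tracks[sample])
            segs = cna_mod.segment_track(track, fdr_level=config.seg_fdr)
            prof = cna_mod.call_segments(segs, track=track)
            profiles[sample] = prof
            s = cna_mod.percent_altered(prof)
            summaries.append({
                "sample": sample, "percent_loss": s.percent_loss,
                "percent_gain": s.percent_gain, "percent_amp": s.percent_amp,
                "percent_normal": s.percent_normal,
                "percent_altered": s.percent_altered,
                "is_non_tumor": s.is_non_tumor,
            })
        summary = pd.DataFrame(summaries).set_index("sample")
        call_matrix = pd.DataFrame(
            {s: profiles[s].probes["state"].to_numpy() for s in profiles}).T
        _, cna_clusters, unaltered = cna_mod.cluster_call_profiles(call_matrix)
        summary["cna_cluster"] = cna_clusters
        summary["unaltered_like"] = summary["cna_cluster"] == unaltered
        mcr = cna_mod.find_mcr(profiles, n_perm=config.mcr_n_perm,
                               alpha=config.mcr_alpha, seed=seeds["mcr"])
        tables["cna_summary"] = summary
        tables["cna_profiles"] = profiles
        tables["mcr"] = mcr
        files["cna_calls.tsv"] = _write(cna_mod.calls_to_seg(profiles),
                                        outdir / "cna_calls.tsv", index=False)
        files["cna_summary.tsv"] = _write(summary, outdir / "cna_summary.tsv")
        files["mcr.tsv"] = _write(mcr, outdir / "mcr.tsv", index=False)
        files["mcr.bed"] = _write(cna_mod.mcr_to_bed(mcr), outdir / "mcr.bed",
                                  index=False, header=False)
        manifest["counts"]["non_tumor_samples"] = int(summary["is_non_tumor"].sum())
        log.info("cna: %d samples, %d flagged non-tumor, %d MCRs",
                 len(summary), summary["is_non_tumor"].sum(), len(mcr))

    # ---- sample structure ------------------------------------------------
    clusters = None
    eigen_scores = None
    top_genes = None
    if config.run_structure:
        pca = struct_mod.run_pca(expression, scale=config.scale_pca)
        clusters = struct_mod.hcpc(pca, k=config.k)
        eigen_scores = struct_mod.eigen_gene_score(pca)
        top_genes = struct_mod.select_top_genes(
            eigen_scores, min(config.top_n, len(eigen_scores)))
        tables["pca"] = pca
        tables["clusters"] = clusters
        tables["eigen_scores"] = eigen_scores
        tables["top_genes"] = top_genes
        struct_out = pd.DataFrame({
            "cluster": clusters.labels,
            "pc1": pca.scores.iloc[:, 0],
            "pc2": pca.scores.iloc[:, 1] if pca.scores.shape[1] > 1 else np.nan,
        })
        files["clusters.tsv"] = _write(struct_out, outdir / "clusters.tsv")
        files["eigen_scores.tsv"] = _write(
            eigen_scores.to_frame(), outdir / "eigen_scores.tsv")
        manifest["counts"]["top_genes"] = len(top_genes)
        log.info("structure: k=%d clusters over %d components; top %d genes",
                 clusters.k, clusters.n_components, len(top_genes))

    # ---- differential expression ----------------------------------------
    detab = None
    if config.run_de:
        if clusters is None:
            raise ValueError("differential expression requires the structure stage")
        detab = de_mod.de_table(expression, clusters.labels,
                                p_adj_threshold=config.p_adj_threshold,
                                min_fc=config.min_fc)
        tables["de"] = detab
        files["de_table.tsv"] = _write(detab, outdir / "de_table.tsv")
        manifest["counts"]["de_genes"] = int(detab["de"].sum())
        log.info("de: %d/%d genes differentially expressed",
                 detab["de"].sum(), len(detab))

    # ---- co-expression network ------------------------------------------
    module_set = None
    if config.run_network:
        if top_genes is None or detab is None:
            raise ValueError("network stage requires structure and DE stages")
        sub = expression.loc[top_genes]
        adj = net_mod.signed_adjacency(sub, beta=config.beta)
        to = net_mod.topological_overlap(adj)
        del adj
        labels = net_mod.detect_modules(to, min_module_size=config.min_module_size)
        del to
        module_set = net_mod.build_module_set(
            sub, labels, detab["p_adj"], n_perm=config.module_n_perm,
            alpha=config.module_alpha, seed=seeds["modules"])
        tables["modules"] = module_set
        files["modules.tsv"] = _write(
            pd.DataFrame({"module": module_set.labels,
                          "gs": module_set.gs,
                          **{f"mm_{m}": module_set.mm[m]
                             for m in module_set.mm.columns}}),
            outdir / "modules.tsv")
        files["eigengenes.tsv"] = _write(module_set.eigengenes,
                                         outdir / "eigengenes.tsv")
        files["module_stats.tsv"] = _write(module_set.stats,
                                           outdir / "module_stats.tsv")
        manifest["counts"]["modules"] = len(module_set.stats)
        manifest["counts"]["significant_modules"] = len(
            module_set.significant_modules)
        log.info("network: %d modules (%d significant)",
                 len(module_set.stats), len(module_set.significant_modules))

    # ---- methylation anti-correlation -----------------------------------
    curve = None
    if config.run_methylation and methylation is not None:
        if eigen_scores is None:
            raise ValueError("methylation stage requires the structure stage")
        imputed = meth_mod.impute_knn(methylation, k=config.knn_k)
        corr = meth_mod.expr_meth_correlation(expression, imputed,
                                              threshold=config.anticorr_r)
        curve = meth_mod.anticorrelation_curve(
            corr["anticorr"], eigen_scores, n_boot=config.n_boot,
            ci=config.boot_ci, seed=seeds["bootstrap"])
        tables["meth_corr"] = corr
        tables["curve"] = curve
        files["anticorr.tsv"] = _write(corr, outdir / "anticorr.tsv")
        files["anticorr_curve.tsv"] = _write(curve.table,
                                             outdir / "anticorr_curve.tsv",
                                             index=False)
        manifest["counts"]["anticorr_genes"] = int(corr["anticorr"].sum())
        log.info("methylation: %d/%d anti-correlated; peak %.1f%% at %d genes",
                 corr["anticorr"].sum(), len(corr), curve.peak_percent,
                 curve.peak_size)

    # ---- key-gene signature ---------------------------------------------
    signature = None
    if config.run_signature:
        if module_set is None or clusters is None:
            raise ValueError("signature stage requires network and structure stages")
        if config.signature_contrast is not None:
            a, b = config.signature_contrast
            keep = clusters.labels.isin([a, b])
            if keep.sum() >= 4 and clusters.labels[keep].nunique() == 2:
                sub_labels = clusters.labels[keep]
                contrast_de = de_mod.de_table(
                    expression.loc[:, sub_labels.index], sub_labels,
                    p_adj_threshold=config.p_adj_threshold, min_fc=config.min_fc)
            else:
                contrast_de = detab
        else:
            contrast_de = detab
        anticorr_flags = (tables["meth_corr"]["anticorr"]
                          if "meth_corr" in tables else None)
        signature = sig_mod.select_key_genes(
            eigen_scores, contrast_de, module_set,
            per_module=config.per_module, anticorr_flags=anticorr_flags)
        check = sig_mod.signature_structure_check(
            expression, signature.genes, clusters)
        tables["signature"] = signature
        tables["signature_check"] = check
        files["signature.tsv"] = _write(signature.table, outdir / "signature.tsv")
        manifest["counts"]["signature_genes"] = len(signature.genes)
        manifest["counts"]["signature_ari"] = round(check.ari, 6)
        log.info("signature: %d genes; structure ARI %.3f",
                 len(signature.genes), check.ari)

    # ---- subtype assignment ---------------------------------------------
    if config.run_subtype:
        centroids = None
        gene_sets = None
        if config.centroids_path:
            centroids = read_matrix(config.centroids_path)
        elif config.gene_sets_path:
            gene_sets = read_gmt(config.gene_sets_path)
        elif result.cohort is not None:
            centroids = result.cohort.truth.subtype_centroids
        if centroids is not None or gene_sets is not None:
            scores = sig_mod.subtype_scores(expression, gene_sets=gene_sets,
                                            centroids=centroids)
            assignment = sig_mod.assign_subtype(scores, annotation=annotation)
            tables["subtypes"] = assignment
            out = pd.DataFrame({"subtype": assignment.labels}).join(scores)
            files["subtypes.tsv"] = _write(out, outdir / "subtypes.tsv")
            if assignment.patient_subtypes is not None:
                ps = assignment.patient_subtypes.map(lambda t: ",".join(t))
                files["patient_subtypes.tsv"] = _write(
                    ps.to_frame("subtypes"), outdir / "patient_subtypes.tsv")
            log.info("subtypes assigned for %d samples", len(assignment.labels))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
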