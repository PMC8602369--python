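"""End-to-end orchestration of the Epromoter identification chain.

Stages, in dependency order: STARR activity quantification -> DE
classification -> response-set assignment -> composite-ISGF3 nearest-peak
annotation -> ISRE site counting -> TSS clustering with TAD status and
Epromoter-like prediction -> proximity / enrichment statistics. The
in-memory engine (:func:`run_pipeline`) is the workhorse; :func:`run_all`
wraps it with file I/O from a run configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding_analysis import annotate_nearest_peaks, binding_matrix, composite_peaks
from .cluster_calling import ClusterConfig, build_cluster_table, cluster_tss
from .core_io import (
    GenomicInterval,
    PromoterDesign,
    ScoredSite,
    read_bed,
    read_chrom_sizes,
    read_promoter_table,
    read_table,
    read_tss_table,
)
from .expression_classes import DEConfig, assign_promoter_sets, classify_de, count_labels
from .isre_sites import MotifConfig, isre_count_table
from .starr_activity import StarrConfig, quantify_activity
from .stats_tests import (
    EnrichmentConfig,
    ks_test,
    nn_distances,
    random_gene_control,
    shuffle_enrichment,
)

logger = logging.getLogger("epromoter")


@dataclass
class RunConfig:
    """Paths and per-stage settings for a file-based pipeline run."""

    counts: str | Path
    promoters: str | Path
    tss: str | Path
    de_table: str | Path
    tf_peaks: Mapping[str, str | Path] = field(default_factory=dict)
    isre_sites: str | Path | None = None
    tads: str | Path | None = None
    chrom_sizes: str | Path | None = None
    outdir: str | Path = "epromoter_out"
    starr: StarrConfig = field(default_factory=StarrConfig)
    de: DEConfig = field(default_factory=DEConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    activity: pd.DataFrame
    gene_classes: pd.DataFrame
    promoter_sets: pd.DataFrame
    gene_sets: pd.DataFrame
    label_counts: pd.DataFrame
    isgf3_annotation: pd.DataFrame | None
    isre_counts: pd.DataFrame | None
    clustered_loci: pd.DataFrame
    clusters: pd.DataFrame
    proximity: dict | None
    enrichment: dict | None
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def summarize_categories(counts: Mapping[str, int]) -> dict:
    """Counts and percentages (two decimals) per category; sums to 100 ± 0.1.

    Empty categories are reported as 0.00 %, never omitted. Raises on an
    empty table.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot summarise an empty category table")
    out = {}
    for key, n in counts.items():
        out[key] = {"count": int(n), "pct": round(100.0 * n / total, 2)}
    return out


def run_pipeline(
    counts: pd.DataFrame,
    promoters: pd.DataFrame,
    tss_table: pd.DataFrame,
    de_table: pd.DataFrame | None,
    tf_peaks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    isre_sites: Mapping[str, Sequence[ScoredSite]] | None = None,
    tads: Sequence[GenomicInterval] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    starr_config: StarrConfig | None = None,
    de_config: DEConfig | None = None,
    motif_config: MotifConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    enrichment_config: EnrichmentConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on in-memory inputs; any stage failure aborts with
    the stage name and cause."""
    starr_config = starr_config or StarrConfig()
    de_config = de_config or DEConfig()
    motif_config = motif_config or MotifConfig()
    cluster_config = cluster_config or ClusterConfig()
    design = starr_config.design

    # ---- starr_activity ----------------------------------------------------
    @_stage("starr_activity")
    def _activity():
        region_len = design.upstream + design.downstream
        return quantify_activity(counts, region_len, starr_config)
    activity = _activity()

    # ---- expression_classes ------------------------------------------------
    @_stage("expression_classes")
    def _classes():
        if de_table is None:
            raise ValueError("no DE table provided")
        gene_classes = classify_de(de_table, de_config)
        promoter_sets, gene_sets = assign_promoter_sets(
            gene_classes, activity, promoters
        )
        return gene_classes, promoter_sets, gene_sets
    gene_classes, promoter_sets, gene_sets = _classes()
    label_counts = count_labels(promoter_sets, gene_sets)

    # ---- binding_analysis --------------------------------------------------
    isgf3_annotation = None
    binding = None
    if tf_peaks:
        @_stage("binding_analysis")
        def _binding():
            composite = composite_peaks(tf_peaks)
            induced_only = gene_sets.loc[
                gene_sets["set_labels"].str.contains("induced_gene_only"), "gene_id"
            ]
            genes_df = tss_table[tss_table["gene_id"].isin(induced_only)]
            annotation = (
                annotate_nearest_peaks(genes_df, composite, tss_table, design.flank)
                if len(genes_df) and composite else pd.DataFrame(
                    columns=["gene_id", "distance", "category"])
            )
            windows = {
                row.promoter_id: design.flank_window(row.chrom, int(row.tss))
                for row in promoters.itertuples(index=False)
            }
            return annotation, binding_matrix(windows, tf_peaks)
        isgf3_annotation, binding = _binding()

    # ---- isre_sites --------------------------------------------------------
    isre_counts = None
    if isre_sites:
        @_stage("isre_sites")
        def _isre():
            windows = {
                row.promoter_id: design.capture_window(
                    row.chrom, int(row.tss), row.strand
                )
                for row in promoters.itertuples(index=False)
            }
            return isre_count_table(windows, isre_sites, motif_config)
        isre_counts = _isre()

    # ---- cluster_calling ---------------------------------------------------
    @_stage("cluster_calling")
    def _clusters():
        induced_genes = set(gene_classes.loc[
            gene_classes["de_class"] == "induced", "gene_id"
        ])
        induced_ep_promoters = set(activity.loc[
            activity["induced_epromoter"], "promoter_id"
        ])
        loci = promoters[
            promoters["gene_id"].isin(induced_genes)
            | promoters["promoter_id"].isin(induced_ep_promoters)
        ][["promoter_id", "gene_id", "chrom", "tss"]].rename(
            columns={"promoter_id": "locus_id"}
        )
        clustered = cluster_tss(loci, cluster_config)
        table = build_cluster_table(clustered, gene_sets, promoters, binding, tads or [])
        return clustered, table
    clustered_loci, clusters = _clusters()

    # ---- stats -------------------------------------------------------------
    proximity = None
    @_stage("stats_proximity")
    def _proximity():
        induced = tss_table[tss_table["gene_id"].isin(
            gene_classes.loc[gene_classes["de_class"] == "induced", "gene_id"]
        )]
        if len(induced) < 4:
            return None
        obs, n_excl = nn_distances(induced)
        control = random_gene_control(tss_table, len(induced), seed)
        ctrl, _ = nn_distances(control)
        D, p = ks_test(obs.to_numpy(), ctrl.to_numpy())
        return {
            "n_induced": int(len(induced)),
            "n_excluded": int(n_excl),
            "median_nn_induced": float(np.median(obs)),
            "median_nn_control": float(np.median(ctrl)),
            "ks_D": D,
            "ks_p": p,
        }
    proximity = _proximity()

    enrichment = None
    if tf_peaks and chrom_sizes and isgf3_annotation is not None and len(isgf3_annotation):
        @_stage("stats_enrichment")
        def _enrich():
            composite = composite_peaks(tf_peaks)
            other_windows = [
                design.flank_window(row.chrom, int(row.tss))
                for row in tss_table.itertuples(index=False)
            ]
            cfg = enrichment_config or EnrichmentConfig(
                seed=seed, chrom_sizes=chrom_sizes
            )
            if cfg.chrom_sizes is None:
                cfg = EnrichmentConfig(
                    n_shuffles=cfg.n_shuffles, seed=cfg.seed, chrom_sizes=chrom_sizes
                )
            res = shuffle_enrichment(composite, other_windows, cfg)
            return {
                "observed": res.observed,
                "shuffle_mean": res.shuffle_mean,
                "shuffle_sd": res.shuffle_sd,
                "p_value": res.p_value,
                "model": res.model,
            }
        enrichment = _enrich()

    # ---- summary -----------------------------------------------------------
    summary: dict = {
        "tau": {k: float(v) for k, v in activity.attrs.get("tau", {}).items()},
        "n_promoters": int(len(activity)),
        "n_removed": int(activity["removed"].sum()),
        "n_induced_epromoters": int(activity["induced_epromoter"].sum()),
        "n_repressed_epromoters": int(activity["repressed_epromoter"].sum()),
        "n_constitutive_epromoters": int(activity["constitutive_epromoter"].sum()),
        "response_sets": {
            row.set_label: {"promoters": int(row.n_promoters), "genes": int(row.n_genes)}
            for row in label_counts.itertuples(index=False)
        },
        "n_clusters": int(len(clusters)),
        "n_clusters_with_epromoter": int(clusters["has_epromoter"].sum()) if len(clusters) else 0,
        "n_epromoter_like_clusters": int(clusters["epromoter_like"].fillna(False).sum())
        if len(clusters) and clusters["epromoter_like"].notna().any() else 0,
        "tad_status": clusters["tad_status"].value_counts().to_dict() if len(clusters) else {},
    }
    if isgf3_annotation is not None and len(isgf3_annotation):
        cat_counts = isgf3_annotation["category"].value_counts().to_dict()
        for cat in ("same_promoter", "another_promoter", "intergenic"):
            cat_counts.setdefault(cat, 0)
        summary["isgf3_categories"] = summarize_categories(cat_counts)
    if isre_counts is not None and len(isre_counts):
        summary["isre_class_all"] = summarize_categories(
            {k: int(v) for k, v in isre_counts["class_all"].value_counts().items()}
        )
        summary["isre_class_highconf"] = summarize_categories(
            {k: int(v) for k, v in isre_counts["class_highconf"].value_counts().items()}
        )
    if proximity:
        summary["proximity"] = proximity
    if enrichment:
        summary["isgf3_promoter_enrichment"] = enrichment

    return PipelineResult(
        activity=activity,
        gene_classes=gene_classes,
        promoter_sets=promoter_sets,
        gene_sets=gene_sets,
        label_counts=label_counts,
        isgf3_annotation=isgf3_annotation,
        isre_counts=isre_counts,
        clustered_loci=clustered_loci,
        clusters=clusters,
        proximity=proximity,
        enrichment=enrichment,
        summary=summary,
    )


def run_all(config: RunConfig) -> PipelineResult:
    """File-based run: read inputs, execute every stage, write outputs."""
    counts = read_table(config.counts)
    promoters = read_promoter_table(config.promoters)
    tss_table = read_tss_table(config.tss)
    de_table = read_table(config.de_table) if config.de_table else None
    tf_peaks = {
        tf: read_bed(path) for tf, path in (config.tf_peaks or {}).items()
    } or None
    isre = None
    if config.isre_sites:
        site_ivs = read_bed(config.isre_sites)
        isre = {}
        for iv in site_ivs:
            tf = iv.name or "unknown"
            isre.setdefault(tf, []).append(ScoredSite(iv, tf, iv.p_value))
    tads = read_bed(config.tads) if config.tads else None
    sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None

    result = run_pipeline(
        counts, promoters, tss_table, de_table, tf_peaks, isre, tads, sizes,
        starr_config=config.starr, de_config=config.de,
        motif_config=config.motif, cluster_config=config.cluster,
        enrichment_config=config.enrichment, seed=config.seed,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.activity.to_csv(outdir / "activity.tsv", sep="\t", index=False)
    result.gene_classes.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    result.promoter_sets.to_csv(outdir / "promoter_sets.tsv", sep="\t", index=False)
    result.gene_sets.to_csv(outdir / "gene_sets.tsv", sep="\t", index=False)
    result.clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    if result.isgf3_annotation is not None:
        result.isgf3_annotation.to_csv(outdir / "isgf3_annotation.tsv", sep="\t", index=False)
    if result.isre_counts is not None:
        result.isre_counts.to_csv(outdir / "isre_counts.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True))
    logger.info("run_all: wrote outputs to %s", outdir)
    return result


# ---------------------------------------------------------------------------
# Recovery evaluation against planted ground truth
# ---------------------------------------------------------------------------

def evaluate_recovery(result: PipelineResult, dataset) -> dict:
    """Compare pipeline calls with the generator's planted truth.

    Returns induced-Epromoter precision/recall, mean best-match Jaccard of
    cluster memberships (over truth clusters), and the Epromoter-like
    prediction accuracy over truth clusters (an unmatched truth cluster
    counts as an error).
    """
    truth_prom = dataset.promoters.set_index("promoter_id")
    act = result.activity.set_index("promoter_id")
    called = act["induced_epromoter"].reindex(truth_prom.index).fillna(False)
    truth = truth_prom["is_induced_epromoter"]
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")

    truth_sets = [
        set(m.split(",")) for m in dataset.truth_clusters["members"]
    ]
    called_sets = [
        set(m.split(",")) for m in result.clusters["members"]
    ] if len(result.clusters) else []
    jaccards = []
    matches: list[int | None] = []
    for ts in truth_sets:
        best, best_j = None, 0.0
        for k, cs in enumerate(called_sets):
            j = len(ts & cs) / len(ts | cs)
            if j > best_j:
                best, best_j = k, j
        jaccards.append(best_j)
        matches.append(best)
    mean_jaccard = float(np.mean(jaccards)) if jaccards else float("nan")

    correct = 0
    ep_truth = dataset.truth_clusters["epromoter_like_truth"].tolist()
    ep_called = result.clusters["epromoter_like"].tolist() if len(result.clusters) else []
    for i, match in enumerate(matches):
        if match is not None and ep_called[match] is not None:
            correct += int(bool(ep_called[match]) == bool(ep_truth[i]))
    ep_accuracy = correct / len(ep_truth) if ep_truth else float("nan")

    return {
        "induced_epromoter_precision": precision,
        "induced_epromoter_recall": recall,
        "induced_epromoter_tp": tp,
        "induced_epromoter_fp": fp,
        "induced_epromoter_fn": fn,
        "cluster_jaccard": mean_jaccard,
        "n_truth_clusters": len(truth_sets),
        "n_called_clusters": len(called_sets),
        "epromoter_like_accuracy": ep_accuracy,
    }
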