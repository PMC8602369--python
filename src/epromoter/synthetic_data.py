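"""Synthetic genome, count, expression, and TF-track generator with planted
ground truth.

The generator emulates the statistical structure the analysis assumes at
desk scale: a capture STARR-seq promoter screen with negative-binomial count
noise, a minority of promoters with planted enhancer activity (constitutive
Epromoters) or planted activity induction (induced Epromoters), clusters of
co-induced genes sharing a single TF-bound hub promoter, ISRE motif-site
tracks with match p-values, and TAD intervals covering clusters. All
randomness flows from one seed through per-component substreams, so adding
a new simulated track does not perturb existing draws.

Model notes
-----------
* The STARR input is a single plasmid library (condition-independent); its
  counts are drawn once and shared across conditions and replicates.
* Per-promoter capture efficiency multiplies both input and reporter means,
  as in the real assay, and therefore cancels in the fold-change.
* Library totals include a constant off-target read mass (capture
  efficiency < 100 %), so FPKM normalisation sees realistic library sizes
  rather than the bare sum of captured counts.
* ``nb_dispersion`` is the DESeq2-style dispersion alpha
  (var = mu + alpha*mu^2); dispersion 0 produces noise-free counts equal to
  the rounded means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GenomicInterval,
    PromoterDesign,
    ScoredSite,
    write_bed,
    write_chrom_sizes,
    write_table,
)
from .isre_sites import DEFAULT_ISRE_TFS

ISGF3_TFS = ("STAT1", "STAT2", "IRF9")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a response-enriched desk-scale genome: 2,000 genes
    (2,500 promoters through alternative promoters) on ten 30-Mb
    chromosomes, 40 planted clusters of 2-5 co-induced genes, half of them
    carrying a TF-bound hub Epromoter, plus standalone induced Epromoters
    on non-induced genes, constitutive Epromoters, and scattered induced /
    repressed genes.
    """

    seed: int = 0
    n_chroms: int = 10
    chrom_length: int = 30_000_000
    n_genes: int = 2000
    frac_alt_promoters: float = 0.25
    n_clusters: int = 40
    cluster_members_min: int = 2
    cluster_members_max: int = 5
    cluster_span: int = 80_000
    frac_epromoter_hubs: float = 0.5
    n_standalone_induced_eps: int = 60
    n_scattered_induced: int = 60
    n_repressed_genes: int = 150
    n_constitutive_eps: int = 150
    n_repressed_eps: int = 10
    activity_fc_active: float = 2.5
    activity_fc_background: float = 1.0
    induction_ratio_planted: float = 4.0
    nb_dispersion: float = 0.2
    n_replicates: int = 3
    mean_input_coverage: float = 300.0
    capture_eff_sd: float = 0.3
    off_target_frac: float = 0.5
    activity_lognorm_sd: float = 0.2
    frac_low_input: float = 0.01
    motif_density_hub: float = 2.5
    motif_density_background: float = 0.5
    tf_peak_at_hub_prob: float = 0.95
    n_background_peaks_per_tf: int = 200
    peak_width: int = 300
    site_width: int = 12
    de_lfc_mean: float = 2.5
    de_lfc_sd: float = 0.8
    tad_cover_frac: float = 0.7
    tad_split_frac: float = 0.15
    n_background_tads: int = 100
    max_gap: int = 100_000
    design: PromoterDesign = field(default_factory=PromoterDesign)

    def __post_init__(self) -> None:
        for name in ("frac_alt_promoters", "frac_epromoter_hubs", "frac_low_input",
                     "tad_cover_frac", "tad_split_frac", "off_target_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.induction_ratio_planted <= 1.0:
            raise ValueError("induction_ratio_planted must be > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus planted ground truth."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame          # gene_id chrom tss strand de_class_truth planted_cluster
    promoters: pd.DataFrame      # promoter_id gene_id chrom tss strand + truth flags
    tads: list[GenomicInterval]
    truth_clusters: pd.DataFrame  # cluster_id members epromoter_like_truth tad_status_truth
    counts: pd.DataFrame | None = None
    de_table: pd.DataFrame | None = None
    tf_peaks: dict[str, list[GenomicInterval]] | None = None
    isre_sites: dict[str, list[ScoredSite]] | None = None

    @property
    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss", "strand"]].copy()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with var = mu + dispersion*mu^2; dispersion 0 is noise-free."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return np.rint(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Genome geometry and ground truth
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig | None = None) -> SimulatedDataset:
    """Place genes, promoters, clusters, and TADs; derive ground truth.

    Deterministic per seed. Raises when the requested genes do not fit the
    chromosome geometry.
    """
    config = config or SimConfig()
    rng = _substreams(config.seed, 8)[0]
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    genome_bp = config.n_chroms * config.chrom_length
    if config.n_genes * 10_000 > genome_bp:
        raise ValueError("infeasible geometry: genes do not fit chromosomes")

    # -- planted clusters ---------------------------------------------------
    per_chrom = int(np.ceil(config.n_clusters / config.n_chroms))
    anchors = []
    for ci, chrom in enumerate(chroms):
        for k in range(per_chrom):
            if len(anchors) >= config.n_clusters:
                break
            base = config.chrom_length * (k + 1) // (per_chrom + 1)
            anchors.append((chrom, base + int(rng.integers(-200_000, 200_000))))

    gene_rows = []
    gid = 0
    cluster_member_ids: list[list[str]] = []
    for cl, (chrom, anchor) in enumerate(anchors):
        m = int(rng.integers(config.cluster_members_min, config.cluster_members_max + 1))
        max_gap_bp = config.cluster_span // max(m - 1, 1)
        pos = anchor
        members = []
        for j in range(m):
            if j > 0:
                pos += int(rng.integers(8_000, max(8_001, max_gap_bp)))
            gene_id = f"G{gid:04d}"
            gene_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "tss": pos,
                 "strand": "+" if rng.random() < 0.5 else "-",
                 "de_class_truth": "induced", "planted_cluster": cl}
            )
            members.append(gene_id)
            gid += 1
        cluster_member_ids.append(members)

    # -- scattered genes ----------------------------------------------------
    n_scatter = config.n_genes - gid
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    for row in gene_rows:
        occupied[row["chrom"]].append(row["tss"])
    chrom_choice = rng.integers(0, config.n_chroms, size=n_scatter * 3)
    pos_choice = rng.integers(50_000, config.chrom_length - 50_000, size=n_scatter * 3)
    placed = 0
    for c_idx, pos in zip(chrom_choice, pos_choice):
        if placed >= n_scatter:
            break
        chrom = chroms[int(c_idx)]
        taken = occupied[chrom]
        if taken and min(abs(pos - t) for t in taken) < 5_000:
            continue
        gene_rows.append(
            {"gene_id": f"G{gid:04d}", "chrom": chrom, "tss": int(pos),
             "strand": "+" if rng.random() < 0.5 else "-",
             "de_class_truth": "unchanged", "planted_cluster": pd.NA}
        )
        occupied[chrom].append(int(pos))
        gid += 1
        placed += 1
    if placed < n_scatter:
        raise ValueError("infeasible geometry: could not place scattered genes")
    genes = pd.DataFrame(gene_rows)

    # scattered induced / repressed genes and standalone-Epromoter host genes
    scattered = genes.index[genes["planted_cluster"].isna()].to_numpy()
    picks = rng.choice(scattered, size=(config.n_scattered_induced
                                        + config.n_standalone_induced_eps
                                        + config.n_repressed_genes), replace=False)
    ind_idx = picks[: config.n_scattered_induced]
    standalone_idx = picks[config.n_scattered_induced:
                           config.n_scattered_induced + config.n_standalone_induced_eps]
    rep_idx = picks[config.n_scattered_induced + config.n_standalone_induced_eps:]
    genes.loc[ind_idx, "de_class_truth"] = "induced"
    genes.loc[rep_idx, "de_class_truth"] = "repressed"

    # -- promoters (primary + alternative) ----------------------------------
    prom_rows = []
    for gene_id, chrom, tss, strand in genes[
        ["gene_id", "chrom", "tss", "strand"]
    ].itertuples(index=False):
        prom_rows.append(
            {"promoter_id": f"P_{gene_id}_1", "gene_id": gene_id, "chrom": chrom,
             "tss": tss, "strand": strand, "is_primary": True}
        )
    n_alt = int(round(config.frac_alt_promoters * config.n_genes))
    alt_genes = rng.choice(len(genes), size=n_alt, replace=False)
    for i in alt_genes:
        g = genes.iloc[int(i)]
        offset = int(rng.integers(5_000, 30_000))
        prom_rows.append(
            {"promoter_id": f"P_{g.gene_id}_2", "gene_id": g.gene_id,
             "chrom": g.chrom, "tss": int(g.tss) + offset, "strand": g.strand,
             "is_primary": False}
        )
    promoters = pd.DataFrame(prom_rows)
    promoters["is_hub"] = False
    promoters["is_induced_epromoter"] = False
    promoters["is_repressed_epromoter"] = False
    promoters["is_constitutive_epromoter"] = False
    promoters["is_low_input"] = False

    prom_idx = promoters.set_index("promoter_id").index

    # hubs: the primary promoter of the first member gene of selected clusters
    n_hubs = int(round(config.frac_epromoter_hubs * config.n_clusters))
    hub_clusters = rng.choice(config.n_clusters, size=n_hubs, replace=False)
    hub_promoters = [f"P_{cluster_member_ids[c][0]}_1" for c in hub_clusters]
    hub_mask = promoters["promoter_id"].isin(hub_promoters)
    promoters.loc[hub_mask, ["is_hub", "is_induced_epromoter"]] = True

    # standalone induced Epromoters on non-induced scattered genes
    standalone_promoters = [
        f"P_{genes.loc[i, 'gene_id']}_1" for i in standalone_idx
    ]
    promoters.loc[
        promoters["promoter_id"].isin(standalone_promoters), "is_induced_epromoter"
    ] = True

    # constitutive and repressed Epromoters among the remaining promoters
    free = promoters.index[~promoters["is_induced_epromoter"]].to_numpy()
    extra = rng.choice(free, size=config.n_constitutive_eps + config.n_repressed_eps,
                       replace=False)
    promoters.loc[extra[: config.n_constitutive_eps], "is_constitutive_epromoter"] = True
    promoters.loc[extra[config.n_constitutive_eps:], "is_repressed_epromoter"] = True

    # shallow-input promoters exercising the FPKM floor
    n_low = int(round(config.frac_low_input * len(promoters)))
    eligible = promoters.index[
        ~(promoters["is_induced_epromoter"] | promoters["is_constitutive_epromoter"]
          | promoters["is_repressed_epromoter"])
    ].to_numpy()
    promoters.loc[rng.choice(eligible, size=n_low, replace=False), "is_low_input"] = True

    # -- TADs ----------------------------------------------------------------
    tads: list[GenomicInterval] = []
    tad_status_truth: dict[int, str] = {}
    for cl, members in enumerate(cluster_member_ids):
        sub = genes[genes["gene_id"].isin(members)]
        lo, hi = int(sub["tss"].min()), int(sub["tss"].max())
        chrom = sub["chrom"].iloc[0]
        u = rng.random()
        if u < config.tad_cover_frac:
            tads.append(GenomicInterval(
                chrom, max(0, lo - int(rng.integers(20_000, 100_000))),
                hi + int(rng.integers(20_000, 100_000))))
            tad_status_truth[cl] = "Y"
        elif u < config.tad_cover_frac + config.tad_split_frac and len(members) >= 2:
            split = (lo + hi) // 2
            tss_sorted = np.sort(sub["tss"].to_numpy())
            # boundary between two members
            gaps = np.diff(tss_sorted)
            k = int(np.argmax(gaps))
            split = int((tss_sorted[k] + tss_sorted[k + 1]) // 2)
            pad = int(rng.integers(20_000, 100_000))
            tads.append(GenomicInterval(chrom, max(0, lo - pad), split))
            tads.append(GenomicInterval(chrom, split + 1_000, hi + pad))
            tad_status_truth[cl] = "N"
        else:
            tad_status_truth[cl] = "O"
    # background TADs away from cluster spans
    spans = [(genes[genes["gene_id"].isin(m)]["chrom"].iloc[0],
              int(genes[genes["gene_id"].isin(m)]["tss"].min()) - 250_000,
              int(genes[genes["gene_id"].isin(m)]["tss"].max()) + 250_000)
             for m in cluster_member_ids]
    n_bg = 0
    while n_bg < config.n_background_tads:
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - 1_000_000))
        length = int(rng.integers(200_000, 1_000_000))
        if any(c == chrom and start < hi and start + length > lo
               for c, lo, hi in spans):
            continue
        tads.append(GenomicInterval(chrom, start, start + length))
        n_bg += 1

    ds = SimulatedDataset(
        config=config, chrom_sizes=sizes, genes=genes, promoters=promoters,
        tads=tads, truth_clusters=pd.DataFrame(),
    )
    ds.truth_clusters = _derive_truth_clusters(ds, tad_status_truth)
    return ds


def _derive_truth_clusters(ds: SimulatedDataset, planted_tad_status: dict[int, str]) -> pd.DataFrame:
    """Geometry-implied clusters of truly induced loci (independent linkage).

    Loci are every promoter TSS of truth-induced genes plus every planted
    induced-Epromoter promoter TSS; components with >=2 distinct genes are
    truth clusters. The Epromoter-like truth is 'exactly one hub promoter
    among the members'. TAD status truth is taken from the planted status
    when the component coincides with a single planted cluster, else
    recomputed from the drawn TADs.
    """
    cfg = ds.config
    induced_genes = set(ds.genes.loc[ds.genes["de_class_truth"] == "induced", "gene_id"])
    ep_prom = ds.promoters[ds.promoters["is_induced_epromoter"]]
    loci = ds.promoters[
        ds.promoters["gene_id"].isin(induced_genes)
        | ds.promoters["promoter_id"].isin(ep_prom["promoter_id"])
    ][["promoter_id", "gene_id", "chrom", "tss"]].copy()

    records = []
    planted = ds.genes.set_index("gene_id")["planted_cluster"]
    from .cluster_calling import tad_status as _tad_status  # rule application
    from .core_io import merge_intervals
    merged_tads = merge_intervals(ds.tads)
    for chrom, sub in loci.groupby("chrom"):
        sub = sub.sort_values("tss")
        pos = sub["tss"].to_numpy()
        breaks = np.r_[True, np.diff(pos) > cfg.max_gap]
        comp = np.cumsum(breaks)
        for c in np.unique(comp):
            block = sub.iloc[comp == c]
            member_genes = sorted(set(block["gene_id"]))
            if len(member_genes) < 2:
                continue
            hubs = ds.promoters[
                ds.promoters["promoter_id"].isin(block["promoter_id"]) &
                ds.promoters["is_hub"]
            ]
            planted_ids = {int(p) for p in planted.loc[member_genes].dropna().unique()}
            if len(planted_ids) == 1 and len(planted_ids) == 1:
                pc = next(iter(planted_ids))
                status = planted_tad_status.get(pc)
                if status is None:
                    status = _tad_status(list(zip(block["chrom"], block["tss"])),
                                         merged_tads, pre_merged=True)
            else:
                status = _tad_status(list(zip(block["chrom"], block["tss"])),
                                     merged_tads, pre_merged=True)
            records.append(
                {"chrom": chrom, "start_tss": int(block["tss"].min()),
                 "end_tss": int(block["tss"].max()),
                 "members": ",".join(member_genes),
                 "n_members": len(member_genes),
                 "epromoter_like_truth": len(hubs) == 1,
                 "tad_status_truth": status}
            )
    out = pd.DataFrame(records).sort_values(["chrom", "start_tss"]).reset_index(drop=True)
    out.insert(0, "cluster_id", [f"truth_{i + 1:03d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# STARR counts
# ---------------------------------------------------------------------------

def simulate_starr_counts(ds: SimulatedDataset, config: SimConfig | None = None) -> pd.DataFrame:
    """Long-format count table (input + starr, 2 conditions × replicates).

    Input counts are drawn once (single plasmid library) and repeated for
    both conditions; reporter counts are NB around capture-efficiency- and
    activity-scaled means. Library sizes include the off-target read mass.
    """
    config = config or ds.config
    rng = _substreams(config.seed, 8)[1]
    prom = ds.promoters
    n = len(prom)

    base = np.exp(rng.normal(0.0, config.activity_lognorm_sd, n))
    act_ns = base * np.where(
        prom["is_induced_epromoter"] | prom["is_constitutive_epromoter"]
        | prom["is_repressed_epromoter"],
        config.activity_fc_active, config.activity_fc_background,
    )
    act_stim = act_ns * np.where(
        prom["is_induced_epromoter"], config.induction_ratio_planted, 1.0
    )
    act_stim = act_stim / np.where(
        prom["is_repressed_epromoter"], config.induction_ratio_planted, 1.0
    )

    eff = np.exp(rng.normal(0.0, config.capture_eff_sd, n))
    eff = eff * np.where(prom["is_low_input"], 1e-3, 1.0)
    mu_in = config.mean_input_coverage * eff
    off_target = (
        config.off_target_frac / (1.0 - config.off_target_frac)
        * config.mean_input_coverage * n
        if config.off_target_frac < 1.0 else 0.0
    )

    input_counts = _nb_draw(rng, mu_in, config.nb_dispersion)
    input_total = float(input_counts.sum()) + off_target

    rows = []
    region_ids = prom["promoter_id"].to_numpy()
    for cond, act in (("ns", act_ns), ("stim", act_stim)):
        for rep in range(1, config.n_replicates + 1):
            starr = _nb_draw(rng, mu_in * act, config.nb_dispersion)
            starr_total = float(starr.sum()) + off_target
            rows.append(pd.DataFrame(
                {"region_id": region_ids, "condition": cond, "replicate": rep,
                 "library": "input", "count": input_counts,
                 "library_size": input_total}))
            rows.append(pd.DataFrame(
                {"region_id": region_ids, "condition": cond, "replicate": rep,
                 "library": "starr", "count": starr,
                 "library_size": starr_total}))
    counts = pd.concat(rows, ignore_index=True)
    ds.counts = counts
    return counts


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def simulate_de_table(ds: SimulatedDataset, config: SimConfig | None = None) -> pd.DataFrame:
    """Planted DESeq2-style output table (log2fc, padj) per gene.

    Induced genes receive log2FC > 1 and padj < 0.001 by construction;
    repressed genes mirror; unchanged genes cannot pass the thresholds.
    """
    config = config or ds.config
    rng = _substreams(config.seed, 8)[2]
    n = len(ds.genes)
    lfc = rng.normal(0.0, 0.3, n)
    padj = rng.uniform(0.05, 1.0, n)

    cls = ds.genes["de_class_truth"].to_numpy()
    for label, sign in (("induced", 1.0), ("repressed", -1.0)):
        mask = cls == label
        k = int(mask.sum())
        mag = rng.normal(config.de_lfc_mean, config.de_lfc_sd, k)
        mag = np.where(mag > 1.0, mag, 1.0 + rng.uniform(0.05, 0.5, k))
        lfc[mask] = sign * mag
        padj[mask] = 10.0 ** rng.uniform(-8.0, -3.1, k)

    de = pd.DataFrame(
        {"gene_id": ds.genes["gene_id"], "log2fc": lfc, "padj": padj}
    )
    ds.de_table = de
    return de


# ---------------------------------------------------------------------------
# TF peaks and ISRE site tracks
# ---------------------------------------------------------------------------

def simulate_tf_tracks(
    ds: SimulatedDataset, config: SimConfig | None = None
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[ScoredSite]]]:
    """ChIP peak BEDs for the key TFs and an ISRE site track with p-values.

    Hub promoters receive a peak for each key TF with probability
    ``tf_peak_at_hub_prob`` and at least two high-confidence ISRE sites
    (p < 1e-4); other promoters receive Poisson(``motif_density_background``)
    weak sites (p > 1e-4) and only random background peaks.
    """
    config = config or ds.config
    rng = _substreams(config.seed, 8)[3]
    prom = ds.promoters
    chroms = list(ds.chrom_sizes)

    peaks: dict[str, list[GenomicInterval]] = {tf: [] for tf in ISGF3_TFS}
    half_peak = config.peak_width // 2
    for _, p in prom[prom["is_hub"]].iterrows():
        center = int(p["tss"])
        for tf in ISGF3_TFS:
            if rng.random() < config.tf_peak_at_hub_prob:
                jitter = int(rng.integers(-50, 51))
                start = max(0, center - half_peak + jitter)
                peaks[tf].append(GenomicInterval(p["chrom"], start, start + config.peak_width))
    for tf in ISGF3_TFS:
        for _ in range(config.n_background_peaks_per_tf):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, ds.chrom_sizes[chrom] - config.peak_width))
            peaks[tf].append(GenomicInterval(chrom, start, start + config.peak_width))

    sites: dict[str, list[ScoredSite]] = {tf: [] for tf in DEFAULT_ISRE_TFS}
    design = config.design
    slot_step = config.site_width + 8
    for _, p in prom.iterrows():
        window = design.capture_window(p["chrom"], int(p["tss"]), p["strand"])
        n_slots = max(1, (len(window) - config.site_width) // slot_step)
        if p["is_hub"]:
            n_hc = 2 + int(rng.poisson(max(config.motif_density_hub - 2.0, 0.0)))
            n_hc = min(n_hc, n_slots)
            chosen = rng.choice(n_slots, size=n_hc, replace=False)
            for slot in chosen:
                start = window.start + int(slot) * slot_step
                tf = DEFAULT_ISRE_TFS[int(rng.integers(0, len(DEFAULT_ISRE_TFS)))]
                pval = 10.0 ** rng.uniform(-8.0, -4.05)
                sites[tf].append(ScoredSite(
                    GenomicInterval(p["chrom"], start, start + config.site_width),
                    tf, pval))
        else:
            n_weak = min(int(rng.poisson(config.motif_density_background)), n_slots)
            if n_weak:
                chosen = rng.choice(n_slots, size=n_weak, replace=False)
                for slot in chosen:
                    start = window.start + int(slot) * slot_step
                    tf = DEFAULT_ISRE_TFS[int(rng.integers(0, len(DEFAULT_ISRE_TFS)))]
                    pval = 10.0 ** rng.uniform(-3.95, -1.0)
                    sites[tf].append(ScoredSite(
                        GenomicInterval(p["chrom"], start, start + config.site_width),
                        tf, pval))
    ds.tf_peaks, ds.isre_sites = peaks, sites
    return peaks, sites


# ---------------------------------------------------------------------------
# One-call bundle and fixture writing
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig | None = None) -> SimulatedDataset:
    """Genome + counts + DE table + TF tracks, all from one seed."""
    config = config or SimConfig()
    ds = simulate_genome(config)
    simulate_starr_counts(ds, config)
    simulate_de_table(ds, config)
    simulate_tf_tracks(ds, config)
    return ds


def write_fixtures(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input format into ``outdir``; returns the paths.

    ISRE sites are written as 10-column narrowPeak so the match p-value
    round-trips through column 8 (−log10 p).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(ds.chrom_sizes, paths["chrom_sizes"])
    paths["tss"] = outdir / "tss.tsv"
    write_table(ds.tss_table, paths["tss"])
    paths["promoters"] = outdir / "promoters.tsv"
    write_table(ds.promoters[["promoter_id", "gene_id", "chrom", "tss", "strand"]],
                paths["promoters"])
    paths["tads"] = outdir / "tads.bed"
    write_bed(ds.tads, paths["tads"])
    if ds.counts is not None:
        paths["counts"] = outdir / "starr_counts.tsv"
        write_table(ds.counts, paths["counts"])
    if ds.de_table is not None:
        paths["de"] = outdir / "de_table.tsv"
        write_table(ds.de_table, paths["de"])
    if ds.tf_peaks is not None:
        for tf, ivs in ds.tf_peaks.items():
            p = outdir / f"peaks_{tf}.bed"
            write_bed(ivs, p)
            paths[f"peaks_{tf}"] = p
    if ds.isre_sites is not None:
        paths["isre_sites"] = outdir / "isre_sites.narrowPeak"
        with paths["isre_sites"].open("w") as fh:
            for tf, site_list in ds.isre_sites.items():
                for s in site_list:
                    iv = s.interval
                    neglog = -np.log10(s.p_value) if s.p_value else -1.0
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tf}\t0\t.\t0\t"
                        f"{neglog:.4f}\t-1\t-1\n"
                    )
    paths["truth_clusters"] = outdir / "truth_clusters.tsv"
    write_table(ds.truth_clusters, paths["truth_clusters"])
    truth_prom = ds.promoters[
        ["promoter_id", "gene_id", "is_hub", "is_induced_epromoter",
         "is_repressed_epromoter", "is_constitutive_epromoter", "is_low_input"]
    ]
    paths["truth_promoters"] = outdir / "truth_promoters.tsv"
    write_table(truth_prom, paths["truth_promoters"])
    return paths
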