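"""TSS-distance clusters of induced loci, typing, TAD status, and
Epromoter-like prediction.

Induced loci (TSSs of induced genes and of genes with induced Epromoters)
are clustered by single linkage within chromosomes: two loci link when their
TSS distance is at most 100 kb (inclusive by default; a strict-less-than
mode is available). Clusters are typed by member response-set labels,
assigned a TAD status (same merged TAD / different TADs / outside any TAD),
and predicted as Epromoter-like when exactly one member promoter binds at
least one key TF while all others bind none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, merge_intervals

logger = logging.getLogger("epromoter")


@dataclass(frozen=True)
class ClusterConfig:
    max_gap: int = 100_000
    min_members: int = 2
    strict_lt: bool = False  # if True, linkage requires distance < max_gap

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")


def cluster_tss(loci: pd.DataFrame, config: ClusterConfig | None = None) -> pd.DataFrame:
    """Single-linkage clustering of loci by TSS distance within chromosomes.

    ``loci`` columns: locus_id, gene_id, chrom, tss. Genes with several
    promoters contribute every TSS to linkage but count once as a gene
    member. Returns the input with a ``cluster_id`` column (pandas NA for
    unclustered loci); clusters need at least ``min_members`` distinct
    genes. Duplicate (locus_id, tss) rows are deduplicated with a warning.
    Deterministic and invariant to input order: clusters are numbered by
    (chrom, leftmost TSS).
    """
    config = config or ClusterConfig()
    for col in ("locus_id", "gene_id", "chrom", "tss"):
        if col not in loci.columns:
            raise ValueError(f"loci table missing column {col!r}")
    df = loci.copy()
    dup = df.duplicated(subset=["locus_id", "tss"])
    if dup.any():
        logger.warning("cluster_tss: dropped %d duplicate locus rows", int(dup.sum()))
        df = df.loc[~dup]
    df = df.sort_values(["chrom", "tss", "locus_id"], kind="mergesort").reset_index(drop=True)

    component = np.full(len(df), -1, dtype=int)
    comp = -1
    prev_chrom, prev_tss = None, None
    for i, (chrom, tss) in enumerate(zip(df["chrom"], df["tss"])):
        gap = None if chrom != prev_chrom else tss - prev_tss
        linked = gap is not None and (
            gap < config.max_gap if config.strict_lt else gap <= config.max_gap
        )
        if not linked:
            comp += 1
        component[i] = comp
        prev_chrom, prev_tss = chrom, tss
    df["_component"] = component

    # a component is a cluster only with >= min_members distinct genes
    sizes = df.groupby("_component")["gene_id"].nunique()
    valid = sizes[sizes >= config.min_members].index
    cluster_ids: dict[int, str] = {}
    for n, c in enumerate(sorted(valid), start=1):
        cluster_ids[c] = f"cluster_{n:03d}"
    df["cluster_id"] = df["_component"].map(cluster_ids)
    df["cluster_id"] = df["cluster_id"].astype("string")
    return df.drop(columns="_component")


def type_cluster(member_labels: Mapping[str, str],
                 constitutive: Mapping[str, bool] | None = None) -> dict:
    """Tally member genes per response-set label.

    ``member_labels`` maps gene_id -> set label (comma-joined multi-labels
    allowed; the gene counts once per carried label with precedence
    induced_gene_and_epromoter > induced_gene_only > induced_epromoter_only
    for the single-count tally). Raises on an unlabeled member.
    """
    counts = {"induced_gene_only": 0, "induced_gene_and_epromoter": 0,
              "induced_epromoter_only": 0}
    precedence = ("induced_gene_and_epromoter", "induced_gene_only",
                  "induced_epromoter_only")
    for gene, label in member_labels.items():
        if not label or pd.isna(label):
            raise ValueError(f"cluster member {gene!r} has no set label")
        labels = set(str(label).split(","))
        for cand in precedence:
            if cand in labels:
                counts[cand] += 1
                break
    has_const = bool(constitutive and any(constitutive.values()))
    counts["has_constitutive_ep"] = has_const
    counts["has_epromoter"] = has_const or counts["induced_gene_and_epromoter"] > 0 \
        or counts["induced_epromoter_only"] > 0
    return counts


def tad_status(
    member_positions: Sequence[tuple[str, int]],
    tad_intervals: Sequence[GenomicInterval],
    pre_merged: bool = False,
) -> str:
    """TAD status of a cluster: Y (same merged TAD), N (different TADs),
    O (>=1 member outside any TAD; takes precedence over N)."""
    tads = list(tad_intervals) if pre_merged else merge_intervals(tad_intervals)
    assigned = []
    for chrom, pos in member_positions:
        idx = None
        for k, tad in enumerate(tads):
            if tad.chrom == chrom and tad.start <= pos < tad.end:
                idx = k
                break
        if idx is None:
            return "O"
        assigned.append(idx)
    return "Y" if len(set(assigned)) == 1 else "N"


def predict_epromoter_like(
    member_promoters: Sequence[str], binding: pd.DataFrame
) -> bool:
    """True iff exactly one member promoter binds >=1 TF and all others none.

    ``binding`` is a boolean promoter×TF matrix; missing members raise.
    Invariant under member permutation.
    """
    missing = [p for p in member_promoters if p not in binding.index]
    if missing:
        raise ValueError(f"promoters missing from binding matrix: {missing}")
    n_bound = sum(
        1 for p in member_promoters if bool(binding.loc[p].any())
    )
    return n_bound == 1


def build_cluster_table(
    clustered: pd.DataFrame,
    gene_sets: pd.DataFrame,
    promoter_map: pd.DataFrame,
    binding: pd.DataFrame | None,
    tads: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """One row per cluster: member genes, category counts, TAD status, and
    the Epromoter-like prediction (None when no binding matrix is given)."""
    labels = gene_sets.set_index("gene_id")["set_labels"]
    const = gene_sets.set_index("gene_id")["constitutive_epromoter"]
    merged_tads = merge_intervals(tads)
    prom_by_gene = promoter_map.groupby("gene_id")["promoter_id"].apply(list)

    rows = []
    for cluster_id, sub in clustered.dropna(subset=["cluster_id"]).groupby("cluster_id"):
        genes = sorted(sub["gene_id"].unique())
        member_labels = {g: labels.get(g, "other") for g in genes}
        counts = type_cluster(member_labels, {g: bool(const.get(g, False)) for g in genes})
        positions = list(zip(sub["chrom"], sub["tss"]))
        status = tad_status(positions, merged_tads, pre_merged=True)
        ep_like = None
        if binding is not None:
            proms = [p for g in genes for p in prom_by_gene.get(g, [])
                     if p in binding.index]
            ep_like = predict_epromoter_like(proms, binding) if proms else False
        rows.append(
            {
                "cluster_id": cluster_id,
                "chrom": sub["chrom"].iloc[0],
                "start_tss": int(sub["tss"].min()),
                "end_tss": int(sub["tss"].max()),
                "n_members": len(genes),
                "members": ",".join(genes),
                "n_induced_only": counts["induced_gene_only"],
                "n_induced_and_ep": counts["induced_gene_and_epromoter"],
                "n_ep_only": counts["induced_epromoter_only"],
                "has_constitutive_ep": counts["has_constitutive_ep"],
                "has_epromoter": counts["has_epromoter"],
                "epromoter_like": ep_like,
                "tad_status": status,
            }
        )
    return pd.DataFrame(rows)
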