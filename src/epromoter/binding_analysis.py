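"""Composite TF peaks, nearest-peak annotation, and promoter binding matrices.

The ISGF3 complex (STAT1/STAT2/IRF9) is operationalised as composite peaks:
maximal intervals covered by at least one peak from every factor. For each
induced gene, the closest composite peak is categorised as lying in the same
promoter (within ±flank of the gene's own TSS), in another promoter (within
±flank of any other gene's TSS), or intergenic. A promoter×TF boolean
binding matrix (≥1 bp overlap with the ±flank window) supports the
Epromoter-like cluster prediction.
"""

from __future__ import annotations

from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, PromoterDesign, intersect_intervals, merge_intervals

CATEGORIES = ("same_promoter", "another_promoter", "intergenic", "unannotated")


def composite_peaks(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    required_tfs: Sequence[str] | None = None,
) -> list[GenomicInterval]:
    """Maximal intervals covered by >=1 peak from EVERY required TF set.

    Peaks are merged (>=1 bp) within each TF first, then intersected
    iteratively; associative in base content.
    """
    tfs = list(required_tfs) if required_tfs is not None else list(peak_sets)
    if len(tfs) < 1:
        raise ValueError("required TF list must not be empty")
    missing = [tf for tf in tfs if tf not in peak_sets]
    if missing:
        raise ValueError(f"peak sets missing for TFs: {missing}")
    merged = [merge_intervals(peak_sets[tf]) for tf in tfs]
    return reduce(intersect_intervals, merged)


def tss_peak_distance(tss: int, peak: GenomicInterval) -> int:
    """Distance from a TSS to the nearest peak edge; 0 when the TSS is inside."""
    return max(peak.start - tss, tss - (peak.end - 1), 0)


def nearest_peak_category(
    gene_id: str,
    chrom: str,
    tss: int,
    peaks: Sequence[GenomicInterval],
    all_tss: pd.DataFrame,
    flank: int = 1000,
) -> dict:
    """Annotate one gene with its nearest composite peak and category.

    Categories: ``same_promoter`` when the nearest peak is within ``flank``
    of the gene's own TSS (takes precedence); ``another_promoter`` when it
    is within ``flank`` of any other gene's TSS; else ``intergenic``.
    ``unannotated`` when no peak exists on the gene's chromosome. Distance
    ties break toward the leftmost peak.
    """
    if not peaks:
        raise ValueError("peak set must not be empty")
    candidates = sorted(
        (p for p in peaks if p.chrom == chrom), key=GenomicInterval.sort_key
    )
    if not candidates:
        return {
            "gene_id": gene_id,
            "nearest_peak": None,
            "distance": None,
            "category": "unannotated",
        }
    dists = [tss_peak_distance(tss, p) for p in candidates]
    best = int(np.argmin(dists))  # argmin takes the first (leftmost) tie
    peak, distance = candidates[best], dists[best]
    if distance <= flank:
        category = "same_promoter"
    else:
        others = all_tss.loc[
            (all_tss["chrom"] == chrom) & (all_tss["gene_id"] != gene_id), "tss"
        ].to_numpy()
        near_other = (
            np.minimum(
                np.abs(others - peak.start), np.abs(others - (peak.end - 1))
            )
            <= flank
        ) | ((others >= peak.start) & (others < peak.end))
        category = "another_promoter" if bool(near_other.any()) else "intergenic"
    return {
        "gene_id": gene_id,
        "nearest_peak": peak,
        "distance": distance,
        "category": category,
    }


def annotate_nearest_peaks(
    genes: pd.DataFrame,
    peaks: Sequence[GenomicInterval],
    all_tss: pd.DataFrame,
    flank: int = 1000,
) -> pd.DataFrame:
    """Vector version of :func:`nearest_peak_category` over a gene table."""
    rows = []
    for gene_id, chrom, tss in genes[["gene_id", "chrom", "tss"]].itertuples(index=False):
        ann = nearest_peak_category(gene_id, chrom, int(tss), peaks, all_tss, flank)
        peak = ann.pop("nearest_peak")
        ann["peak_chrom"] = peak.chrom if peak else None
        ann["peak_start"] = peak.start if peak else None
        ann["peak_end"] = peak.end if peak else None
        rows.append(ann)
    return pd.DataFrame(rows)


def binding_matrix(
    promoter_windows: Mapping[str, GenomicInterval],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Boolean promoter×TF matrix: >=1 bp overlap of any TF peak with the window."""
    prom_ids = list(promoter_windows)
    data = {}
    for tf, peaks in peak_sets.items():
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        for chrom in {p.chrom for p in peaks}:
            sub = [p for p in peaks if p.chrom == chrom]
            starts[chrom] = np.sort(np.array([p.start for p in sub]))
            ends[chrom] = np.sort(np.array([p.end for p in sub]))
        col = []
        for pid in prom_ids:
            w = promoter_windows[pid]
            if w.chrom not in starts:
                col.append(False)
                continue
            n_started = np.searchsorted(starts[w.chrom], w.end - 1, side="right")
            n_ended = np.searchsorted(ends[w.chrom], w.start, side="right")
            col.append(bool(n_started > n_ended))
        data[tf] = col
    return pd.DataFrame(data, index=pd.Index(prom_ids, name="promoter_id"))


def enhancer_tss_proximity(
    enhancers: Sequence[GenomicInterval],
    all_tss: pd.DataFrame,
    cut: int = 1000,
) -> pd.DataFrame:
    """Distance from each enhancer midpoint to the nearest TSS, with label.

    ``proximal`` when the distance is <= ``cut`` (inclusive), else
    ``distal``. Enhancers on chromosomes without any TSS get an infinite
    distance and the distal label.
    """
    if all_tss.empty:
        raise ValueError("TSS table must not be empty")
    tss_by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in all_tss.groupby("chrom")
    }
    rows = []
    for i, enh in enumerate(enhancers):
        mid = enh.midpoint
        positions = tss_by_chrom.get(enh.chrom)
        if positions is None or positions.size == 0:
            distance = float("inf")
        else:
            j = np.searchsorted(positions, mid)
            nearest = []
            if j > 0:
                nearest.append(abs(mid - positions[j - 1]))
            if j < positions.size:
                nearest.append(abs(mid - positions[j]))
            distance = float(min(nearest))
        rows.append(
            {
                "enhancer_id": enh.name if enh.name else f"enh{i}",
                "chrom": enh.chrom,
                "midpoint": mid,
                "distance": distance,
                "label": "proximal" if distance <= cut else "distal",
            }
        )
    return pd.DataFrame(rows)
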