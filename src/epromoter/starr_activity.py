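"""Enhancer-activity quantification of captured promoters from STARR-style counts.

The chain mirrors the capture STARR-seq quantification: fragment reads are
extended to the mean captured-fragment size (314 nt), coverage of each
captured promoter window is counted, normalised to FPKM, and enhancer
activity is the fold-change of the reporter (STARR) library over the input
library. Promoters whose input FPKM falls below a floor are removed. A
promoter is an Epromoter in a condition when its mean fold-change across
replicates reaches the inflection point (knee) of the ranked fold-change
curve; induced/repressed Epromoters are called from the between-condition
induction ratio together with per-replicate activity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, PromoterDesign

logger = logging.getLogger("epromoter")

RatioMode = Literal["ratio_of_means", "mean_of_ratios"]


@dataclass(frozen=True)
class StarrConfig:
    """Quantification thresholds.

    fragment_extension
        Reads are extended to this length (nt) from their 5' end, the mean
        size of the captured fragments.
    fpkm_min_input
        Promoters with input FPKM below this floor are removed before any
        activity call.
    induced_ratio
        Fold threshold on the stimulated/non-stimulated induction ratio;
        the comparison is strictly greater-than.
    pseudo_fc
        Floor applied to a zero denominator fold-change when forming ratios.
    ratio_mode
        How the induction ratio aggregates replicates: ratio of mean
        fold-changes (default) or mean of per-replicate ratios.
    """

    fragment_extension: int = 314
    fpkm_min_input: float = 1.0
    induced_ratio: float = 2.0
    pseudo_fc: float = 0.01
    ratio_mode: RatioMode = "ratio_of_means"
    design: PromoterDesign = field(default_factory=PromoterDesign)

    def __post_init__(self) -> None:
        if min(self.fragment_extension, self.fpkm_min_input, self.induced_ratio, self.pseudo_fc) <= 0:
            raise ValueError("all thresholds must be > 0")


# ---------------------------------------------------------------------------
# Fragment-level operations
# ---------------------------------------------------------------------------

def extend_fragments(
    read_intervals: Sequence[GenomicInterval], extension_nt: int
) -> list[GenomicInterval]:
    """Extend each read to ``extension_nt`` from its 5' end, clipped at 0.

    Plus-strand reads are anchored at ``start``, minus-strand reads at
    ``end``; reads must carry a strand.
    """
    out = []
    for read in read_intervals:
        if read.strand == "+":
            start, end = read.start, read.start + extension_nt
        elif read.strand == "-":
            start, end = max(0, read.end - extension_nt), read.end
        else:
            raise ValueError(
                f"read {read.chrom}:{read.start}-{read.end} has no strand"
            )
        out.append(GenomicInterval(read.chrom, start, end, read.strand))
    return out


def region_coverage(
    fragments: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> list[int]:
    """Per-region count of fragments overlapping by >=1 bp.

    Sort-based: counts fragments with start < region.end minus those with
    end <= region.start, per chromosome.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {f.chrom for f in fragments}:
        sub = [f for f in fragments if f.chrom == chrom]
        starts[chrom] = np.sort(np.array([f.start for f in sub]))
        ends[chrom] = np.sort(np.array([f.end for f in sub]))
    counts = []
    for region in regions:
        if region.chrom not in starts:
            counts.append(0)
            continue
        n_started = np.searchsorted(starts[region.chrom], region.end - 1, side="right")
        n_ended = np.searchsorted(ends[region.chrom], region.start, side="right")
        counts.append(int(n_started - n_ended))
    return counts


def fpkm(count: float, region_length_bp: int, total_fragments: float) -> float:
    """Fragments per kilobase of region per million mapped fragments."""
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be > 0")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0")
    return count / (region_length_bp / 1e3) / (total_fragments / 1e6)


def activity_fold_change(
    starr_fpkm: float, input_fpkm: float, fpkm_min_input: float = 1.0
) -> tuple[float | None, bool]:
    """Reporter-over-input fold-change, or removal when input is too shallow.

    Returns ``(fold_change, removed)``; ``fold_change`` is None when the
    promoter is removed by the input-FPKM floor.
    """
    if starr_fpkm < 0 or input_fpkm < 0:
        raise ValueError("FPKM values must be >= 0")
    if input_fpkm < fpkm_min_input:
        return None, True
    return starr_fpkm / input_fpkm, False


# ---------------------------------------------------------------------------
# Inflection-point threshold
# ---------------------------------------------------------------------------

def inflection_threshold(fold_changes: Sequence[float], tol: float = 1e-9) -> float:
    """Knee of the ranked fold-change curve.

    Fold-changes are ranked in decreasing order; on the (rank, log2 FC)
    curve the threshold is the FC at the point of maximum perpendicular
    distance to the chord joining the first and last points. Ties break
    toward the higher rank. Scale-equivariant: multiplying all FC by c
    multiplies the threshold by c.

    Raises ``ValueError`` ("degenerate ranked curve") for fewer than three
    values, all-equal values, or an exactly linear log2 curve.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size < 3:
        raise ValueError("degenerate ranked curve: need >= 3 fold-changes")
    if not np.all(np.isfinite(fc)) or np.any(fc <= 0):
        raise ValueError("fold-changes must be finite and positive")
    fc = np.sort(fc)[::-1]
    y = np.log2(fc)
    if y[0] - y[-1] <= tol:
        raise ValueError("degenerate ranked curve: all fold-changes equal")
    x = np.arange(fc.size, dtype=float)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist /= float(np.hypot(y1 - y0, x1 - x0))
    if dist.max() <= tol:
        raise ValueError("degenerate ranked curve: collinear log2 curve")
    # ties toward the higher rank
    knee = fc.size - 1 - int(np.argmax(dist[::-1]))
    return float(fc[knee])


# ---------------------------------------------------------------------------
# Epromoter calls
# ---------------------------------------------------------------------------

def call_epromoters(
    replicate_fc: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate active flags and the per-condition Epromoter flag.

    ``replicate_fc`` has shape (n_replicates, n_promoters); a replicate is
    active when its FC >= tau (inclusive), and a promoter is an Epromoter
    when its mean FC across replicates >= tau.
    """
    replicate_fc = np.asarray(replicate_fc, dtype=float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        active = replicate_fc >= tau
        epromoter = np.nanmean(replicate_fc, axis=0) >= tau
    return active, epromoter


def induction_ratio(
    fc_stim: np.ndarray,
    fc_ns: np.ndarray,
    mode: RatioMode = "ratio_of_means",
    pseudo_fc: float = 0.01,
) -> np.ndarray:
    """Stimulated/non-stimulated induction ratio per promoter.

    ``fc_*`` have shape (n_replicates, n_promoters). Zero denominators are
    floored at ``pseudo_fc`` (logged).
    """
    fc_stim = np.asarray(fc_stim, dtype=float)
    fc_ns = np.asarray(fc_ns, dtype=float)
    n_floored = int(np.sum(fc_ns < pseudo_fc))
    if n_floored:
        logger.info("induction_ratio: floored %d zero/low denominators", n_floored)
    if mode == "ratio_of_means":
        return fc_stim.mean(axis=0) / np.maximum(fc_ns.mean(axis=0), pseudo_fc)
    if mode == "mean_of_ratios":
        return (fc_stim / np.maximum(fc_ns, pseudo_fc)).mean(axis=0)
    raise ValueError(f"unknown ratio mode {mode!r}")


def call_induced_repressed(
    ratio: float,
    any_stim_active: bool,
    any_ns_active: bool,
    epromoter_stim: bool,
    epromoter_ns: bool,
    induced_ratio_threshold: float = 2.0,
) -> str:
    """Classify one promoter as induced / repressed / neither.

    Induced: an Epromoter in the stimulated condition whose induction ratio
    is strictly greater than the threshold, with at least one stimulated
    replicate active. Repressed mirrors the rule in the non-stimulated
    condition (ratio strictly below 1/threshold).
    """
    if epromoter_stim and ratio > induced_ratio_threshold and any_stim_active:
        return "induced"
    if epromoter_ns and ratio < 1.0 / induced_ratio_threshold and any_ns_active:
        return "repressed"
    return "neither"


# ---------------------------------------------------------------------------
# End-to-end quantification from a count table
# ---------------------------------------------------------------------------

def quantify_activity(
    counts: pd.DataFrame,
    region_lengths: Mapping[str, int] | int,
    config: StarrConfig | None = None,
    condition_ns: str = "ns",
    condition_stim: str = "stim",
) -> pd.DataFrame:
    """Run the full activity chain on a long-format count table.

    ``counts`` columns: region_id, condition, replicate, library
    ('input'|'starr'), count, and optionally library_size (total mapped
    fragments per library; defaults to the column sum of counts).

    Returns one row per promoter with per-condition mean fold-changes,
    removal flag, Epromoter flags, induction ratio, and the
    induced/repressed call. The knee threshold is computed per condition on
    the mean FC of retained promoters.
    """
    config = config or StarrConfig()
    required = {"region_id", "condition", "replicate", "library", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")

    conditions = (condition_ns, condition_stim)
    regions = counts["region_id"].drop_duplicates().tolist()
    region_index = pd.Index(regions, name="region_id")
    if isinstance(region_lengths, int):
        lengths = pd.Series(region_lengths, index=region_index, dtype=float)
    else:
        lengths = pd.Series(
            [region_lengths[r] for r in regions], index=region_index, dtype=float
        )

    # FPKM per (condition, replicate, library)
    fpkm_mats: dict[tuple[str, int, str], pd.Series] = {}
    for (cond, rep, lib), sub in counts.groupby(
        ["condition", "replicate", "library"], sort=True
    ):
        vec = sub.set_index("region_id")["count"].reindex(region_index).fillna(0.0)
        if "library_size" in sub.columns and sub["library_size"].notna().any():
            total = float(sub["library_size"].iloc[0])
        else:
            total = float(vec.sum())
        if total <= 0:
            raise ValueError(f"library ({cond}, {rep}, {lib}) has no fragments")
        fpkm_mats[(cond, rep, lib)] = vec / (lengths / 1e3) / (total / 1e6)

    replicates = sorted({rep for (_, rep, _) in fpkm_mats})
    n_rep, n_reg = len(replicates), len(region_index)

    fc = {c: np.full((n_rep, n_reg), np.nan) for c in conditions}
    input_fpkm_min = np.full(n_reg, np.inf)
    for cond in conditions:
        for i, rep in enumerate(replicates):
            try:
                inp = fpkm_mats[(cond, rep, "input")].to_numpy()
                starr = fpkm_mats[(cond, rep, "starr")].to_numpy()
            except KeyError as exc:
                raise ValueError(
                    f"missing library for condition={cond!r} replicate={rep}"
                ) from exc
            input_fpkm_min = np.minimum(input_fpkm_min, inp)
            with np.errstate(divide="ignore", invalid="ignore"):
                fc[cond][i] = np.where(inp > 0, starr / inp, np.nan)

    removed = input_fpkm_min < config.fpkm_min_input
    if removed.any():
        logger.info("quantify_activity: removed %d promoters (input FPKM < %g)",
                    int(removed.sum()), config.fpkm_min_input)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_fc = {c: np.nanmean(fc[c], axis=0) for c in conditions}
    # the knee is computed on retained promoters with quantifiable activity;
    # zero fold-changes (no reporter signal) are trivially inactive
    tau = {}
    for c in conditions:
        usable = mean_fc[c][~removed]
        usable = usable[np.isfinite(usable) & (usable > 0)]
        tau[c] = inflection_threshold(usable)

    active = {}
    epromoter = {}
    for c in conditions:
        act, epk = call_epromoters(fc[c], tau[c])
        act[:, removed] = False
        epk[removed] = False
        active[c], epromoter[c] = act, epk

    ratio = induction_ratio(
        fc[condition_stim], fc[condition_ns],
        mode=config.ratio_mode, pseudo_fc=config.pseudo_fc,
    )

    any_stim = active[condition_stim].any(axis=0)
    any_ns = active[condition_ns].any(axis=0)
    induced = (
        epromoter[condition_stim]
        & (ratio > config.induced_ratio)
        & any_stim
        & ~removed
    )
    repressed = (
        epromoter[condition_ns]
        & (ratio < 1.0 / config.induced_ratio)
        & any_ns
        & ~removed
        & ~induced
    )

    out = pd.DataFrame(
        {
            "promoter_id": region_index,
            "removed": removed,
            f"mean_fc_{condition_ns}": mean_fc[condition_ns],
            f"mean_fc_{condition_stim}": mean_fc[condition_stim],
            f"epromoter_{condition_ns}": epromoter[condition_ns],
            f"epromoter_{condition_stim}": epromoter[condition_stim],
            "induction_ratio": ratio,
            "induced_epromoter": induced,
            "repressed_epromoter": repressed,
        }
    ).reset_index(drop=True)
    out.attrs["tau"] = tau
    # constitutive: an Epromoter in both conditions but neither induced nor repressed
    out["constitutive_epromoter"] = (
        out[f"epromoter_{condition_ns}"]
        & out[f"epromoter_{condition_stim}"]
        & ~out["induced_epromoter"]
        & ~out["repressed_epromoter"]
    )
    return out
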