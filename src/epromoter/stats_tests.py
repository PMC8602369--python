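"""Statistical layer: nearest-neighbour distances, random gene controls,
KS and chi-square tests, and shuffle-based overlap enrichment with a
negative-binomial null.

The enrichment test repositions each query region uniformly within its own
chromosome (lengths and per-chromosome counts preserved), counts query
regions overlapping >=1 reference region across shuffles, fits a negative
binomial to the shuffle counts by the method of moments, and reports the
upper-tail probability of the observed overlap. When the shuffle counts are
underdispersed the null falls back to Poisson (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, merge_intervals

logger = logging.getLogger("epromoter")


# ---------------------------------------------------------------------------
# Gene-proximity statistics
# ---------------------------------------------------------------------------

def nn_distances(tss_table: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-locus distance to the nearest other locus on the same chromosome.

    Returns ``(distances indexed like the usable loci, n_excluded)``; loci
    alone on their chromosome are excluded, with the count reported.
    Raises when fewer than two loci share any chromosome.
    """
    for col in ("chrom", "tss"):
        if col not in tss_table.columns:
            raise ValueError(f"TSS table missing column {col!r}")
    pieces = []
    n_excluded = 0
    for _, sub in tss_table.groupby("chrom"):
        if len(sub) < 2:
            n_excluded += len(sub)
            continue
        order = sub["tss"].sort_values()
        pos = order.to_numpy(dtype=float)
        left = np.r_[np.inf, np.diff(pos)]
        right = np.r_[np.diff(pos), np.inf]
        pieces.append(pd.Series(np.minimum(left, right), index=order.index))
    if not pieces:
        raise ValueError("need >= 2 loci on some chromosome")
    return pd.concat(pieces).sort_index(), n_excluded


def random_gene_control(
    gene_universe: pd.DataFrame, k: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Uniform sample of ``k`` genes without replacement; reproducible."""
    if k > len(gene_universe):
        raise ValueError(f"k={k} exceeds universe size {len(gene_universe)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(gene_universe), size=k, replace=False)
    return gene_universe.iloc[np.sort(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Classical tests (scipy-backed)
# ---------------------------------------------------------------------------

def ks_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic with the asymptotic two-sided p-value."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table (df=1, upper-tail p).

    Continuity correction is off by default; zero marginals raise.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2×2 with non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be > 0")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Shuffle enrichment with a negative-binomial null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentConfig:
    n_shuffles: int = 100
    seed: int = 0
    chrom_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2")


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    shuffle_mean: float
    shuffle_sd: float
    nb_r: float | None
    nb_p: float | None
    p_value: float
    model: str  # "negative_binomial" or "poisson"


def count_overlapping(
    query: Sequence[GenomicInterval], reference: Sequence[GenomicInterval]
) -> int:
    """Number of query regions overlapping >=1 reference region by >=1 bp."""
    merged = merge_intervals(reference)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in merged}:
        sub = [r for r in merged if r.chrom == chrom]
        starts[chrom] = np.array([r.start for r in sub])
        ends[chrom] = np.array([r.end for r in sub])
    n = 0
    for q in query:
        if q.chrom not in starts:
            continue
        i = np.searchsorted(starts[q.chrom], q.end - 1, side="right")
        j = np.searchsorted(ends[q.chrom], q.start, side="right")
        if i > j:
            n += 1
    return n


def _shuffle_regions(
    query: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    out = []
    for q in query:
        size = chrom_sizes[q.chrom]
        length = len(q)
        if length > size:
            raise ValueError(
                f"region {q.chrom}:{q.start}-{q.end} longer than its chromosome"
            )
        start = int(rng.integers(0, size - length + 1))
        out.append(GenomicInterval(q.chrom, start, start + length))
    return out


def shuffle_enrichment(
    query_regions: Sequence[GenomicInterval],
    reference_regions: Sequence[GenomicInterval],
    config: EnrichmentConfig,
) -> EnrichmentResult:
    """Shuffle-based overlap enrichment against a negative-binomial null.

    Observed statistic: count of query regions overlapping >=1 reference
    region. Each shuffle repositions every query region uniformly within
    its own chromosome (length preserved). The NB null is fitted to the
    shuffle counts by moments (r = m²/(s²−m)); if s² <= m the null falls
    back to Poisson with mean m. p = P(X >= observed).
    """
    if config.chrom_sizes is None:
        raise ValueError("chrom_sizes required")
    for r in list(query_regions) + list(reference_regions):
        if r.chrom not in config.chrom_sizes:
            raise ValueError(f"chromosome {r.chrom!r} missing from chrom_sizes")
    rng = np.random.default_rng(config.seed)
    observed = count_overlapping(query_regions, reference_regions)
    counts = np.array(
        [
            count_overlapping(
                _shuffle_regions(query_regions, config.chrom_sizes, rng),
                reference_regions,
            )
            for _ in range(config.n_shuffles)
        ],
        dtype=float,
    )
    m = float(counts.mean())
    sd = float(counts.std(ddof=1))
    s2 = sd * sd
    if s2 > m and m > 0:
        r = m * m / (s2 - m)
        p_nb = r / (r + m)
        p_value = float(stats.nbinom.sf(observed - 1, r, p_nb))
        model, nb_r, nb_p = "negative_binomial", float(r), float(p_nb)
    else:
        logger.info(
            "shuffle_enrichment: shuffle counts underdispersed (s²=%.3g <= m=%.3g), "
            "Poisson fallback", s2, m,
        )
        p_value = float(stats.poisson.sf(observed - 1, m)) if m > 0 else (
            1.0 if observed == 0 else 0.0
        )
        model, nb_r, nb_p = "poisson", None, None
    p_value = min(1.0, max(p_value, 1e-300))
    return EnrichmentResult(
        observed=observed,
        shuffle_mean=m,
        shuffle_sd=sd,
        nb_r=nb_r,
        nb_p=nb_p,
        p_value=p_value,
        model=model,
    )
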