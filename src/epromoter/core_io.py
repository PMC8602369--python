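"""Domain types, interval algebra, and table I/O.

All coordinates are 0-based half-open ``[start, end)`` (BED convention); a TSS
is a single 0-based position. One-based or inverted coordinates are rejected
loudly rather than silently shifted. Strand matters only for capture-window
construction; distances are strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("epromoter")

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end for {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap with ``other`` in base pairs (0 when disjoint or trans)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class PromoterDesign:
    """Window geometry around a TSS.

    ``upstream``/``downstream`` define the capture window (−200/+50 by
    default, the CapSTARR-seq promoter library design); ``flank`` is the
    half-width of the ±1 kb window used for TF binding and proximity calls.
    """

    upstream: int = 200
    downstream: int = 50
    flank: int = 1000

    def __post_init__(self) -> None:
        if min(self.upstream, self.downstream, self.flank) <= 0:
            raise ValueError("all window sizes must be strictly positive")

    def capture_window(self, chrom: str, tss: int, strand: str) -> GenomicInterval:
        """Strand-aware capture window around a TSS, clipped at position 0."""
        if strand == "-":
            start, end = tss - self.downstream, tss + self.upstream
        else:
            start, end = tss - self.upstream, tss + self.downstream
        return GenomicInterval(chrom, max(0, start), end)

    def flank_window(self, chrom: str, tss: int) -> GenomicInterval:
        """Strand-agnostic ±flank window around a TSS, clipped at 0."""
        return GenomicInterval(chrom, max(0, tss - self.flank), tss + self.flank)


@dataclass(frozen=True)
class ScoredSite:
    """A motif/binding site with a TF label and optional match p-value."""

    interval: GenomicInterval
    tf_name: str
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


# ---------------------------------------------------------------------------
# BED / narrowPeak reading
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 or 10-column narrowPeak into intervals, in file order.

    For the narrowPeak dialect, column 8 (−log10 p) is mapped to
    ``p_value = 10**(-col8)``; a value of −1 (p unavailable) maps to ``None``.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            p_value = None
            if len(fields) == 10:  # narrowPeak: col 8 is -log10(p)
                neglog_p = float(fields[7])
                if neglog_p >= 0:
                    p_value = min(1.0, 10.0 ** (-neglog_p))
            try:
                out.append(
                    GenomicInterval(
                        fields[0], start, end, strand, name, score, p_value
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name/score default to '.'/0)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = iv.score if iv.score is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], min_overlap_bp: int = 1
) -> list[GenomicInterval]:
    """Merge intervals overlapping by at least ``min_overlap_bp`` bases.

    Output is pairwise disjoint and sorted by (chrom, start). Touching but
    non-overlapping intervals ([0,10), [10,20)) are NOT merged under the
    default ≥1 bp overlap rule. Idempotent; empty input gives empty output.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if (
            out
            and out[-1].chrom == iv.chrom
            and min(out[-1].end, iv.end) - iv.start >= min_overlap_bp
        ):
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_intervals(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise overlap segments between two interval sets (each ≥1 bp).

    Every returned interval is contained in one member of each input set.
    Output is sorted by (chrom, start, end).
    """
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in set_b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom_b.values():
        ivs.sort(key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for a in sorted(set_a, key=GenomicInterval.sort_key):
        for b in by_chrom_b.get(a.chrom, ()):
            if b.start >= a.end:
                break
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if hi > lo:
                out.append(GenomicInterval(a.chrom, lo, hi))
    out.sort(key=GenomicInterval.sort_key)
    return out


def interval_bases(intervals: Iterable[GenomicInterval]) -> set[tuple[str, int]]:
    """Explicit per-base membership set; brute-force oracle helper."""
    bases: set[tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

TSS_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
PROMOTER_COLUMNS = ["promoter_id", "gene_id", "chrom", "tss", "strand"]
DE_COLUMNS = ["gene_id", "log2fc", "padj"]
COUNT_COLUMNS = ["region_id", "condition", "replicate", "library", "count"]


def write_table(records: pd.DataFrame, path: str | Path, schema: Sequence[str] | None = None) -> None:
    """Write a DataFrame as a TSV with header; round-trips via read_table."""
    df = records if schema is None else records.loc[:, list(schema)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table (gene_id, chrom, tss, strand); validates coordinates."""
    df = read_table(path, TSS_COLUMNS)
    if (df["tss"] < 0).any():
        raise ValueError(f"{path}: negative TSS coordinate (1-based input?)")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValueError(f"{path}: duplicate gene_id values, e.g. {list(dups)}")
    return df


def read_promoter_table(path: str | Path) -> pd.DataFrame:
    """Read a promoter table (promoter_id, gene_id, chrom, tss, strand)."""
    df = read_table(path, PROMOTER_COLUMNS)
    if (df["tss"] < 0).any():
        raise ValueError(f"{path}: negative TSS coordinate (1-based input?)")
    if df["promoter_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate promoter_id values")
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chrom.sizes file -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
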