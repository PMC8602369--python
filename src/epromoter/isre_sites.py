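"""Non-redundant ISRE motif-site counting per promoter.

Individual IRF-family (IRF1..IRF9) and STAT1/STAT2 site tracks are merged
into a single pan-ISRE track (union, >=1 bp overlap merge); per promoter the
number of merged sites overlapping the counting window is tallied and binned
into the 0 / 1 / >=2 classes. The high-confidence tier keeps only sites with
a motif-match p-value strictly below 1e-4 and is merged AFTER filtering, so
weak sites cannot bridge two confident sites into one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GenomicInterval, PromoterDesign, ScoredSite, merge_intervals

logger = logging.getLogger("epromoter")

DEFAULT_ISRE_TFS = tuple(f"IRF{i}" for i in range(1, 10)) + ("STAT1", "STAT2")


@dataclass(frozen=True)
class MotifConfig:
    isre_tfs: tuple[str, ...] = DEFAULT_ISRE_TFS
    high_conf_p: float = 1e-4
    window: PromoterDesign = field(default_factory=PromoterDesign)

    def __post_init__(self) -> None:
        if not (0.0 < self.high_conf_p < 1.0):
            raise ValueError("high_conf_p must be in (0, 1)")


def highconf_filter(
    site_sets: Mapping[str, Sequence[ScoredSite]], p_max: float
) -> dict[str, list[ScoredSite]]:
    """Keep sites with p_value strictly below ``p_max``.

    Sites lacking a p-value are excluded from the high-confidence tier
    (logged).
    """
    out: dict[str, list[ScoredSite]] = {}
    n_missing = 0
    for tf, sites in site_sets.items():
        kept = []
        for s in sites:
            if s.p_value is None:
                n_missing += 1
            elif s.p_value < p_max:
                kept.append(s)
        out[tf] = kept
    if n_missing:
        logger.info("highconf_filter: excluded %d sites without p-values", n_missing)
    return out


def pan_isre_track(
    site_sets: Mapping[str, Sequence[ScoredSite]],
    config: MotifConfig | None = None,
) -> list[GenomicInterval]:
    """Merged non-redundant ISRE track across all configured TFs.

    Unknown TF labels are skipped with a warning.
    """
    config = config or MotifConfig()
    known = set(config.isre_tfs)
    pooled: list[GenomicInterval] = []
    for tf, sites in site_sets.items():
        if tf not in known:
            logger.warning("pan_isre_track: unknown TF label %r skipped", tf)
            continue
        pooled.extend(s.interval for s in sites)
    return merge_intervals(pooled)


def count_isre(
    promoter_window: GenomicInterval, pan_track: Sequence[GenomicInterval]
) -> int:
    """Number of merged sites overlapping the window by >=1 bp."""
    return sum(1 for site in pan_track if promoter_window.overlap_bp(site) >= 1)


def site_class(count: int) -> str:
    return "0" if count == 0 else ("1" if count == 1 else "2+")


def isre_count_table(
    promoter_windows: Mapping[str, GenomicInterval],
    site_sets: Mapping[str, Sequence[ScoredSite]],
    config: MotifConfig | None = None,
) -> pd.DataFrame:
    """Per-promoter ISRE counts and classes for both confidence tiers.

    The all-sites tier merges before any filtering; the high-confidence tier
    filters (p < high_conf_p, strict) and merges afterwards.
    """
    config = config or MotifConfig()
    track_all = pan_isre_track(site_sets, config)
    track_hc = pan_isre_track(
        highconf_filter(site_sets, config.high_conf_p), config
    )
    rows = []
    for pid, window in promoter_windows.items():
        n_all = count_isre(window, track_all)
        n_hc = count_isre(window, track_hc)
        rows.append(
            {
                "promoter_id": pid,
                "n_sites_all": n_all,
                "n_sites_highconf": n_hc,
                "class_all": site_class(n_all),
                "class_highconf": site_class(n_hc),
            }
        )
    return pd.DataFrame(rows)
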