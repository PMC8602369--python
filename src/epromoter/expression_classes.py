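"""Differential-expression classes and the three promoter response sets.

Genes are classified from a DESeq2-style table (log2 fold-change, adjusted
p-value) with strict thresholds, then combined with Epromoter activity calls
into the response sets: induced gene only, induced gene & Epromoter, and
induced Epromoter only. Genes may carry several labels through alternative
promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("epromoter")

SET_LABELS = (
    "induced_gene_only",
    "induced_gene_and_epromoter",
    "induced_epromoter_only",
    "other",
)


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for calling differential expression.

    Both comparisons are strict: induced means log2FC > ``lfc_min`` AND
    p < ``padj_max``. The default thresholds are the interferon-response
    preset (adjusted p < 0.001); the LPS preset uses raw p < 0.01
    (``p_is_adjusted=False``).
    """

    lfc_min: float = 1.0
    padj_max: float = 0.001
    p_is_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be > 0")
        if not (0.0 < self.padj_max < 1.0):
            raise ValueError("padj_max must be in (0, 1)")


def classify_de(de_table: pd.DataFrame, config: DEConfig | None = None) -> pd.DataFrame:
    """Add a ``de_class`` column (induced/repressed/unchanged) to a DE table.

    Genes with a missing p-value are dropped with a warning.
    """
    config = config or DEConfig()
    for col in ("gene_id", "log2fc", "padj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    df = de_table.copy()
    n_missing = int(df["padj"].isna().sum())
    if n_missing:
        logger.warning("classify_de: dropped %d genes with missing p-values", n_missing)
        df = df.loc[df["padj"].notna()]
    sig = df["padj"] < config.padj_max
    df["de_class"] = "unchanged"
    df.loc[sig & (df["log2fc"] > config.lfc_min), "de_class"] = "induced"
    df.loc[sig & (df["log2fc"] < -config.lfc_min), "de_class"] = "repressed"
    return df.reset_index(drop=True)


def assign_promoter_sets(
    gene_classes: pd.DataFrame,
    activity: pd.DataFrame,
    promoter_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each promoter (and each gene) to a response set.

    Parameters
    ----------
    gene_classes : output of :func:`classify_de` (gene_id, de_class).
    activity : output of ``quantify_activity`` (promoter_id,
        induced_epromoter, constitutive_epromoter, removed).
    promoter_map : promoter_id -> gene_id mapping (one row per promoter).

    Returns ``(promoter_sets, gene_sets)``. Promoter labels partition the
    promoters; gene labels are the union over the gene's promoters, so a
    gene may carry several labels. A gene is associated with a constitutive
    Epromoter when at least one of its promoters is an Epromoter in both
    conditions without being induced or repressed.
    """
    unknown = set(promoter_map["gene_id"]) - set(gene_classes["gene_id"])
    if unknown:
        raise ValueError(
            f"promoters map to unknown genes: {sorted(unknown)[:10]}"
        )
    de_class = gene_classes.set_index("gene_id")["de_class"]
    act = activity.set_index("promoter_id")

    rows = []
    for promoter_id, gene_id in promoter_map[["promoter_id", "gene_id"]].itertuples(index=False):
        if promoter_id in act.index:
            a = act.loc[promoter_id]
            removed = bool(a["removed"])
            induced_ep = bool(a["induced_epromoter"])
            constitutive_ep = bool(a.get("constitutive_epromoter", False))
        else:  # promoter not captured by the assay
            removed, induced_ep, constitutive_ep = True, False, False
        gene_induced = de_class.get(gene_id) == "induced"
        if gene_induced and induced_ep:
            label = "induced_gene_and_epromoter"
        elif gene_induced:
            label = "induced_gene_only"
        elif induced_ep:
            label = "induced_epromoter_only"
        else:
            label = "other"
        rows.append(
            {
                "promoter_id": promoter_id,
                "gene_id": gene_id,
                "set_label": label,
                "removed": removed,
                "induced_epromoter": induced_ep,
                "constitutive_epromoter": constitutive_ep,
            }
        )
    promoter_sets = pd.DataFrame(rows)

    gene_rows = []
    for gene_id, sub in promoter_sets.groupby("gene_id", sort=True):
        labels = sorted(set(sub["set_label"]) - {"other"}) or ["other"]
        gene_rows.append(
            {
                "gene_id": gene_id,
                "de_class": de_class.get(gene_id, "unchanged"),
                "set_labels": ",".join(labels),
                "constitutive_epromoter": bool(sub["constitutive_epromoter"].any()),
            }
        )
    gene_sets = pd.DataFrame(gene_rows)
    return promoter_sets, gene_sets


def count_labels(promoter_sets: pd.DataFrame, gene_sets: pd.DataFrame) -> pd.DataFrame:
    """Promoter- and gene-level counts per response set label."""
    rows = []
    for label in SET_LABELS:
        n_prom = int((promoter_sets["set_label"] == label).sum())
        n_gene = int(
            gene_sets["set_labels"].str.split(",").apply(lambda ls: label in ls).sum()
        )
        rows.append({"set_label": label, "n_promoters": n_prom, "n_genes": n_gene})
    return pd.DataFrame(rows)
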