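"""Composite peaks, nearest-peak categories, binding matrices, proximity."""

import numpy as np
import pandas as pd
import pytest

from epromoter import (
    GenomicInterval,
    binding_matrix,
    composite_peaks,
    enhancer_tss_proximity,
    nearest_peak_category,
)
from epromoter.binding_analysis import annotate_nearest_peaks, tss_peak_distance
from epromoter.core_io import interval_bases

from conftest import random_intervals


class TestCompositePeaks:
    def test_chain_intersection(self):
        sets = {
            "STAT1": [GenomicInterval("chr1", 0, 100)],
            "STAT2": [GenomicInterval("chr1", 50, 150)],
            "IRF9": [GenomicInterval("chr1", 90, 200)],
        }
        assert composite_peaks(sets) == [GenomicInterval("chr1", 90, 100)]

    def test_missing_factor_gives_no_composite(self):
        sets = {
            "STAT1": [GenomicInterval("chr1", 0, 100)],
            "STAT2": [GenomicInterval("chr1", 50, 150)],
            "IRF9": [GenomicInterval("chr2", 0, 100)],
        }
        assert composite_peaks(sets) == []

    def test_empty_required_list_errors(self):
        with pytest.raises(ValueError):
            composite_peaks({"A": []}, required_tfs=[])

    def test_matches_per_base_and_oracle_and_associates(self, rng):
        a = random_intervals(rng, 80)
        b = random_intervals(rng, 80)
        c = random_intervals(rng, 80)
        got = composite_peaks({"A": a, "B": b, "C": c})
        expected = interval_bases(a) & interval_bases(b) & interval_bases(c)
        assert interval_bases(got) == expected
        nested = composite_peaks(
            {"AB": composite_peaks({"A": a, "B": b}), "C": c}
        )
        assert interval_bases(nested) == expected


class TestNearestPeakCategory:
    TSS = pd.DataFrame(
        {
            "gene_id": ["own", "other", "far"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [10_000, 60_300, 5_000],
        }
    )

    def test_peak_overlapping_own_tss_is_same_promoter(self):
        ann = nearest_peak_category(
            "own", "chr1", 10_000, [GenomicInterval("chr1", 9_900, 10_100)],
            self.TSS,
        )
        assert ann["distance"] == 0
        assert ann["category"] == "same_promoter"

    def test_peak_near_another_tss_is_another_promoter(self):
        # 50 kb from own TSS but 300 bp from gene "other"
        ann = nearest_peak_category(
            "own", "chr1", 10_000, [GenomicInterval("chr1", 60_000, 60_200)],
            self.TSS,
        )
        assert ann["category"] == "another_promoter"

    def test_peak_far_from_every_tss_is_intergenic(self):
        ann = nearest_peak_category(
            "own", "chr1", 10_000, [GenomicInterval("chr1", 200_000, 200_300)],
            self.TSS,
        )
        assert ann["category"] == "intergenic"

    def test_no_peak_on_chromosome_is_unannotated(self):
        ann = nearest_peak_category(
            "far", "chr2", 5_000, [GenomicInterval("chr1", 0, 100)], self.TSS
        )
        assert ann["category"] == "unannotated"

    def test_agrees_with_all_pairs_oracle(self, rng):
        n_genes, n_peaks, flank = 500, 120, 1000
        tss = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.choice(["chr1", "chr2"], n_genes),
                "tss": rng.integers(0, 2_000_000, n_genes),
            }
        )
        peaks = random_intervals(rng, n_peaks, max_pos=2_000_000, max_len=500)
        ann = annotate_nearest_peaks(tss, peaks, tss, flank)
        for row, (_, g) in zip(ann.itertuples(index=False), tss.iterrows()):
            cands = [p for p in peaks if p.chrom == g["chrom"]]
            if not cands:
                assert row.category == "unannotated"
                continue
            dists = [tss_peak_distance(int(g["tss"]), p) for p in cands]
            assert row.distance == min(dists)
            if min(dists) <= flank:
                assert row.category == "same_promoter"

    def test_categories_partition_and_fractions_sum(self, default_run):
        ann = default_run.isgf3_annotation
        assert set(ann["category"]) <= {
            "same_promoter", "another_promoter", "intergenic", "unannotated"
        }
        cats = default_run.summary["isgf3_categories"]
        assert sum(v["pct"] for v in cats.values()) == pytest.approx(100.0, abs=0.1)


class TestBindingMatrix:
    def test_one_bp_overlap_counts_and_half_open_boundary(self):
        windows = {"p": GenomicInterval("chr1", 0, 2000)}
        inside = {"TF": [GenomicInterval("chr1", 999, 1100)]}
        outside = {"TF": [GenomicInterval("chr1", 2000, 2100)]}
        assert binding_matrix(windows, inside).loc["p", "TF"]
        assert not binding_matrix(windows, outside).loc["p", "TF"]

    def test_matches_quadratic_oracle(self, rng):
        windows = {
            f"p{i}": iv for i, iv in enumerate(random_intervals(rng, 60))
        }
        peak_sets = {
            tf: random_intervals(rng, 40) for tf in ("STAT1", "STAT2")
        }
        mat = binding_matrix(windows, peak_sets)
        for pid, w in windows.items():
            for tf, peaks in peak_sets.items():
                expected = any(w.overlap_bp(p) >= 1 for p in peaks)
                assert mat.loc[pid, tf] == expected


class TestEnhancerProximity:
    TSS = pd.DataFrame(
        {"gene_id": ["a", "b"], "chrom": ["chr1", "chr1"], "tss": [5_000, 50_000]}
    )

    def test_centered_on_tss_is_proximal_at_zero(self):
        out = enhancer_tss_proximity(
            [GenomicInterval("chr1", 4_900, 5_100)], self.TSS
        )
        assert out["distance"].iloc[0] == 0
        assert out["label"].iloc[0] == "proximal"

    def test_boundary_at_cut_is_inclusive_proximal(self):
        out = enhancer_tss_proximity(
            [GenomicInterval("chr1", 5_900, 6_100)], self.TSS, cut=1000
        )
        assert out["distance"].iloc[0] == 1000
        assert out["label"].iloc[0] == "proximal"

    def test_far_enhancer_is_distal(self):
        out = enhancer_tss_proximity(
            [GenomicInterval("chr1", 24_900, 25_100)], self.TSS
        )
        assert out["label"].iloc[0] == "distal"

    def test_empty_tss_table_errors(self):
        with pytest.raises(ValueError):
            enhancer_tss_proximity(
                [GenomicInterval("chr1", 0, 100)], self.TSS.iloc[:0]
            )
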