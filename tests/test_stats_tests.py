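"""Nearest-neighbour distances, controls, KS, chi-square, shuffle enrichment."""

import numpy as np
import pandas as pd
import pytest

from epromoter import (
    EnrichmentConfig,
    GenomicInterval,
    chi_square_2x2,
    ks_test,
    nn_distances,
    random_gene_control,
    shuffle_enrichment,
)
from epromoter.stats_tests import count_overlapping

from conftest import random_intervals


class TestNNDistances:
    def test_worked_example(self):
        tss = pd.DataFrame({"chrom": ["chr1"] * 3, "tss": [0, 100, 500]})
        d, n_excl = nn_distances(tss)
        assert list(d) == [100.0, 100.0, 400.0]
        assert n_excl == 0

    def test_singleton_chromosome_excluded(self):
        tss = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chrX"], "tss": [0, 100, 5]}
        )
        d, n_excl = nn_distances(tss)
        assert len(d) == 2 and n_excl == 1

    def test_too_few_loci_errors(self):
        with pytest.raises(ValueError):
            nn_distances(pd.DataFrame({"chrom": ["chr1"], "tss": [0]}))

    def test_matches_all_pairs_oracle(self, rng):
        tss = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 200),
                "tss": rng.integers(0, 10**6, 200),
            }
        )
        d, _ = nn_distances(tss)
        for idx, dist in d.items():
            row = tss.loc[idx]
            others = tss[(tss["chrom"] == row["chrom"]) & (tss.index != idx)]
            assert dist == abs(others["tss"] - row["tss"]).min()


class TestRandomControl:
    UNIVERSE = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(50)],
         "chrom": ["chr1"] * 50, "tss": range(0, 50_000, 1000)}
    )

    def test_full_sample_is_the_universe(self):
        out = random_gene_control(self.UNIVERSE, 50, seed=1)
        assert set(out["gene_id"]) == set(self.UNIVERSE["gene_id"])

    def test_fixed_seed_reproducible(self):
        a = random_gene_control(self.UNIVERSE, 10, seed=42)
        b = random_gene_control(self.UNIVERSE, 10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            random_gene_control(self.UNIVERSE, 51, seed=0)

    def test_clustered_loci_have_shorter_nn_distances(self, default_dataset):
        ds = default_dataset
        induced = ds.genes[ds.genes["de_class_truth"] == "induced"]
        obs, _ = nn_distances(induced)
        ctrl = random_gene_control(ds.genes, len(induced), seed=3)
        ctrl_d, _ = nn_distances(ctrl)
        D, p = ks_test(obs.to_numpy(), ctrl_d.to_numpy())
        assert D > 0 and p < 1e-6
        assert np.median(obs) < np.median(ctrl_d)


class TestKS:
    def test_identical_samples_give_zero(self):
        D, p = ks_test([1, 2, 3], [1, 2, 3])
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_hand_ecdf_example(self):
        # ECDF gap is maximal at x=3: 1 vs 3/4
        D, _ = ks_test([1, 2, 3], [1, 2, 3, 1000])
        assert D == pytest.approx(0.25)

    def test_statistic_matches_explicit_ecdf_enumeration(self, rng):
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(5, 40)))
            b = rng.normal(loc=rng.normal(), size=int(rng.integers(5, 40)))
            D, _ = ks_test(a, b)
            grid = np.concatenate([a, b])
            ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
            ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
            assert D == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-8)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_test([], [1.0])


class TestChiSquare:
    def test_independent_table(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, 4)
            stat, _ = chi_square_2x2([[a, b], [c, d]])
            n = a + b + c + d
            expected = (a * d - b * c) ** 2 * n / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert stat == pytest.approx(expected, abs=1e-8)

    def test_row_swap_symmetry(self):
        s1, _ = chi_square_2x2([[22, 16], [47, 347]])
        s2, _ = chi_square_2x2([[47, 347], [22, 16]])
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestShuffleEnrichment:
    SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}

    def _config(self, seed=0, n=100):
        return EnrichmentConfig(n_shuffles=n, seed=seed, chrom_sizes=self.SIZES)

    def test_observed_counting(self, rng):
        query = random_intervals(rng, 50, max_pos=900_000)
        ref = random_intervals(rng, 50, max_pos=900_000)
        expected = sum(
            1 for q in query if any(q.overlap_bp(r) >= 1 for r in ref)
        )
        assert count_overlapping(query, ref) == expected

    def test_observed_at_null_mean_gives_middling_p(self, rng):
        ref = [GenomicInterval("chr1", s, s + 20_000)
               for s in range(0, 1_000_000, 50_000)]
        query = random_intervals(rng, 40, max_pos=900_000, max_len=100)
        res = shuffle_enrichment(query, ref, self._config())
        # query placed uniformly: observed should sit inside the null bulk
        assert 0.05 < res.p_value <= 1.0

    def test_strong_enrichment_detected(self):
        ref = [GenomicInterval("chr1", i * 100_000, i * 100_000 + 1_000)
               for i in range(10)]
        query = [GenomicInterval("chr1", i * 100_000 + 200, i * 100_000 + 600)
                 for i in range(10)]
        res = shuffle_enrichment(query, ref, self._config(seed=5))
        assert res.observed == 10
        assert res.p_value < 0.01

    def test_poisson_fallback_on_degenerate_shuffles(self):
        # reference covers everything: every shuffle count equals len(query)
        ref = [GenomicInterval("chr1", 0, 1_000_000)]
        query = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 30, 40)]
        res = shuffle_enrichment(query, ref, self._config(n=2))
        assert res.model == "poisson"
        assert res.shuffle_sd == 0.0

    def test_fixed_seed_bit_identical(self, rng):
        query = random_intervals(rng, 30, max_pos=900_000)
        ref = random_intervals(rng, 30, max_pos=900_000)
        r1 = shuffle_enrichment(query, ref, self._config(seed=11))
        r2 = shuffle_enrichment(query, ref, self._config(seed=11))
        assert r1 == r2

    def test_region_longer_than_chromosome_errors(self):
        with pytest.raises(ValueError, match="longer than its chromosome"):
            shuffle_enrichment(
                [GenomicInterval("chr1", 0, 2_000_000)],
                [GenomicInterval("chr1", 0, 100)],
                self._config(),
            )
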