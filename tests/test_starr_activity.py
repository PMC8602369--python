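"""Activity quantification: extension, coverage, FPKM, knee, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epromoter import (
    GenomicInterval,
    StarrConfig,
    activity_fold_change,
    call_epromoters,
    call_induced_repressed,
    extend_fragments,
    fpkm,
    induction_ratio,
    inflection_threshold,
    quantify_activity,
    region_coverage,
)

from conftest import random_intervals


class TestExtendFragments:
    @pytest.mark.parametrize(
        "read,expected",
        [
            (GenomicInterval("chr1", 1000, 1050, "+"), (1000, 1314)),
            (GenomicInterval("chr1", 1000, 1050, "-"), (736, 1050)),
            (GenomicInterval("chr1", 100, 150, "-"), (0, 150)),  # boundary clip
        ],
    )
    def test_five_prime_anchor(self, read, expected):
        (frag,) = extend_fragments([read], 314)
        assert (frag.start, frag.end) == expected

    def test_missing_strand_errors(self):
        with pytest.raises(ValueError, match="no strand"):
            extend_fragments([GenomicInterval("chr1", 0, 50, ".")], 314)


class TestRegionCoverage:
    def test_overlap_counting_is_half_open(self):
        frag_in = GenomicInterval("chr1", 0, 314, "+")
        frag_out = GenomicInterval("chr1", 0, 100, "+")
        region_a = GenomicInterval("chr1", 250, 500)
        region_b = GenomicInterval("chr1", 100, 200)
        assert region_coverage([frag_in], [region_a]) == [1]
        assert region_coverage([frag_out], [region_b]) == [0]

    def test_matches_quadratic_oracle(self, rng):
        frags = random_intervals(rng, 500)
        regions = random_intervals(rng, 20)
        expected = [
            sum(1 for f in frags if f.overlap_bp(r) >= 1) for r in regions
        ]
        assert region_coverage(frags, regions) == expected


class TestFpkm:
    def test_worked_example(self):
        assert fpkm(10, 250, 1_000_000) == pytest.approx(40.0)
        assert fpkm(0, 250, 1_000_000) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            fpkm(10, 250, 0)

    @given(
        count=st.integers(1, 10_000),
        length=st.integers(1, 5_000),
        total=st.integers(1, 10**9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_under_joint_doubling(self, count, length, total):
        assert fpkm(2 * count, length, 2 * total) == pytest.approx(
            fpkm(count, length, total)
        )
        assert fpkm(2 * count, length, total) == pytest.approx(
            2 * fpkm(count, length, total)
        )


class TestActivityFoldChange:
    def test_fold_change_and_identity(self):
        assert activity_fold_change(8.0, 2.0, 1.0) == (4.0, False)
        assert activity_fold_change(3.0, 3.0, 1.0) == (1.0, False)

    def test_shallow_input_removed(self):
        fc, removed = activity_fold_change(8.0, 0.5, 1.0)
        assert removed and fc is None


class TestInflectionThreshold:
    def test_knee_found_at_piecewise_breakpoint(self):
        # 20 values at FC 8, then 180 decaying linearly in log2 from 1.5 to 0.5
        plateau = [8.0] * 20
        tail = list(2.0 ** np.linspace(np.log2(1.5), np.log2(0.5), 180))
        fc = np.array(plateau + tail)
        tau = inflection_threshold(fc)
        # brute-force maximum-distance search over all ranks
        srt = np.sort(fc)[::-1]
        y, x = np.log2(srt), np.arange(len(srt), dtype=float)
        x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
        d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
        d /= np.hypot(y1 - y0, x1 - x0)
        best = len(d) - 1 - int(np.argmax(d[::-1]))
        assert tau == pytest.approx(srt[best])
        assert tau == pytest.approx(1.5, rel=0.02)  # the breakpoint value

    def test_degenerate_curves_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            inflection_threshold([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            inflection_threshold([1.0, 2.0])
        # exactly linear in log2: all chord distances vanish
        with pytest.raises(ValueError, match="degenerate"):
            inflection_threshold(list(2.0 ** np.linspace(3, 0, 50)))

    @given(
        seed=st.integers(0, 1000),
        scale=st.floats(0.1, 100.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scales_multiplicatively_and_ignores_order(self, seed, scale):
        r = np.random.default_rng(seed)
        fc = np.concatenate([r.uniform(5, 9, 10), r.uniform(0.5, 1.5, 90)])
        tau = inflection_threshold(fc)
        assert inflection_threshold(fc * scale) == pytest.approx(tau * scale)
        assert inflection_threshold(r.permutation(fc)) == pytest.approx(tau)


class TestCalls:
    def test_epromoter_call_is_inclusive_at_tau(self):
        fc = np.array([[2.0, 1.0, 0.5], [2.0, 1.0, 0.5]])
        active, epk = call_epromoters(fc, tau=1.0)
        assert list(epk) == [True, True, False]
        assert active[:, 1].all()  # FC exactly tau is active

    def test_mean_of_ratios_worked_example(self):
        fc_stim = np.array([[2.5], [1.8]])
        fc_ns = np.array([[1.0], [1.0]])
        ratio = induction_ratio(fc_stim, fc_ns, mode="mean_of_ratios")
        assert ratio[0] == pytest.approx(2.15)
        label = call_induced_repressed(
            ratio=float(ratio[0]), any_stim_active=True, any_ns_active=False,
            epromoter_stim=True, epromoter_ns=False,
        )
        assert label == "induced"

    def test_ratio_exactly_two_is_not_induced(self):
        assert call_induced_repressed(
            ratio=2.0, any_stim_active=True, any_ns_active=False,
            epromoter_stim=True, epromoter_ns=False,
        ) == "neither"

    def test_repressed_mirror_rule(self):
        ratio = induction_ratio(
            np.array([[0.3], [0.4]]), np.array([[1.0], [1.0]]),
            mode="mean_of_ratios",
        )
        assert ratio[0] == pytest.approx(0.35)
        assert call_induced_repressed(
            ratio=float(ratio[0]), any_stim_active=False, any_ns_active=True,
            epromoter_stim=False, epromoter_ns=True,
        ) == "repressed"

    def test_zero_denominator_uses_pseudo_floor(self):
        ratio = induction_ratio(
            np.array([[4.0]]), np.array([[0.0]]), mode="mean_of_ratios",
            pseudo_fc=0.01,
        )
        assert ratio[0] == pytest.approx(400.0)


class TestQuantifyActivity:
    def _toy_counts(self):
        rows = []
        # 10 background promoters at FC~1, 2 strong responders, 1 shallow input
        specs = {f"p{i}": (100, 100, 100) for i in range(10)}
        specs["hot1"] = (100, 500, 2000)   # input, starr_ns, starr_stim
        specs["hot2"] = (100, 450, 1900)
        specs["shallow"] = (0, 50, 50)
        for rid, (inp, sns, sstim) in specs.items():
            for cond, starr in (("ns", sns), ("stim", sstim)):
                for rep in (1, 2):
                    rows.append((rid, cond, rep, "input", inp, 1e6))
                    rows.append((rid, cond, rep, "starr", starr + rep, 1e6))
        return pd.DataFrame(
            rows,
            columns=["region_id", "condition", "replicate", "library",
                     "count", "library_size"],
        )

    def test_end_to_end_calls(self):
        out = quantify_activity(self._toy_counts(), 250)
        out = out.set_index("promoter_id")
        assert bool(out.loc["shallow", "removed"])
        assert bool(out.loc["hot1", "induced_epromoter"])
        assert bool(out.loc["hot2", "induced_epromoter"])
        assert not out.loc[[f"p{i}" for i in range(10)], "induced_epromoter"].any()
        assert out.loc["hot1", "induction_ratio"] == pytest.approx(4.0, rel=0.1)

    def test_planted_actives_recovered_from_generator(self, default_run, default_dataset):
        act = default_run.activity.set_index("promoter_id")
        truth = default_dataset.promoters.set_index("promoter_id")
        hubs = truth.index[truth["is_hub"]]
        # hub promoters carry strong planted induction; all are called
        assert act.loc[hubs, "induced_epromoter"].mean() >= 0.9
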