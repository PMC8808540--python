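"""Counting, size factors, the NB Wald model and the all-peak comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chipscape.differential import (
    CountMatrix,
    NBDifferentialModel,
    allpeak_signal_comparison,
    count_reads,
    size_factors,
)
from chipscape.simulate import simulate_nb_counts
from chipscape.stats import bh_fdr
from chipscape.types import GenomicInterval, Peak, SampleMeta

from conftest import random_intervals


def mkregions(n, width=1000, gap=1000):
    return [
        Peak(GenomicInterval("chr1", i * (width + gap), i * (width + gap) + width), width // 2)
        for i in range(n)
    ]


def mksamples(design):
    return [
        SampleMeta(f"s{j}", "BC", d, "H3K27ac", j + 1, "chip")
        for j, d in enumerate(design)
    ]


class TestCountReads:
    def test_no_reads_zero_matrix(self):
        regions = mkregions(3)
        cm = count_reads(regions, {"s0": {}}, mksamples(["NC"])[:1])
        assert not cm.counts.any()

    def test_single_read_single_region(self):
        regions = mkregions(2)
        reads = {"s0": {"chr1": np.array([[100, 150]])}}
        cm = count_reads(regions, reads, mksamples(["NC"])[:1])
        assert cm.counts.tolist() == [[1], [0]]

    def test_matches_brute_force(self, rng):
        regions = [
            Peak(iv, iv.width // 2)
            for iv in random_intervals(rng, 30, chroms=("chr1",), max_pos=50_000)
        ]
        starts = rng.integers(0, 50_000, 2000)
        reads = {"s0": {"chr1": np.column_stack((starts, starts + 250))}}
        cm = count_reads(regions, reads, mksamples(["NC"])[:1])
        for i, r in enumerate(regions):
            want = int(((starts < r.end) & (starts + 250 > r.start)).sum())
            assert cm.counts[i, 0] == want


class TestSizeFactors:
    def test_doubled_sample_has_double_factor(self, rng):
        a = rng.integers(5, 100, size=(50, 1))
        counts = np.hstack([a, a * 2])
        f = size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self, rng):
        a = rng.integers(5, 100, size=(50, 1))
        f = size_factors(np.hstack([a, a, a]))
        assert np.allclose(f, f[0])

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(200, 4))
        f = size_factors(counts)
        pos = (counts > 0).all(axis=1)
        logs = np.log(counts[pos].astype(float))
        geo = logs.mean(axis=1)
        want = np.exp(np.median(logs - geo[:, None], axis=0))
        assert np.allclose(f, want)

    def test_fallback_warns_without_all_positive_region(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.warns(UserWarning):
            f = size_factors(counts)
        assert (f > 0).all()


class TestBH:
    def test_matches_brute_force_step_up(self, rng):
        for _ in range(30):
            p = rng.random(size=int(rng.integers(5, 80)))
            got = bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            want = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                want[i] = prev
            assert np.allclose(got, want)


class TestNBModel:
    def test_symmetric_data_gives_zero_log2fc(self, rng):
        base = rng.integers(10, 200, size=(100, 3))
        counts = np.hstack([base, base])  # MUT columns identical to NC
        cm = CountMatrix(mkregions(100), mksamples(["NC"] * 3 + ["MUT"] * 3), counts)
        res = NBDifferentialModel.from_samples(cm).fit()
        assert np.allclose(res.frame.log2FC, 0.0)

    def test_invariant_to_scaling_one_sample(self, rng):
        counts, design, _ = simulate_nb_counts(300, 3, rng)
        cm1 = CountMatrix(mkregions(300), mksamples(design), counts)
        r1 = NBDifferentialModel.from_samples(cm1).fit()
        scaled = counts.copy()
        scaled[:, 0] = scaled[:, 0] * 3
        cm2 = CountMatrix(mkregions(300), mksamples(design), scaled)
        r2 = NBDifferentialModel.from_samples(cm2).fit()
        # size-factor normalization absorbs the depth change
        assert np.corrcoef(r1.frame.log2FC, r2.frame.log2FC)[0, 1] > 0.99
        assert np.median(np.abs(r1.frame.log2FC - r2.frame.log2FC)) < 0.05

    def test_condition_absent_raises(self, rng):
        counts = rng.integers(1, 50, size=(10, 4))
        cm = CountMatrix(mkregions(10), mksamples(["NC"] * 4), counts)
        with pytest.raises(ValueError, match="MUT"):
            NBDifferentialModel.from_samples(cm)

    def test_planted_folds_recovered_with_sign(self, rng):
        n_null, n_eff = 500, 100
        fc = np.ones(n_null + n_eff)
        fc[n_null:] = np.where(rng.random(n_eff) < 0.5, 4.0, 0.25)
        counts, design, lfc = simulate_nb_counts(
            n_null + n_eff, 3, rng, fold_changes=fc, dispersion=0.05
        )
        cm = CountMatrix(mkregions(len(fc)), mksamples(design), counts)
        res = NBDifferentialModel.from_samples(cm).fit()
        up, down = res.select_significant()
        sel = res.significant_mask()
        sign_ok = np.sign(res.frame.log2FC.to_numpy()) == np.sign(lfc)
        recall = (sel[n_null:] & sign_ok[n_null:]).mean()
        assert recall >= 0.9

    def test_fdr_monotone_in_p_rank(self, rng):
        counts, design, _ = simulate_nb_counts(400, 3, rng)
        cm = CountMatrix(mkregions(400), mksamples(design), counts)
        res = NBDifferentialModel.from_samples(cm).fit()
        order = np.argsort(res.frame.pvalue.to_numpy())
        fdr_sorted = res.frame.fdr.to_numpy()[order]
        assert (np.diff(fdr_sorted) >= -1e-12).all()


class TestSelectSignificant:
    def _result(self, log2fc, fdr):
        n = len(log2fc)
        frame = pd.DataFrame(
            {
                "baseMean": np.ones(n),
                "log2FC": log2fc,
                "lfcSE": np.ones(n),
                "stat": np.zeros(n),
                "pvalue": fdr,
                "fdr": fdr,
                "direction": np.where(np.asarray(log2fc) > 0, "up_in_MUT", "down_in_MUT"),
            },
            index=[f"r{i}" for i in range(n)],
        )
        from chipscape.differential import DifferentialResult

        return DifferentialResult(frame=frame, regions=mkregions(n), design=["NC", "NC", "MUT", "MUT"])

    def test_trivial_thresholds_select_everything(self):
        res = self._result([0.1, -0.2, 0.0], [0.9, 0.5, 0.99])
        up, down = res.select_significant(fc=1, fdr=1)
        assert len(up) + len(down) == 3

    def test_fold_1p99_excluded_at_fc2(self):
        res = self._result([0.99], [0.049])  # fold 1.99, FDR 0.049
        up, down = res.select_significant(fc=2, fdr=0.05)
        assert up == [] and down == []

    def test_boundary_log2fc_exactly_one_included(self):
        res = self._result([1.0], [0.049])
        up, down = res.select_significant(fc=2, fdr=0.05)
        assert len(up) == 1


class TestAllPeakComparison:
    def test_identical_groups(self, rng):
        x = rng.normal(10, 2, size=200)
        m = pd.DataFrame({"a": x, "b": x, "c": x, "d": x})
        out = allpeak_signal_comparison(m, ["NC", "NC", "MUT", "MUT"])
        assert out["percent_change"] == pytest.approx(0.0)
        assert out["pvalue"] == 1.0

    def test_constructed_thirteen_and_a_half_percent_decrease(self, rng):
        nc = rng.normal(10, 2, size=500) + 20
        mut = nc * 0.865
        m = pd.DataFrame({"n1": nc, "n2": nc, "m1": mut, "m2": mut})
        out = allpeak_signal_comparison(m, ["NC", "NC", "MUT", "MUT"])
        assert out["percent_change"] == pytest.approx(-13.5)
        assert out["pvalue"] < 0.05

    def test_paired_shift_detected_with_direction(self, rng):
        nc = rng.normal(5, 1, size=1000)
        mut = nc + 0.5 + rng.normal(0, 0.2, size=1000)
        m = pd.DataFrame({"n": nc, "m": mut})
        out = allpeak_signal_comparison(m, ["NC", "MUT"])
        assert out["t_stat"] > 0 and out["pvalue"] < 0.05

    def test_too_few_regions_error(self):
        with pytest.raises(ValueError):
            allpeak_signal_comparison(pd.DataFrame({"a": [1.0], "b": [2.0]}), ["NC", "MUT"])
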