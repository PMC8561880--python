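import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import stdtr

from sdrscan import depth_scan
from sdrscan.depth_scan import (
    BinnedDepth,
    bin_depths,
    filter_depth_windows,
    welch_window_tests,
    zero_depth_tracts,
)
from sdrscan.io_formats import ContigTable, Sex

from conftest import make_cohort


def welch_oracle(x, y):
    """Independent closed-form Welch t-test (two-sided)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stdtr(df, -abs(t))
    return t, p


def binned_from_means(male_means, female_means, contig="c1", bin_width=1000):
    """One BinnedDepth per window row from explicit per-sex window means."""
    male_means = np.atleast_2d(np.asarray(male_means, float))
    female_means = np.atleast_2d(np.asarray(female_means, float))
    n_windows = male_means.shape[0]
    samples = [f"M{i + 1:02d}" for i in range(male_means.shape[1])] + [
        f"F{i + 1:02d}" for i in range(female_means.shape[1])
    ]
    starts = np.arange(n_windows) * bin_width
    return BinnedDepth(
        contig=contig,
        starts=starts,
        ends=starts + bin_width,
        samples=samples,
        means=np.hstack([male_means, female_means]),
    )


class TestBinDepths:
    def two_sample_depths(self, arrays):
        return {"M01": {"c1": arrays[0]}, "F01": {"c1": arrays[1]}}

    def test_constant_depth_single_window(self):
        depths = self.two_sample_depths([np.full(1000, 10), np.full(1000, 10)])
        (bd,) = bin_depths(depths, ContigTable((("c1", 1000),)))
        assert bd.means.tolist() == [[10.0, 10.0]]

    def test_partial_terminal_window_uses_true_length(self):
        depths = self.two_sample_depths([np.full(1500, 2), np.full(1500, 2)])
        (bd,) = bin_depths(depths, ContigTable((("c1", 1500),)))
        assert bd.starts.tolist() == [0, 1000]
        assert bd.ends.tolist() == [1000, 1500]
        assert np.allclose(bd.means, 2.0)

    def test_means_match_per_window_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.poisson(9, size=2573)
        depths = {"M01": {"c1": arr}, "F01": {"c1": arr.copy()}}
        (bd,) = bin_depths(depths, ContigTable((("c1", 2573),)), bin_width=500)
        expected = [arr[s:e].mean() for s, e in zip(bd.starts, bd.ends)]
        assert np.allclose(bd.means[:, 0], expected)

    def test_missing_sample_track_is_an_error(self):
        depths = {"M01": {}, "F01": {"c1": np.zeros(10)}}
        with pytest.raises(ValueError, match="no depth track"):
            bin_depths(depths, ContigTable((("c1", 10),)))


class TestWelchWindowTests:
    def test_identical_multisets_give_no_signal(self, cohort_13):
        means = [13, 12, 14, 13, 12, 14]
        bd = binned_from_means([means + [13]], [means])
        stats = welch_window_tests([bd], cohort_13)
        row = stats.iloc[0]
        assert row.t == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0, abs=1e-12)
        assert row.neg_log10_p == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_welch_formula(self, cohort_13):
        males = [12, 14, 13, 12, 14, 13, 12]
        females = [13, 12, 14, 13, 12, 14]
        bd = binned_from_means([males], [females])
        stats = welch_window_tests([bd], cohort_13)
        t_exp, p_exp = welch_oracle(males, females)
        assert stats.iloc[0].t == pytest.approx(t_exp, abs=1e-9)
        assert stats.iloc[0].p == pytest.approx(p_exp, abs=1e-9)

    def test_degenerate_variances_unequal_means_hit_cap(self, cohort_13):
        bd = binned_from_means([[13.0] * 7], [[0.0] * 6])
        stats = welch_window_tests([bd], cohort_13)
        assert stats.iloc[0].p == 1e-300
        assert stats.iloc[0].neg_log10_p == 300.0
        assert np.isposinf(stats.iloc[0].t)

    def test_degenerate_variances_equal_means_give_p_one(self, cohort_13):
        bd = binned_from_means([[5.0] * 7], [[5.0] * 6])
        stats = welch_window_tests([bd], cohort_13)
        assert stats.iloc[0].p == 1.0
        assert stats.iloc[0].t == 0.0

    def test_one_sided_zero_variance_stays_finite(self, cohort_13):
        males = [13.1, 12.9, 13.0, 13.2, 12.8, 13.0, 13.1]
        bd = binned_from_means([males], [[0.0] * 6])
        stats = welch_window_tests([bd], cohort_13)
        t_exp, p_exp = welch_oracle(males, [0.0] * 6)
        assert np.isfinite(stats.iloc[0].t)
        assert stats.iloc[0].p == pytest.approx(p_exp, rel=1e-9)

    def test_sex_label_swap_negates_t_keeps_p(self, cohort_13):
        rng = np.random.default_rng(5)
        m = rng.normal(13, 1, size=(40, 7))
        f = rng.normal(11, 2, size=(40, 6))
        fwd = welch_window_tests([binned_from_means(m, f)], cohort_13)
        swapped_cohort = make_cohort(6, 7)  # females first become "males"
        rev = welch_window_tests(
            [
                BinnedDepth(
                    "c1",
                    fwd.start.to_numpy(),
                    fwd.end.to_numpy(),
                    [f"M{i + 1:02d}" for i in range(6)]
                    + [f"F{i + 1:02d}" for i in range(7)],
                    np.hstack([f, m]),
                )
            ],
            swapped_cohort,
        )
        assert np.allclose(rev.t, -fwd.t)
        assert np.allclose(rev.p, fwd.p)

    def test_fewer_than_two_per_sex_is_an_error(self):
        bd = binned_from_means([[1.0, 2.0]], [[3.0]])
        with pytest.raises(ValueError, match="at least 2"):
            welch_window_tests([bd], make_cohort(2, 1))


class TestFilterDepthWindows:
    def frame(self, values):
        return pd.DataFrame(
            {
                "contig": "c1",
                "start": np.arange(len(values)) * 1000,
                "end": (np.arange(len(values)) + 1) * 1000,
                "neg_log10_p": values,
            }
        )

    def test_threshold_is_strict(self):
        kept = filter_depth_windows(self.frame([2.0, 2.0001]))
        assert kept.neg_log10_p.tolist() == [2.0001]

    def test_empty_input(self):
        assert len(filter_depth_windows(self.frame([]))) == 0

    def test_zero_threshold_keeps_everything_significant(self):
        kept = filter_depth_windows(self.frame([0.5, 0.0, 3.0]), threshold=0)
        assert len(kept) == 2


class TestZeroDepthTracts:
    def cohort_depths(self, female_arrays, male_arrays, length):
        depths = {}
        for i, arr in enumerate(male_arrays):
            depths[f"M{i + 1:02d}"] = {"c1": arr}
        for i, arr in enumerate(female_arrays):
            depths[f"F{i + 1:02d}"] = {"c1": arr}
        return depths, ContigTable((("c1", length),))

    def test_shared_zero_interval_is_one_tract(self):
        rng = np.random.default_rng(0)
        females = []
        for _ in range(6):
            arr = rng.poisson(13, 1000)
            arr[100:600] = 0
            females.append(arr)
        males = [rng.poisson(13, 1000) + 1 for _ in range(7)]
        depths, contigs = self.cohort_depths(females, males, 1000)
        tracts = zero_depth_tracts(
            depths, make_cohort(), Sex.FEMALE, contigs, min_tract_len=500
        )
        assert [(t.start, t.end) for t in tracts] == [(100, 600)]

    def test_single_nonzero_base_splits_the_tract(self):
        females = [np.zeros(1000, dtype=int) for _ in range(6)]
        females[0][300] = 1
        males = [np.full(1000, 13) for _ in range(7)]
        depths, contigs = self.cohort_depths(females, males, 1000)
        tracts = zero_depth_tracts(
            depths, make_cohort(), Sex.FEMALE, contigs, min_tract_len=1
        )
        spans = [(t.start, t.end) for t in tracts]
        assert (0, 300) in spans and (301, 1000) in spans

    def test_matches_per_base_intersection_oracle(self):
        rng = np.random.default_rng(42)
        length = 2000
        females = [rng.poisson(0.5, length) for _ in range(6)]
        males = [rng.poisson(13, length) for _ in range(7)]
        depths, contigs = self.cohort_depths(females, males, length)
        tracts = zero_depth_tracts(
            depths, make_cohort(), Sex.FEMALE, contigs,
            max_allowed_depth=0, min_tract_len=3,
        )
        ok = np.all([arr == 0 for arr in females], axis=0)
        expected = []
        start = None
        for i in range(length + 1):
            good = i < length and ok[i]
            if good and start is None:
                start = i
            elif not good and start is not None:
                if i - start >= 3:
                    expected.append((start, i))
                start = None
        assert [(t.start, t.end) for t in tracts] == expected
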