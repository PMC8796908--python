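import numpy as np
import pandas as pd
import pytest

from poolscan.diversity import (
    anova_fst_components,
    genomewide_summary,
    global_fst,
    hudson_fst_components,
    per_snp_fst,
    plugin_fst_components,
    pool_frequency_arrays,
    quantile_threshold,
    snp_fst_frame,
    snp_he,
    windowed_he,
)
from poolscan.types import PopulationMeta


def make_frame(meta, chrom, pos0, ref_counts, alt_counts, qual=30.0):
    data = {
        "chrom": chrom,
        "pos0": pos0,
        "ref": "A",
        "alt": "G",
        "qual": qual,
        "n_alt": 1,
    }
    for m, r, a in zip(meta, ref_counts, alt_counts):
        data[f"ref_{m.pool_id}"] = r
        data[f"alt_{m.pool_id}"] = a
    return pd.DataFrame(data)


@pytest.fixture
def two_pools():
    return [
        PopulationMeta("n1", "sp", 50, "north"),
        PopulationMeta("s1", "sp", 50, "south"),
    ]


@pytest.mark.parametrize("p,expected", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.1, 0.18)])
def test_snp_he_closed_form(p, expected):
    assert snp_he(p) == pytest.approx(expected)


def test_zero_depth_pool_has_missing_frequency(two_pools):
    frame = make_frame(two_pools, "chr1", [10], [[0], [30]], [[0], [30]])
    freqs, depths = pool_frequency_arrays(frame, two_pools)
    assert np.isnan(freqs[0, 0]) and freqs[0, 1] == 0.5
    assert depths[0, 0] == 0


class TestWindowedHe:
    def test_single_snp_in_empty_window(self, two_pools):
        # one SNP at p=0.5 diluted over the full 50 kb
        frame = make_frame(two_pools, "chr1", [100], [[20], [20]], [[20], [20]])
        win = windowed_he(frame, two_pools, {"chr1": 50_000})
        assert len(win) == 1
        assert win["he_n1"][0] == pytest.approx(1.0e-5)
        assert win["n_snps"][0] == 1

    def test_empty_window_is_zero(self, two_pools):
        frame = make_frame(two_pools, "chr1", [100], [[20], [20]], [[20], [20]])
        win = windowed_he(frame, two_pools, {"chr1": 100_000})
        assert win["he_n1"][1] == 0.0 and win["n_snps"][1] == 0

    def test_two_snp_window_sum(self, two_pools):
        # H_E 0.5 and 0.18 in one 50-kb window -> (0.5+0.18)/50000
        frame = make_frame(
            two_pools, "chr1", [100, 200], [[20, 45], [20, 45]], [[20, 5], [20, 5]]
        )
        win = windowed_he(frame, two_pools, {"chr1": 50_000})
        assert win["he_n1"][0] == pytest.approx(0.68 / 50_000)

    def test_trailing_partial_window_uses_actual_length(self, two_pools):
        frame = make_frame(two_pools, "chr1", [60_000], [[20], [20]], [[20], [20]])
        win = windowed_he(frame, two_pools, {"chr1": 60_500})
        assert win["end"].tolist() == [50_000, 60_500]
        assert win["he_n1"][1] == pytest.approx(0.5 / 10_500)

    def test_snp_beyond_tiling_is_an_error(self, two_pools):
        frame = make_frame(two_pools, "chr1", [70_000], [[20], [20]], [[20], [20]])
        with pytest.raises(ValueError, match="outside"):
            windowed_he(frame, two_pools, {"chr1": 60_000})

    def test_window_conservation_random_layouts(self, two_pools):
        """Sum(window He x length) equals the per-SNP He sum, exactly."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            length = int(rng.integers(10_000, 200_000))
            pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
            refs = rng.integers(0, 50, (2, pos.size))
            alts = rng.integers(0, 50, (2, pos.size))
            frame = make_frame(two_pools, "chr1", pos, refs, alts)
            wsize = int(rng.choice([7_000, 25_000, 50_000]))
            win = windowed_he(frame, two_pools, {"chr1": length}, wsize)
            freqs, _ = pool_frequency_arrays(frame, two_pools)
            he = np.nansum(snp_he(freqs), axis=0)
            lengths = (win["end"] - win["start"]).to_numpy()
            for j, m in enumerate(two_pools):
                total = float((win[f"he_{m.pool_id}"].to_numpy() * lengths).sum())
                assert total == pytest.approx(he[j], rel=1e-12, abs=1e-12)


class TestFstEstimators:
    def test_fixed_opposite_alleles_give_one(self):
        num, den = anova_fst_components([100], [0], [0], [100], 100, 100)
        assert per_snp_fst(num, den)[0] == pytest.approx(1.0)

    def test_identical_deep_profiles_near_zero(self):
        num, den = anova_fst_components([500], [500], [500], [500], 100, 100)
        assert abs(per_snp_fst(num, den)[0]) < 0.02

    def test_both_pools_fixed_same_allele_is_missing(self):
        num, den = anova_fst_components([100], [0], [100], [0], 100, 100)
        assert np.isnan(per_snp_fst(num, den)[0])

    def test_hudson_closed_form_parametric_limit(self):
        # p1=0.2, p2=0.8 at depth -> infinity: F = 0.36/0.68
        d = 10_000_000
        num, den = hudson_fst_components(
            [int(0.8 * d)], [int(0.2 * d)], [int(0.2 * d)], [int(0.8 * d)]
        )
        assert per_snp_fst(num, den)[0] == pytest.approx(0.36 / 0.68, abs=1e-4)

    def test_null_simulation_centred_on_zero(self):
        rng = np.random.default_rng(5)
        n = 10_000
        p0 = rng.uniform(0.05, 0.95, n)
        k1, k2 = rng.binomial(100, p0), rng.binomial(100, p0)
        d1, d2 = rng.poisson(100, n).clip(min=2), rng.poisson(100, n).clip(min=2)
        a1, a2 = rng.binomial(d1, k1 / 100), rng.binomial(d2, k2 / 100)
        num, den = anova_fst_components(d1 - a1, a1, d2 - a2, a2, 100, 100)
        assert abs(np.nanmean(per_snp_fst(num, den))) < 0.01
        assert abs(global_fst(num, den)) < 0.01

    @staticmethod
    def _pool_counts(rng, p_pop, two_n, depth):
        n = p_pop.size
        k = rng.binomial(two_n, p_pop)
        d = rng.poisson(depth, n).clip(min=2)
        a = rng.binomial(d, k / two_n)
        return d - a, a

    def test_pool_correction_depth_invariance_vs_plugin_bias(self):
        """Doubling depth leaves the pool-aware estimate unchanged while the
        naive plug-in on read frequencies drifts with depth."""
        rng = np.random.default_rng(11)
        n, F, two_n = 30_000, 0.14, 100
        p0 = rng.uniform(0.05, 0.95, n)
        shape = (1 - F) / F
        p1 = rng.beta(p0 * shape, (1 - p0) * shape)
        p2 = rng.beta(p0 * shape, (1 - p0) * shape)
        est = {}
        for depth in (25, 50):
            r1, a1 = self._pool_counts(rng, p1, two_n, depth)
            r2, a2 = self._pool_counts(rng, p2, two_n, depth)
            est[depth] = {
                "anova": global_fst(*anova_fst_components(r1, a1, r2, a2, two_n, two_n)),
                "plugin": global_fst(*plugin_fst_components(r1, a1, r2, a2)),
            }
        assert est[25]["anova"] == pytest.approx(est[50]["anova"], abs=0.01)
        # plug-in inflates FST more at lower depth
        assert est[25]["plugin"] - est[50]["plugin"] > 0.01
        assert est[25]["plugin"] - F > 0.02

    def test_anova_and_hudson_agree_at_depth_much_larger_than_pool(self):
        rng = np.random.default_rng(12)
        n, F, two_n, depth = 30_000, 0.14, 100, 1000
        p0 = rng.uniform(0.05, 0.95, n)
        shape = (1 - F) / F
        p1 = rng.beta(p0 * shape, (1 - p0) * shape)
        p2 = rng.beta(p0 * shape, (1 - p0) * shape)
        r1, a1 = self._pool_counts(rng, p1, two_n, depth)
        r2, a2 = self._pool_counts(rng, p2, two_n, depth)
        anova = global_fst(*anova_fst_components(r1, a1, r2, a2, two_n, two_n))
        hudson = global_fst(*hudson_fst_components(r1, a1, r2, a2))
        assert abs(anova - hudson) < 0.01


def test_snp_fst_frame_uses_north_south_pairs(two_pools):
    four = two_pools + [
        PopulationMeta("n2", "sp", 40, "north"),
        PopulationMeta("s2", "sp", 40, "south"),
    ]
    frame = make_frame(
        four, "chr1", [5, 10], [[30, 30]] * 4, [[30, 0], [0, 30], [30, 0], [0, 30]]
    )
    fst = snp_fst_frame(frame, four)
    # 2 north x 2 south pairings, two SNPs each
    assert len(fst) == 8
    assert set(zip(fst["pool_a"], fst["pool_b"])) == {
        ("n1", "s1"), ("n1", "s2"), ("n2", "s1"), ("n2", "s2")
    }


class TestSummaries:
    def test_mean_and_se_closed_form(self):
        mean, se, n = genomewide_summary([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert se == pytest.approx(1.0 / np.sqrt(3))

    def test_constant_vector_has_zero_se(self):
        _, se, _ = genomewide_summary([0.4] * 10)
        assert se == 0.0

    def test_single_value_has_missing_se(self):
        mean, se, n = genomewide_summary([1.5])
        assert mean == 1.5 and n == 1 and np.isnan(se)

    def test_seeded_normal_mean_within_three_se(self):
        draws = np.random.default_rng(3).standard_normal(1000)
        mean, se, _ = genomewide_summary(draws)
        assert abs(mean) < 3 * se


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    st.lists(
        st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=200
    ),
    st.floats(min_value=0.01, max_value=0.99),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_quantile_threshold_is_an_observed_value_within_bounds(values, q):
    t = quantile_threshold(values, q)
    assert min(values) <= t <= max(values)
    assert t in values


class TestQuantileThreshold:
    def test_nearest_rank_median(self):
        assert quantile_threshold(np.arange(1, 11), 0.5) == 5

    def test_constant_input(self):
        assert quantile_threshold([2.0] * 50, 0.99) == 2.0

    def test_top_rank_is_ceil_nq(self):
        # rank ceil(1000 * 0.999) = 999 -> the 999th smallest value
        assert quantile_threshold(np.arange(1, 1001), 0.999) == 999

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            quantile_threshold([], 0.5)
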