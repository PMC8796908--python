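import itertools
import math

import numpy as np
import pytest

from poolscan.convergence import (
    NullWConfig,
    draw_control_snps,
    empirical_p,
    null_w_test,
    wilcoxon_w_z,
)
from poolscan.scans import TopCandidateResult
from poolscan.types import GeneAnnotation, GeneRecord, OrthologPair


class TestDrawControls:
    def test_deterministic_under_seed(self):
        vals = np.arange(500, dtype=float)
        a = draw_control_snps(vals, 100, seed=9)
        b = draw_control_snps(vals, 100, seed=9)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 100  # without replacement

    def test_requesting_more_than_available_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="using all"):
            out = draw_control_snps(np.arange(50, dtype=float), 100, seed=0)
        assert out.size == 50

    def test_sampling_is_approximately_uniform(self):
        vals = np.arange(100, dtype=float)
        hits = np.zeros(100)
        for seed in range(1000):
            picked = draw_control_snps(vals, 10, seed=seed)
            hits[picked.astype(int)] += 1
        freq = hits / 1000
        assert freq.mean() == pytest.approx(0.1)
        assert abs(freq - 0.1).max() < 0.04


class TestWilcoxonWZ:
    def test_all_gene_values_above_controls(self):
        w, z = wilcoxon_w_z([10, 11, 12], [1, 2, 3])
        assert w == 9
        assert z == pytest.approx(4.5 / math.sqrt(5.25), abs=1e-6)

    def test_identical_groups_are_central(self):
        w, z = wilcoxon_w_z([1, 2, 3], [1, 2, 3])
        assert w == 4.5 and z == 0.0

    def test_label_swap_negates_z(self):
        rng = np.random.default_rng(0)
        g, c = rng.normal(0.4, 0.1, 8), rng.normal(0.2, 0.1, 15)
        _, z1 = wilcoxon_w_z(g, c)
        _, z2 = wilcoxon_w_z(c, g)
        assert z1 == pytest.approx(-z2)

    def test_all_tied_values_give_zero_z(self):
        w, z = wilcoxon_w_z([5, 5], [5, 5, 5])
        assert w == 3.0 and z == 0.0

    def test_w_counts_pairs_with_half_ties(self):
        # pairs: 2>1, 2=2 (half), 2<3 -> W = 1.5 per gene value
        w, _ = wilcoxon_w_z([2], [1, 2, 3])
        assert w == 1.5

    def test_z_matches_exact_enumeration_mean_and_variance(self):
        """Closed-form standardization equals exact permutation moments."""
        rng = np.random.default_rng(3)
        for n1, n2 in [(2, 3), (3, 3), (4, 2)]:
            combined = rng.integers(0, 5, n1 + n2).astype(float)  # forces ties
            idx = range(n1 + n2)
            ws = []
            for subset in itertools.combinations(idx, n1):
                g = combined[list(subset)]
                c = combined[[i for i in idx if i not in subset]]
                ws.append(wilcoxon_w_z(g, c)[0])
            ws = np.asarray(ws)
            w_obs, z_obs = wilcoxon_w_z(combined[:n1], combined[n1:])
            if ws.var() == 0:
                assert z_obs == 0.0
                continue
            z_exact = (w_obs - ws.mean()) / ws.std()
            assert z_obs == pytest.approx(z_exact, abs=1e-9)


from hypothesis import given, settings
from hypothesis import strategies as st

finite_floats = st.floats(min_value=-5, max_value=5, allow_nan=False)


@given(
    st.lists(finite_floats, min_size=1, max_size=15),
    st.lists(finite_floats, min_size=1, max_size=15),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_w_range_and_antisymmetry_property(g, c):
    w, z = wilcoxon_w_z(g, c)
    assert 0 <= w <= len(g) * len(c)
    w_swap, z_swap = wilcoxon_w_z(c, g)
    assert w + w_swap == pytest.approx(len(g) * len(c))
    assert z == pytest.approx(-z_swap, abs=1e-9)


class TestEmpiricalP:
    def test_above_every_null(self):
        assert empirical_p(10.0, np.linspace(-3, 3, 999)) == pytest.approx(1 / 1000)

    def test_at_null_median(self):
        null = np.linspace(-3, 3, 999)
        assert empirical_p(0.0, null) == pytest.approx(0.5, abs=0.01)

    def test_never_zero_or_above_one(self):
        null = np.arange(10, dtype=float)
        assert 0 < empirical_p(100.0, null) <= 1
        assert empirical_p(-100.0, null) == 1.0


def _gene_records(fst_by_gene):
    out = []
    for gid, vals in fst_by_gene.items():
        out.append(
            GeneRecord(
                annotation=GeneAnnotation(gid, "chr1", 0, 100),
                snp_fst_values=list(vals),
            )
        )
    return out


def _candidates(ids, candidate_ids):
    return [
        TopCandidateResult(g, 10, 6 if g in candidate_ids else 0, 5,
                           g in candidate_ids, 0.999, 0.001)
        for g in ids
    ]


class TestNullWTest:
    def _setup(self, seed=0, n_genes=120, planted=("a0",)):
        rng = np.random.default_rng(seed)
        genome_fst = rng.beta(1, 6, 5000)  # background FST distribution
        fst_by_gene = {}
        orthologs = []
        for i in range(n_genes):
            ga, gb = f"a{i}", f"b{i}"
            orthologs.append(OrthologPair(ga, gb, 99.0, 99.0, "one2one"))
            if ga in planted:
                # stochastically above the background
                fst_by_gene[gb] = rng.uniform(0.7, 1.0, 25)
            else:
                fst_by_gene[gb] = rng.choice(genome_fst, 25)
        return genome_fst, fst_by_gene, orthologs

    def test_planted_gene_attains_smallest_p(self):
        genome_fst, fst_by_gene, orthologs = self._setup(seed=1, planted=("a0",))
        cands = _candidates([f"a{i}" for i in range(120)], {"a0", "a5", "a9"})
        cfg = NullWConfig(n_control_snps=2000, rng_seed=4)
        out = null_w_test(cands, orthologs, _gene_records(fst_by_gene),
                          genome_fst, cfg)
        assert len(out.results) == 3
        best = min(out.results, key=lambda r: r.emp_p)
        assert best.gene_b == "b0"
        assert best.adj_p == pytest.approx(min(1.0, best.emp_p * 3))

    def test_empty_test_set_warns(self):
        genome_fst, fst_by_gene, orthologs = self._setup()
        cands = _candidates([f"a{i}" for i in range(120)], set())
        with pytest.warns(UserWarning, match="empty test set"):
            out = null_w_test(cands, orthologs, _gene_records(fst_by_gene),
                              genome_fst, NullWConfig(n_control_snps=2000))
        assert out.results == []

    def test_min_snp_threshold_excludes_sparse_genes(self):
        genome_fst, fst_by_gene, orthologs = self._setup()
        fst_by_gene["b0"] = [0.9]  # single SNP
        cands = _candidates([f"a{i}" for i in range(120)], {"a0", "a1"})
        cfg = NullWConfig(n_control_snps=2000, min_snps_per_gene=5)
        out = null_w_test(cands, orthologs, _gene_records(fst_by_gene), genome_fst, cfg)
        assert [r.gene_b for r in out.results] == ["b1"]

    def test_random_k_null_set_size(self):
        genome_fst, fst_by_gene, orthologs = self._setup()
        cands = _candidates([f"a{i}" for i in range(120)], {"a0"})
        cfg = NullWConfig(n_control_snps=2000, null_gene_set="random_k",
                          n_null_genes=50, rng_seed=3)
        with pytest.warns(UserWarning, match="unstable"):
            out = null_w_test(cands, orthologs, _gene_records(fst_by_gene),
                              genome_fst, cfg)
        assert out.null_z.size == 50

    def test_significance_respects_bonferroni(self):
        genome_fst, fst_by_gene, orthologs = self._setup(planted=("a0", "a1"))
        cands = _candidates([f"a{i}" for i in range(120)], {"a0", "a1"})
        out = null_w_test(cands, orthologs, _gene_records(fst_by_gene), genome_fst,
                          NullWConfig(n_control_snps=2000, rng_seed=5))
        for r in out.results:
            assert r.significant == (r.adj_p < 0.05)
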