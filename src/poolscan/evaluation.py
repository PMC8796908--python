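"""Self-validation experiments: parameter recovery, calibration and power.

Each function builds a synthetic scenario with the generator, runs the
relevant pipeline stages, and returns the measured quantity. The
scenarios are the package's reference study conditions:

* FST recovery — two pools of 50 diploids at depth 100, 1e5 SNPs, over
  the differentiation range the study species span (F = 0.02 to 0.49).
* Top-candidate power — genes of 2 kb at one SNP per ~55 bp (>= 20 SNPs
  per gene), 2% of genes planted at 4x the baseline F of 0.12. The
  planted fraction is kept small so the planted SNPs cannot saturate the
  genome-wide 0.999 outlier quantile.
* Null-W — 1000-gene ortholog maps, 10,000 control SNPs, baseline F
  0.12; the "strong convergence" scenario plants 1% of genes at F = 0.6
  in both species.

Every function is deterministic given its seed.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .convergence import NullWConfig, null_w_test
from .diversity import collapse_pairs_mean, global_fst, snp_fst_frame
from .gene_level import filter_orthologs, gene_mean_fst
from .scans import TopCandidateResult, fst_outlier_flags, top_candidates
from .synthetic_data import SimulationConfig, simulate_species, simulate_species_pair

FST_TARGETS = (0.02, 0.12, 0.14, 0.49)


def _recovery_cfg(species: str, fst: float, n_snps: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        species=species,
        n_chromosomes=2,
        chromosome_length=1_000_000,
        n_genes=100,
        n_snps=n_snps,
        pools=[(50, 100), (50, 100)],
        baseline_fst=fst,
        rng_seed=seed,
    )


def fst_parameter_recovery(
    seed: int, f_values: tuple[float, ...] = FST_TARGETS, n_snps: int = 100_000
) -> dict[float, float]:
    """Genome-wide multilocus FST estimated at each true baseline F."""
    out = {}
    for i, f in enumerate(f_values):
        ds = simulate_species(_recovery_cfg("R", f, n_snps, seed + i))
        fst = snp_fst_frame(ds.frame, ds.meta)
        out[f] = global_fst(fst["fst_num"].to_numpy(), fst["fst_den"].to_numpy())
    return out


def null_fst_bias(seed: int, n_snps: int = 100_000) -> float:
    """Estimated FST when populations share (essentially) identical
    frequencies: mean of per-SNP estimates, which should sit at zero."""
    ds = simulate_species(_recovery_cfg("N", 1e-9, n_snps, seed))
    fst = snp_fst_frame(ds.frame, ds.meta)
    return float(np.nanmean(fst["fst"].to_numpy()))


# ---------------------------------------------------------------------------
# top-candidate scan


def _scan(ds):
    fst = snp_fst_frame(ds.frame, ds.meta)
    records = gene_mean_fst(ds.genes, fst)
    snp = collapse_pairs_mean(fst)
    _, threshold = fst_outlier_flags(snp["fst"].to_numpy())
    return records, snp, top_candidates(records, threshold)


def topcandidate_neutral_fraction(
    seed: int, n_genes: int = 2000, n_snps: int = 50_000
) -> float:
    """Fraction of genes called candidates with nothing planted."""
    cfg = SimulationConfig(
        species="C",
        n_chromosomes=2,
        chromosome_length=2_500_000,
        n_genes=n_genes,
        gene_length=2_000,
        n_snps=n_snps,
        baseline_fst=0.12,
        rng_seed=seed,
    )
    _, _, results = _scan(simulate_species(cfg))
    return float(np.mean([r.is_candidate for r in results]))


def topcandidate_sensitivity(
    seed: int,
    n_reps: int = 10,
    elevation: float = 4.0,
    baseline: float = 0.12,
    n_planted: int = 4,
) -> float:
    """Recovery rate of genes planted at ``elevation`` x baseline F.

    200 genes per replicate, ~36 SNPs per gene, 2% planted.
    """
    hits = total = 0
    for r in range(n_reps):
        planted = [
            (f"P_g{i:04d}", elevation * baseline)
            for i in range(0, 200, 200 // n_planted)
        ][:n_planted]
        cfg = SimulationConfig(
            species="P",
            n_chromosomes=2,
            chromosome_length=500_000,
            n_genes=200,
            gene_length=2_000,
            n_snps=20_000,
            baseline_fst=baseline,
            selected_genes=planted,
            rng_seed=seed + r,
        )
        _, _, results = _scan(simulate_species(cfg))
        wanted = {g for g, _ in planted}
        hits += sum(r_.is_candidate for r_ in results if r_.gene_id in wanted)
        total += len(wanted)
    return hits / total


# ---------------------------------------------------------------------------
# Null-W


def _nullw_cfg(species: str, seed: int) -> SimulationConfig:
    return SimulationConfig(
        species=species,
        n_chromosomes=2,
        chromosome_length=2_000_000,
        n_genes=1000,
        gene_length=2_000,
        n_snps=40_000,
        baseline_fst=0.12,
        rng_seed=seed,
    )


def _nullw_run(seed: int, convergent_fraction: float, spoof_test: int = 0):
    pair = simulate_species_pair(
        _nullw_cfg("A", seed),
        _nullw_cfg("B", seed + 1),
        convergent_fraction=convergent_fraction,
        seed=seed,
        convergent_fst=0.6,
    )
    a, b = pair.dataset_a, pair.dataset_b
    fst_b = snp_fst_frame(b.frame, b.meta)
    rec_b = gene_mean_fst(b.genes, fst_b)
    snp_b = collapse_pairs_mean(fst_b)
    pairs = filter_orthologs(pair.orthologs, a.genes, b.genes)
    if spoof_test:
        # exchangeable test set: an arbitrary subset of orthologous genes
        rng = np.random.default_rng(seed + 10_000)
        chosen = set(
            rng.choice([p.gene_a for p in pairs], size=spoof_test, replace=False)
        )
        cands = [
            TopCandidateResult(p.gene_a, 10, 6 if p.gene_a in chosen else 0, 5,
                               p.gene_a in chosen, 0.999, 0.001)
            for p in pairs
        ]
    else:
        fst_a = snp_fst_frame(a.frame, a.meta)
        rec_a = gene_mean_fst(a.genes, fst_a)
        snp_a = collapse_pairs_mean(fst_a)
        _, thr = fst_outlier_flags(snp_a["fst"].to_numpy())
        cands = top_candidates(rec_a, thr)
    out = null_w_test(
        cands,
        pairs,
        rec_b,
        snp_b["fst"].to_numpy(),
        NullWConfig(n_control_snps=10_000, rng_seed=seed),
    )
    conv_b = set(
        pair.truth_orthologs.loc[pair.truth_orthologs.convergent, "gene_b"]
    )
    return out, conv_b


def nullw_null_significant_counts(seed: int, n_reps: int = 20) -> list[int]:
    """Bonferroni-significant calls per replicate with no convergence planted."""
    counts = []
    for r in range(n_reps):
        out, _ = _nullw_run(seed + 100 * r, convergent_fraction=0.0)
        counts.append(sum(res.significant for res in out.results))
    return counts


def nullw_pvalue_ks(seed: int, n_test: int = 300) -> float:
    """KS distance of null-scenario empirical p-values from Uniform(0,1)."""
    out, _ = _nullw_run(seed, convergent_fraction=0.0, spoof_test=n_test)
    ps = np.array([r.emp_p for r in out.results])
    return float(kstest(ps, "uniform").statistic)


def nullw_family_wise_power(seed: int, n_reps: int = 8) -> float:
    """Fraction of replicates where >= 1 planted convergent ortholog is
    Bonferroni-significant (1% of genes planted at F = 0.6 in both)."""
    hits = 0
    for r in range(n_reps):
        out, conv_b = _nullw_run(seed + 100 * r, convergent_fraction=0.01)
        hits += any(res.significant and res.gene_b in conv_b for res in out.results)
    return hits / n_reps


# ---------------------------------------------------------------------------
# ortholog filter truth check


def ortholog_filter_truth_match(seed: int) -> tuple[int, int, bool]:
    """(kept, expected, exact-match?) for a pair with known 1:many structure."""
    pair = simulate_species_pair(
        SimulationConfig(species="A", n_genes=400, n_snps=2_000, rng_seed=seed),
        SimulationConfig(species="B", n_genes=400, n_snps=2_000, rng_seed=seed + 1),
        seed=seed,
        one2many_fraction=0.2,
    )
    kept = {
        (p.gene_a, p.gene_b)
        for p in filter_orthologs(
            pair.orthologs, pair.dataset_a.genes, pair.dataset_b.genes
        )
    }
    truth = pair.truth_orthologs
    expected = {(r.gene_a, r.gene_b) for r in truth[truth.expected_kept].itertuples()}
    return len(kept), len(expected), kept == expected
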