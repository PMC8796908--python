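"""Null-W test for convergent evolution between a species pair.

Direction matters: top candidates are identified in species A, and the
test asks whether their orthologs in species B show elevated FST. Every
gene (test and null alike) is scored against one shared set of randomly
chosen control SNPs from species B using the Mann–Whitney W statistic,
normalised to a Z-score with the standard normal approximation
(tie-corrected variance, no continuity correction). Because selection
should *raise* FST in the second species, the test is one-sided on high Z.

Significance is judged empirically: each test gene's Z is placed within
the Z distribution of null genes (by default all orthologous
non-candidate genes; optionally a random subset), with the add-one
estimator p = (1 + #{null Z >= z}) / (1 + N_null) so p is never zero,
then Bonferroni-corrected across test genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scans import TopCandidateResult
from .types import GeneRecord, OrthologPair


@dataclass
class NullWConfig:
    n_control_snps: int = 10_000
    null_gene_set: str = "all_noncandidate_orthologs"  # or "random_k"
    n_null_genes: int = 1000
    min_snps_per_gene: int = 1
    rng_seed: int = 0
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.n_control_snps < 1:
            raise ValueError("n_control_snps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.null_gene_set not in ("all_noncandidate_orthologs", "random_k"):
            raise ValueError(f"unknown null_gene_set {self.null_gene_set!r}")
        if self.correction != "bonferroni":
            raise ValueError("only bonferroni correction is supported")


@dataclass
class NullWResult:
    gene_a: str
    gene_b: str
    n_gene_snps: int
    W: float
    Z: float
    emp_p: float
    adj_p: float
    significant: bool


@dataclass
class NullWOutput:
    results: list[NullWResult] = field(default_factory=list)
    null_z: np.ndarray = field(default_factory=lambda: np.empty(0))
    control_fst: np.ndarray = field(default_factory=lambda: np.empty(0))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [r.gene_a for r in self.results],
                "gene_b": [r.gene_b for r in self.results],
                "n_gene_snps": [r.n_gene_snps for r in self.results],
                "W": [r.W for r in self.results],
                "Z": [r.Z for r in self.results],
                "emp_p": [r.emp_p for r in self.results],
                "adj_p": [r.adj_p for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def draw_control_snps(
    fst: Sequence[float] | np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Sample n control FST values without replacement, deterministically.

    The same control set must be reused for all test and null genes within
    one run. If fewer than n values are available, all are used (warning).
    """
    arr = np.asarray(fst, float)
    arr = arr[np.isfinite(arr)]
    rng = np.random.default_rng(seed)
    if arr.size <= n:
        if arr.size < n:
            warnings.warn(
                f"only {arr.size} non-missing FST values for {n} requested controls; using all"
            )
        return arr.copy()
    return rng.choice(arr, size=n, replace=False)


def wilcoxon_w_z(
    gene_fst: Sequence[float] | np.ndarray, control_fst: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Mann–Whitney W of the gene's SNPs versus the controls, and its Z-score.

    W counts (gene, control) pairs where the gene value ranks higher, ties
    as 1/2. Z = (W - n1 n2 / 2) / sd with the tie-corrected variance
    n1 n2 / 12 * (n + 1 - sum(t^3 - t) / (n (n - 1))); Z = 0 when every
    value is tied.
    """
    g = np.asarray(gene_fst, float)
    c = np.asarray(control_fst, float)
    g = g[np.isfinite(g)]
    c = c[np.isfinite(c)]
    if g.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = g.size, c.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([g, c]))
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(np.concatenate([g, c]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 0.0
    z = (w - n1 * n2 / 2.0) / np.sqrt(var)
    return w, float(z)


def empirical_p(z: float, null_z: np.ndarray) -> float:
    """Add-one one-sided empirical p: position of z within the null Z set."""
    return float((1 + np.sum(null_z >= z)) / (1 + null_z.size))


def null_w_test(
    candidates_a: Sequence[TopCandidateResult],
    orthologs: Sequence[OrthologPair],
    genes_b: Sequence[GeneRecord],
    fst_b: Sequence[float] | np.ndarray,
    cfg: NullWConfig | None = None,
) -> NullWOutput:
    """Run the directional Null-W test (candidates from A, FST from B).

    ``orthologs`` must already be filtered to 1:1 pairs; ``genes_b`` carry
    the per-SNP FST values of species B. Genes with fewer than
    ``cfg.min_snps_per_gene`` informative SNPs are excluded from both the
    test and the null set.
    """
    cfg = cfg or NullWConfig()
    by_id_b = {g.gene_id: g for g in genes_b}
    candidate_ids_a = {r.gene_id for r in candidates_a if r.is_candidate}

    def usable(gene_id: str) -> bool:
        g = by_id_b.get(gene_id)
        if g is None:
            return False
        vals = np.asarray(g.snp_fst_values, float)
        return int(np.isfinite(vals).sum()) >= cfg.min_snps_per_gene

    test_ids = {p.gene_b for p in orthologs if p.gene_a in candidate_ids_a and usable(p.gene_b)}
    null_ids = [
        p.gene_b
        for p in orthologs
        if p.gene_a not in candidate_ids_a and p.gene_b not in test_ids and usable(p.gene_b)
    ]
    if cfg.null_gene_set == "random_k" and len(null_ids) > cfg.n_null_genes:
        rng = np.random.default_rng(cfg.rng_seed + 1)
        null_ids = list(rng.choice(null_ids, size=cfg.n_null_genes, replace=False))

    out = NullWOutput()
    if not test_ids:
        warnings.warn("Null-W: empty test set (no candidate orthologs with SNPs)")
        return out
    if len(null_ids) < 100:
        warnings.warn(
            f"Null-W: only {len(null_ids)} null genes; empirical p-values are unstable"
        )

    controls = draw_control_snps(fst_b, cfg.n_control_snps, cfg.rng_seed)
    out.control_fst = controls

    null_z = np.array(
        [wilcoxon_w_z(by_id_b[i].snp_fst_values, controls)[1] for i in null_ids]
    )
    out.null_z = null_z

    pair_by_b = {p.gene_b: p for p in orthologs}
    n_tests = len(test_ids)
    for gene_b_id in sorted(test_ids):
        g = by_id_b[gene_b_id]
        w, z = wilcoxon_w_z(g.snp_fst_values, controls)
        p = empirical_p(z, null_z)
        adj = min(1.0, p * n_tests)
        out.results.append(
            NullWResult(
                gene_a=pair_by_b[gene_b_id].gene_a,
                gene_b=gene_b_id,
                n_gene_snps=int(np.isfinite(np.asarray(g.snp_fst_values, float)).sum()),
                W=w,
                Z=z,
                emp_p=p,
                adj_p=adj,
                significant=adj < cfg.alpha,
            )
        )
    return out
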